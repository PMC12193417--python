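"""Herbicide multi-resistance profiling and trait-resistance correlation.

A population is scored against each herbicide by its fresh-weight inhibition
rate relative to untreated controls, 100*(1 - treated/control); a rate below
78% calls the population resistant to that herbicide.  Multi-resistance is
summarized as the number of distinct herbicide sites of action (SOAs) with at
least one resistant call, and correlated with quantitative traits by Pearson
r with two-sided t-distribution p-values (n-2 df).

The default SOA map covers the six assay herbicides with their HRAC/WSSA-style
mechanism classes (ACCase inhibitors, ALS inhibitors, PSII inhibitor, synthetic
auxin); it is a plain dict and can be overridden from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ResistanceTable, TraitTable

#: Fresh-weight inhibition (%) below which a population is called resistant.
RESISTANCE_THRESHOLD = 78.0

#: Mechanism classes for the six whole-plant assay herbicides.
DEFAULT_SOA_MAP = {
    "metamifop": "ACCase",
    "cyhalofop-butyl": "ACCase",
    "penoxsulam": "ALS",
    "pyribenzoxim": "ALS",
    "propanil": "PSII",
    "quinclorac": "auxin",
}


def inhibition_rate(treated_fw: float, control_fw: float) -> float:
    """Fresh-weight inhibition percent, clamped at 0 when treated > control."""
    if control_fw <= 0:
        raise ValidationError("control fresh weight must be > 0")
    if treated_fw < 0:
        raise ValidationError("treated fresh weight must be >= 0")
    return max(0.0, 100.0 * (1.0 - treated_fw / control_fw))


def call_resistance(inhibition: float) -> bool:
    """True iff inhibition is strictly below the 78% threshold."""
    if not 0 <= inhibition <= 100:
        raise ValidationError(f"inhibition {inhibition} outside [0, 100]")
    return inhibition < RESISTANCE_THRESHOLD


def soa_profile(
    calls: dict[str, bool], soa_map: dict[str, str] | None = None
) -> int:
    """Number of distinct SOA classes with at least one resistant call."""
    soa_map = DEFAULT_SOA_MAP if soa_map is None else soa_map
    unmapped = [h for h in calls if h not in soa_map]
    if unmapped:
        raise ValidationError(f"herbicide(s) missing from SOA map: {unmapped}")
    return len({soa_map[h] for h, res in calls.items() if res})


def resistance_profiles(
    table: ResistanceTable, soa_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-population profile: inhibition per herbicide, resistant calls,
    resistant-herbicide count and distinct-SOA count.

    Returned frame is indexed by population_id with one inhibition column per
    herbicide plus ``n_resistant`` and ``soa_count``.
    """
    soa_map = DEFAULT_SOA_MAP if soa_map is None else soa_map
    wide = table.wide()
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index[0]
        raise ValidationError(f"incomplete herbicide panel for {missing!r}")
    calls = wide.apply(lambda col: col.map(call_resistance))
    out = wide.copy()
    out["n_resistant"] = calls.sum(axis=1).astype(int)
    out["soa_count"] = [
        soa_profile(dict(zip(wide.columns, row)), soa_map)
        for row in calls.to_numpy()
    ]
    return out


def trait_resistance_correlation(
    table: TraitTable,
    profiles: pd.DataFrame,
    on: str = "soa_count",
) -> pd.DataFrame:
    """Pearson correlation of each trait with multi-resistance.

    ``on`` selects the multi-resistance variable: ``"soa_count"`` (distinct
    sites of action, the default) or ``"n_resistant"`` (herbicide count).
    Returns per-trait r, two-sided p (t distribution, n-2 df) and
    significance flags at 0.05 / 0.01.  Zero-variance pairs are reported as
    missing (NaN), never silently dropped.
    """
    if on not in profiles.columns:
        raise ValidationError(f"profiles lack column {on!r}")
    common = [p for p in table.populations if p in profiles.index]
    if len(common) < 3:
        raise ValidationError("need at least 3 matched populations")
    if set(table.populations) != set(profiles.index):
        diff = set(table.populations) ^ set(profiles.index)
        raise ValidationError(f"population mismatch: {sorted(diff)}")
    y = profiles.loc[common, on].to_numpy(dtype=float)
    rows = {}
    for trait in table.data.columns:
        x = table.data.loc[common, trait].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows[trait] = {"r": np.nan, "p": np.nan}
            continue
        r, p = stats.pearsonr(x, y)
        rows[trait] = {"r": float(r), "p": float(p)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["sig_05"] = out["p"] <= 0.05
    out["sig_01"] = out["p"] <= 0.01
    out.attrs["n"] = len(common)
    out.attrs["on"] = on
    return out
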