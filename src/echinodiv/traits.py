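"""Quantitative-trait variation and diversity statistics, and Ward clustering.

For each trait measured across populations the module computes the classical
germplasm-survey summary: range, max, min, mean (X), sample standard
deviation (s, n-1 denominator), coefficient of variation CV = 100*s/X, and
the Shannon-Wiener diversity index H' = -sum(Pi ln Pi) over ten trait levels.

Levels span X +/- 2s in steps of 0.5s: level 1 holds values below X - 2s,
level 10 holds values at or above X + 2s, and the eight inner levels are the
half-open intervals [X - 2s + (k-2)*0.5s, X - 2s + (k-1)*0.5s) for k = 2..9.
With ten levels H' is bounded by ln(10) ~ 2.3026 nats, attained only by the
uniform level distribution.

Clustering standardizes each trait to zero mean and unit sample SD and
applies Ward's minimum-variance method over Euclidean distances; the
dendrogram may be cut at a height threshold (optionally on a 0-25 rescaled
axis as drawn by SPSS-style software) into integer-labelled clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import (
    ClusterAssignment,
    Dendrogram,
    cut_dendrogram,
    cut_dendrogram_k,
    ward_dendrogram,
)
from .errors import ValidationError
from .io import TRAIT_COLUMNS, TraitTable

N_LEVELS = 10

SUMMARY_COLUMNS = ["Range", "Max", "Min", "Mean", "S", "CV", "Hprime"]


@dataclass
class LevelDistribution:
    """Per-trait 10-level assignment and level frequencies.

    ``levels``: population x trait integer levels in 1..10.
    ``frequencies``: trait x level frequency matrix, each row summing to 1.
    """

    levels: pd.DataFrame
    frequencies: pd.DataFrame


def summarize_trait(values: np.ndarray | pd.Series) -> dict[str, float]:
    """Range/max/min/mean/s/CV for one trait vector (sample SD, n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values to summarize a trait")
    if not np.isfinite(v).all():
        raise ValidationError("non-finite trait value")
    mean = float(v.mean())
    s = float(v.std(ddof=1))
    if mean == 0:
        if s > 0:
            raise ValidationError("CV undefined: zero mean with positive SD")
        cv = 0.0
    else:
        cv = 100.0 * s / mean
    return {
        "Range": float(v.max() - v.min()),
        "Max": float(v.max()),
        "Min": float(v.min()),
        "Mean": mean,
        "S": s,
        "CV": cv,
    }


def cv_percent(mean: float, s: float) -> float:
    """CV (%) = 100*s/mean, the scale-free dispersion of a trait."""
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    return 100.0 * s / mean


def assign_levels(
    values: np.ndarray | pd.Series, mean: float, sd: float
) -> np.ndarray:
    """Assign each value a level 1..10 on the X +/- 2s grid (0.5s steps).

    Intervals are half-open [lo, hi); level 1 is v < X-2s and level 10 is
    v >= X+2s, so ties at any inner edge fall in the upper bin.
    """
    if sd <= 0:
        raise ValidationError("degenerate trait: sd must be > 0 for level binning")
    v = np.asarray(values, dtype=float)
    # inner edges at X-2s, X-1.5s, ..., X+2s -> bin index via floor division
    idx = np.floor((v - (mean - 2 * sd)) / (0.5 * sd)).astype(int) + 2
    return np.clip(idx, 1, N_LEVELS)


def level_frequencies(levels: np.ndarray) -> np.ndarray:
    """Frequency vector P over the 10 levels (sums to 1)."""
    levels = np.asarray(levels, dtype=int)
    counts = np.bincount(levels, minlength=N_LEVELS + 1)[1 : N_LEVELS + 1]
    return counts / counts.sum()


def shannon_index(freqs: np.ndarray | pd.Series) -> float:
    """Shannon-Wiener H' = -sum(Pi ln Pi), zero terms contributing 0 (nats)."""
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValidationError("negative frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"frequencies sum to {p.sum()}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def diversity_table(
    table: TraitTable,
) -> tuple[pd.DataFrame, LevelDistribution]:
    """Per-trait summary rows (Range..CV, H') plus the level distribution.

    The returned summary carries ``mean CV`` and ``mean H'`` in
    ``summary.attrs["mean_cv"]`` / ``attrs["mean_hprime"]``.
    """
    if table.n_populations < 2:
        raise ValidationError("need at least 2 populations")
    rows = {}
    levels = {}
    freqs = {}
    for trait in TRAIT_COLUMNS:
        v = table.data[trait].to_numpy(dtype=float)
        row = summarize_trait(v)
        lev = assign_levels(v, row["Mean"], row["S"])
        p = level_frequencies(lev)
        row["Hprime"] = shannon_index(p)
        rows[trait] = row
        levels[trait] = lev
        freqs[trait] = p
    summary = pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_COLUMNS]
    summary.attrs["mean_cv"] = float(summary["CV"].mean())
    summary.attrs["mean_hprime"] = float(summary["Hprime"].mean())
    dist = LevelDistribution(
        pd.DataFrame(levels, index=table.populations),
        pd.DataFrame(freqs, index=[f"L{i}" for i in range(1, N_LEVELS + 1)]).T,
    )
    return summary, dist


def summary_aggregates(summary: pd.DataFrame) -> dict[str, float]:
    """Column means of CV and H' over the per-trait summary rows."""
    return {
        "mean_cv": float(summary["CV"].mean()),
        "mean_hprime": float(summary["Hprime"].mean()),
    }


def standardize(table: TraitTable) -> pd.DataFrame:
    """Z-score each trait column (mean 0, sample SD 1)."""
    z = {}
    for trait in TRAIT_COLUMNS:
        v = table.data[trait].to_numpy(dtype=float)
        s = v.std(ddof=1)
        if s == 0:
            raise ValidationError(f"constant trait column {trait}: cannot standardize")
        z[trait] = (v - v.mean()) / s
    return pd.DataFrame(z, index=table.populations)


def ward_cluster(z: pd.DataFrame, rescale_spss: bool = False) -> Dendrogram:
    """Ward dendrogram of standardized trait rows (Euclidean distances)."""
    d = ward_dendrogram(z.to_numpy(dtype=float), list(z.index))
    if rescale_spss:
        d = d.rescale_spss()
    return d


def cluster_profiles(
    assignment: ClusterAssignment, table: TraitTable
) -> pd.DataFrame:
    """Per-cluster trait means plus cluster sizes."""
    missing = set(table.populations) - set(assignment.ids)
    if missing:
        raise ValidationError(f"unassigned populations: {sorted(missing)}")
    labels = pd.Series(assignment.labels, index=assignment.ids)
    joined = table.data.copy()
    joined["cluster"] = labels.reindex(joined.index)
    profile = joined.groupby("cluster").mean()
    profile["n"] = joined.groupby("cluster").size()
    return profile


__all__ = [
    "ClusterAssignment",
    "Dendrogram",
    "LevelDistribution",
    "assign_levels",
    "cluster_profiles",
    "cut_dendrogram",
    "cut_dendrogram_k",
    "cv_percent",
    "diversity_table",
    "level_frequencies",
    "shannon_index",
    "standardize",
    "summarize_trait",
    "summary_aggregates",
    "ward_cluster",
]
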