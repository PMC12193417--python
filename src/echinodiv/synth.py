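"""Synthetic multi-marker studies with known ground truth.

Generates a complete study — trait table, per-locus barcode alignments, 0/1
band matrix and resistance table — from a :class:`SimulationConfig` holding
G population groups with:

* group-specific trait archetypes (normal mean/SD per group and trait);
* group-specific barcode haplotypes: each locus has a random reference
  sequence plus planted per-group substitutions; within-group sequences are
  identical by default (groups are haplotype classes);
* group-structured band profiles with symmetric Bernoulli flip noise on the
  plan's polymorphic loci (monomorphic loci model invariant bands and stay
  invariant);
* a multi-resistance count drawn from a binomial whose logit is linear in
  selected z-scored traits, then expanded into per-herbicide fresh weights.

One master seed feeds four documented substreams (traits, sequences, bands,
resistance) spawned in that fixed order from ``numpy.random.SeedSequence``,
so identical config + seed reproduce byte-identical files and adding a
generator never perturbs earlier streams.

:func:`reference_survey_config` returns the default study: 46 populations in 5
groups (sizes 12/13/9/3/9), loci ITS 588 bp / psbA 337 bp / matK 1312 bp /
trnL-F 954 bp carrying 5/2/2/1 haplotypes, and 72 bands over 6 primers of
which 62 are polymorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import (
    BandMatrix,
    LocusAlignment,
    ResistanceTable,
    TRAIT_COLUMNS,
    TraitTable,
    write_alignment,
    write_band_matrix,
    write_trait_table,
)
from .resistance import DEFAULT_SOA_MAP

DNA = np.array(list("ACGT"))


@dataclass
class LocusPlan:
    """Barcode locus: reference length and per-group planted substitutions.

    ``group_substitutions[g]`` is a tuple of (1-based position, base) pairs;
    groups absent from the dict carry the reference haplotype.  The generated
    reference carries 'A' at every planted position so any substitution to
    C/G/T is guaranteed to create variation.
    """

    name: str
    length: int
    group_substitutions: dict[int, tuple[tuple[int, str], ...]] = field(
        default_factory=dict
    )

    def planted_positions(self) -> list[int]:
        pos = sorted(
            {p for subs in self.group_substitutions.values() for p, _ in subs}
        )
        return pos

    def validate(self, n_groups: int) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.name}: length must be positive")
        for g, subs in self.group_substitutions.items():
            if not 1 <= g <= n_groups:
                raise ValidationError(f"{self.name}: unknown group {g}")
            for pos, base in subs:
                if not 1 <= pos <= self.length:
                    raise ValidationError(
                        f"{self.name}: position {pos} outside 1..{self.length}"
                    )
                if base not in "CGT":
                    raise ValidationError(
                        f"{self.name}: substitution base must be C/G/T, got {base!r}"
                    )


@dataclass
class SimulationConfig:
    group_sizes: list[int]
    trait_means: pd.DataFrame  # groups (1..G) x M1..M9
    trait_sds: pd.DataFrame
    loci: list[LocusPlan]
    band_loci: list[str]
    band_primer_of: dict[str, str]
    group_band_profiles: np.ndarray  # G x n_loci 0/1
    flip_prob: float = 0.02
    herbicides: list[str] = field(
        default_factory=lambda: list(DEFAULT_SOA_MAP)
    )
    soa_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SOA_MAP))
    coupling: float = 1.2
    coupling_intercept: float = 0.0
    coupled_traits: list[str] = field(default_factory=lambda: ["M1", "M6"])
    within_group_mutation_rate: float = 0.0
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_populations(self) -> int:
        return int(sum(self.group_sizes))

    def population_ids(self) -> list[str]:
        return [f"P{i + 1:03d}" for i in range(self.n_populations)]

    def group_of(self) -> np.ndarray:
        """True group label (1..G) per population, in population order."""
        return np.repeat(np.arange(1, self.n_groups + 1), self.group_sizes)

    def validate(self) -> None:
        if self.n_groups < 1 or any(s < 1 for s in self.group_sizes):
            raise ValidationError("group sizes must be positive")
        for df, what in ((self.trait_means, "means"), (self.trait_sds, "SDs")):
            if list(df.columns) != TRAIT_COLUMNS or len(df) != self.n_groups:
                raise ValidationError(f"trait {what} must be G x M1..M9")
        if (self.trait_sds.to_numpy() <= 0).any():
            raise ValidationError("trait SDs must be > 0")
        for plan in self.loci:
            plan.validate(self.n_groups)
        if not 0 <= self.flip_prob < 0.5:
            raise ValidationError("flip probability must lie in [0, 0.5)")
        if self.group_band_profiles.shape != (self.n_groups, len(self.band_loci)):
            raise ValidationError("band profiles must be G x n_loci")
        if not np.isin(self.group_band_profiles, (0, 1)).all():
            raise ValidationError("band profiles must be 0/1")
        missing = [l for l in self.band_loci if l not in self.band_primer_of]
        if missing:
            raise ValidationError(f"band loci without primer: {missing}")
        unmapped = [h for h in self.herbicides if h not in self.soa_map]
        if unmapped:
            raise ValidationError(f"herbicides without SOA class: {unmapped}")
        bad = [t for t in self.coupled_traits if t not in TRAIT_COLUMNS]
        if bad:
            raise ValidationError(f"unknown coupled trait(s): {bad}")
        if not 0 <= self.within_group_mutation_rate < 1:
            raise ValidationError("within-group mutation rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "group_sizes": [int(s) for s in self.group_sizes],
            "trait_means": {
                str(g): [float(v) for v in row]
                for g, row in self.trait_means.iterrows()
            },
            "trait_sds": {
                str(g): [float(v) for v in row]
                for g, row in self.trait_sds.iterrows()
            },
            "loci": [
                {
                    "name": p.name,
                    "length": p.length,
                    "group_substitutions": {
                        str(g): [[int(pos), base] for pos, base in subs]
                        for g, subs in p.group_substitutions.items()
                    },
                }
                for p in self.loci
            ],
            "band_loci": list(self.band_loci),
            "band_primer_of": dict(self.band_primer_of),
            "group_band_profiles": self.group_band_profiles.tolist(),
            "flip_prob": float(self.flip_prob),
            "herbicides": list(self.herbicides),
            "soa_map": dict(self.soa_map),
            "coupling": float(self.coupling),
            "coupling_intercept": float(self.coupling_intercept),
            "coupled_traits": list(self.coupled_traits),
            "within_group_mutation_rate": float(self.within_group_mutation_rate),
            "seed": int(self.seed),
        }


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated study."""

    groups: pd.Series  # population_id -> true group (1..G)
    snp_positions: dict[str, list[int]]  # locus -> planted 1-based positions
    band_profiles: np.ndarray  # G x n_loci

    def partition(self) -> frozenset[frozenset]:
        return frozenset(
            frozenset(self.groups.index[self.groups == g])
            for g in sorted(self.groups.unique())
        )


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    trait_table: TraitTable
    alignments: dict[str, LocusAlignment]
    band_matrix: BandMatrix
    resistance_fresh_weights: pd.DataFrame  # long: population, herbicide, fws
    resistance_table: ResistanceTable
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _simulate_traits(
    cfg: SimulationConfig, rng: np.random.Generator
) -> TraitTable:
    groups = cfg.group_of()
    rows = np.empty((cfg.n_populations, len(TRAIT_COLUMNS)))
    for t, trait in enumerate(TRAIT_COLUMNS):
        mu = cfg.trait_means[trait].to_numpy()[groups - 1]
        sd = cfg.trait_sds[trait].to_numpy()[groups - 1]
        v = rng.normal(mu, sd)
        if trait == "M7":
            v = np.clip(v, 0.01, 1.0)
        else:
            v = np.clip(v, 0.0, None)
        rows[:, t] = v
    data = pd.DataFrame(rows, index=cfg.population_ids(), columns=TRAIT_COLUMNS)
    data.index.name = "population_id"
    return TraitTable(data)


def _simulate_alignments(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, LocusAlignment]:
    groups = cfg.group_of()
    pops = cfg.population_ids()
    out = {}
    for plan in cfg.loci:
        ref = rng.choice(DNA, size=plan.length)
        for pos in plan.planted_positions():
            ref[pos - 1] = "A"  # guarantee substitutions create variation
        group_seqs = {}
        for g in range(1, cfg.n_groups + 1):
            seq = ref.copy()
            for pos, base in plan.group_substitutions.get(g, ()):
                seq[pos - 1] = base
            group_seqs[g] = seq
        sequences = {}
        for pid, g in zip(pops, groups):
            seq = group_seqs[g].copy()
            if cfg.within_group_mutation_rate > 0:
                hits = rng.random(plan.length) < cfg.within_group_mutation_rate
                for i in np.where(hits)[0]:
                    choices = [b for b in "ACGT" if b != seq[i]]
                    seq[i] = rng.choice(choices)
            sequences[pid] = "".join(seq)
        out[plan.name] = LocusAlignment(plan.name, list(pops), sequences)
    return out


def _simulate_bands(
    cfg: SimulationConfig, rng: np.random.Generator
) -> BandMatrix:
    groups = cfg.group_of()
    profiles = cfg.group_band_profiles
    # flip noise only where the plan itself is polymorphic: invariant bands
    # model loci scored identically in every sample
    plan_poly = profiles.min(axis=0) != profiles.max(axis=0)
    rows = profiles[groups - 1].copy()
    flips = (rng.random(rows.shape) < cfg.flip_prob) & plan_poly[None, :]
    rows = rows ^ flips
    data = pd.DataFrame(
        rows.astype(int), index=cfg.population_ids(), columns=cfg.band_loci
    )
    data.index.name = "sample_id"
    return BandMatrix(data, dict(cfg.band_primer_of))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_resistance(
    cfg: SimulationConfig, traits: TraitTable, rng: np.random.Generator
) -> tuple[pd.DataFrame, ResistanceTable]:
    pops = cfg.population_ids()
    z = np.zeros(len(pops))
    for trait in cfg.coupled_traits:
        v = traits.data[trait].to_numpy(dtype=float)
        s = v.std(ddof=1)
        if s > 0:
            z += (v - v.mean()) / s
    z /= max(len(cfg.coupled_traits), 1)
    soa_classes = sorted(set(cfg.soa_map[h] for h in cfg.herbicides))
    p = _sigmoid(cfg.coupling_intercept + cfg.coupling * z)
    soa_counts = rng.binomial(len(soa_classes), p)
    records = []
    for pid, count in zip(pops, soa_counts):
        resistant_classes = set(
            rng.choice(soa_classes, size=count, replace=False)
        )
        for herb in cfg.herbicides:
            resistant = cfg.soa_map[herb] in resistant_classes
            inhib = rng.uniform(35, 70) if resistant else rng.uniform(85, 99.5)
            control = rng.uniform(8.0, 12.0)
            treated = control * (1 - inhib / 100.0)
            records.append(
                {
                    "population_id": pid,
                    "herbicide": herb,
                    "treated_fw": round(treated, 4),
                    "control_fw": round(control, 4),
                }
            )
    fw = pd.DataFrame.from_records(records)
    inhib = 100.0 * (1 - fw["treated_fw"] / fw["control_fw"])
    table = ResistanceTable(
        pd.DataFrame(
            {
                "population_id": fw["population_id"],
                "herbicide": fw["herbicide"],
                "inhibition": inhib.clip(lower=0.0),
            }
        )
    )
    return fw, table


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Simulate a full study from a validated config; fully seed-determined."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    trait_ss, seq_ss, band_ss, res_ss = ss.spawn(4)
    traits = _simulate_traits(cfg, np.random.default_rng(trait_ss))
    alignments = _simulate_alignments(cfg, np.random.default_rng(seq_ss))
    bands = _simulate_bands(cfg, np.random.default_rng(band_ss))
    fw, res = _simulate_resistance(cfg, traits, np.random.default_rng(res_ss))
    truth = SyntheticTruth(
        pd.Series(cfg.group_of(), index=cfg.population_ids(), name="group"),
        {p.name: p.planted_positions() for p in cfg.loci},
        cfg.group_band_profiles.copy(),
    )
    return SyntheticStudy(cfg, traits, alignments, bands, fw, res, truth)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study's input files plus truth.csv and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["traits"] = out / "traits.csv"
    write_trait_table(study.trait_table, paths["traits"])
    for locus, aln in study.alignments.items():
        p = out / f"{locus.replace('/', '_')}.fasta"
        write_alignment(aln, p)
        paths[f"fasta:{locus}"] = p
    paths["bands"] = out / "bands.csv"
    paths["primer_map"] = out / "primer_map.csv"
    write_band_matrix(study.band_matrix, paths["bands"], paths["primer_map"])
    paths["resistance"] = out / "resistance.csv"
    study.resistance_fresh_weights.to_csv(paths["resistance"], index=False)
    paths["truth"] = out / "truth.csv"
    study.truth.groups.rename_axis("population_id").to_csv(paths["truth"])
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(study.config.to_dict(), fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# The default (study-condition) configuration
# ---------------------------------------------------------------------------

# Within-group archetypes for the five morphotypes: group 1 tall/long-leaved/
# awnless, group 2 short-leaved slender, group 3 compact thick-stemmed with
# long awns, group 4 tall long-awned (small group), group 5 diminutive
# awnless.  Overall means/SDs sit near the published survey aggregates.
_GROUP_TRAIT_MEANS = {
    #        M1     M2    M3    M4    M5     M6     M7    M8    M9
    1: [39.0, 1.40, 11.5, 3.50, 0.00, 0.40, 0.45, 0.55, 89.1],
    2: [26.6, 0.90, 8.50, 2.60, 0.05, 0.32, 0.40, 0.35, 55.0],
    3: [30.0, 1.00, 9.50, 3.00, 0.45, 0.38, 0.44, 0.66, 70.0],
    4: [33.0, 1.10, 10.0, 3.20, 0.81, 0.37, 0.42, 0.38, 75.0],
    5: [28.0, 0.90, 8.00, 2.50, 0.00, 0.31, 0.38, 0.29, 43.4],
}
_GROUP_TRAIT_SDS = {
    g: [5.0, 0.22, 1.0, 0.35, 0.05, 0.035, 0.05, 0.11, 9.0]
    for g in range(1, 6)
}

#: Band allocation per primer: polymorphic counts follow the published
#: per-primer counts; total bands for SCoT12 (9) and SCoT20 (15) are
#: published, the remaining totals are an invented allocation consistent
#: with the published overall total of 72 bands / 62 polymorphic.
_PRIMER_BAND_PLAN = {
    "SCoT06": (12, 11),  # (bands, polymorphic)
    "SCoT11": (13, 12),
    "SCoT12": (9, 7),
    "SCoT20": (15, 14),
    "SCoT29": (12, 10),
    "SCoT31": (11, 8),
}

_PROFILE_SEED = 20240601  # fixes the band-profile plan inside the config


def reference_survey_config(seed: int = 0) -> SimulationConfig:
    """The default 46-population, 5-group study configuration.

    Loci: ITS 588 bp with 5 planted haplotypes over 5 variable positions,
    psbA 337 bp and matK 1312 bp each splitting groups {1,2,3} vs {4,5}
    (2 resp. 1 variable positions), trnL-F 954 bp invariant.  Bands: 72 loci
    over 6 primers, 62 polymorphic, group profiles drawn once (fixed internal
    seed — part of the plan, not of the study randomness) with all-equal
    columns redrawn so every planned polymorphic locus separates some groups.
    """
    group_sizes = [12, 13, 9, 3, 9]
    trait_means = pd.DataFrame.from_dict(
        _GROUP_TRAIT_MEANS, orient="index", columns=TRAIT_COLUMNS
    )
    trait_sds = pd.DataFrame.from_dict(
        _GROUP_TRAIT_SDS, orient="index", columns=TRAIT_COLUMNS
    )
    loci = [
        LocusPlan(
            "ITS",
            588,
            {
                2: ((101, "C"),),
                3: ((205, "G"),),
                4: ((330, "T"),),
                5: ((412, "C"), (517, "G")),
            },
        ),
        LocusPlan("psbA", 337, {4: ((88, "T"), (210, "C")), 5: ((88, "T"), (210, "C"))}),
        LocusPlan("matK", 1312, {4: ((645, "G"),), 5: ((645, "G"),)}),
        LocusPlan("trnL-F", 954, {}),
    ]
    band_loci: list[str] = []
    primer_of: dict[str, str] = {}
    poly_mask: list[bool] = []
    for primer, (n_bands, n_poly) in _PRIMER_BAND_PLAN.items():
        for b in range(1, n_bands + 1):
            locus = f"{primer}_b{b:02d}"
            band_loci.append(locus)
            primer_of[locus] = primer
            poly_mask.append(b <= n_poly)
    rng = np.random.default_rng(_PROFILE_SEED)
    profiles = np.ones((5, len(band_loci)), dtype=int)
    for j, poly in enumerate(poly_mask):
        if not poly:
            continue
        col = rng.integers(0, 2, size=5)
        while col.min() == col.max():
            col = rng.integers(0, 2, size=5)
        profiles[:, j] = col
    return SimulationConfig(
        group_sizes=group_sizes,
        trait_means=trait_means,
        trait_sds=trait_sds,
        loci=loci,
        band_loci=band_loci,
        band_primer_of=primer_of,
        group_band_profiles=profiles,
        flip_prob=0.02,
        seed=seed,
    )
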