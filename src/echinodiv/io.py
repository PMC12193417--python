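"""Readers and writers for every external representation of the pipeline.

All tabular formats are comma-separated UTF-8 with a mandatory header row and
'.' decimals.  Sequence alignments are plain (optionally line-wrapped) FASTA
and must already be aligned — the package never aligns.  Trees are written as
Newick (see :mod:`echinodiv.trees` for the dialect).  Validation is strict:
every malformed input raises :class:`~echinodiv.errors.ValidationError` naming
the offending row/column.

Coordinates in all reports are 1-based and inclusive, matching GenBank-style
position conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ValidationError
from .trees import Tree

#: The nine quantitative traits: M1 leaf length, M2 leaf width, M3 panicle
#: length, M4 raceme length, M5 awn length, M6 spikelet length (all cm),
#: M7 first-glume/spikelet length ratio (dimensionless), M8 main stem
#: diameter, M9 plant height (cm).
TRAIT_COLUMNS = [f"M{i}" for i in range(1, 10)]

#: Dimensionless ratio trait, constrained to (0, 1].
RATIO_TRAITS = {"M7"}

IUPAC_DNA = set("ACGTNRYSWKMBDHV-")
UNAMBIGUOUS = set("ACGT")


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Population x quantitative-trait matrix (M1..M9).

    ``data`` is indexed by population_id with exactly the columns
    :data:`TRAIT_COLUMNS`, in row order as read.  ``region`` optionally tags
    each population with a sampling region.
    """

    data: pd.DataFrame
    region: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def populations(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_populations(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        self.data.index.name = "population_id"
        if list(self.data.columns) != TRAIT_COLUMNS:
            missing = [c for c in TRAIT_COLUMNS if c not in self.data.columns]
            if missing:
                raise ValidationError(f"missing trait column(s): {', '.join(missing)}")
            raise ValidationError(
                f"unexpected trait columns: {list(self.data.columns)}"
            )
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate population_id: {list(dups)}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = self.data.columns[np.where(~np.isfinite(values))[1][0]]
            raise ValidationError(f"non-finite value in trait column {bad}")
        if (values < 0).any():
            bad = self.data.columns[np.where(values < 0)[1][0]]
            raise ValidationError(f"negative value in trait column {bad}")
        for col in RATIO_TRAITS:
            v = self.data[col]
            if ((v <= 0) | (v > 1)).any():
                row = v[(v <= 0) | (v > 1)].index[0]
                raise ValidationError(
                    f"ratio out of range: {col} must lie in (0, 1], "
                    f"violated at population {row!r}"
                )


def read_trait_table(
    path: str | Path, aggregate: Optional[str] = None
) -> TraitTable:
    """Read a trait CSV with columns population_id, M1..M9 [, region].

    With ``aggregate="mean"`` the file may contain replicate-level rows
    (duplicate population ids); replicates are averaged per population before
    validation.  Without it duplicate ids are an error.
    """
    df = _read_csv(path)
    if "population_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'population_id' column")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing trait column(s): {', '.join(missing)}"
        )
    for col in TRAIT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric cell in column {col}, row {row + 2}"
            )
        df[col] = coerced
    region = None
    if "region" in df.columns:
        region = df.set_index("population_id")["region"]
    body = df.set_index("population_id")[TRAIT_COLUMNS].astype(float)
    if aggregate == "mean":
        order = body.index.unique()
        body = body.groupby(level=0, sort=False).mean().loc[order]
        if region is not None:
            region = region.groupby(level=0, sort=False).first().loc[order]
    elif aggregate is not None:
        raise ValidationError(f"unknown aggregate mode {aggregate!r}")
    return TraitTable(body, region)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    out = table.data.copy()
    if table.region is not None:
        out["region"] = table.region
    out.to_csv(path, index_label="population_id")


# ---------------------------------------------------------------------------
# Locus alignment
# ---------------------------------------------------------------------------


@dataclass
class LocusAlignment:
    """Equal-length aligned DNA sequences for one barcode locus.

    Sample sequences are upper-case IUPAC DNA with '-' gaps.  An optional
    reference accession (excluded from ``ids``) anchors SNP coordinates.
    """

    locus: str
    ids: list[str]
    sequences: dict[str, str]
    reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    def sequence(self, sample_id: str) -> str:
        return self.sequences[sample_id]

    @property
    def reference(self) -> Optional[str]:
        if self.reference_id is None:
            return None
        return self.sequences[self.reference_id]

    def validate(self) -> None:
        if not self.ids:
            raise ValidationError(f"{self.locus}: alignment has no samples")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError(f"{self.locus}: duplicate sample ids")
        every = list(self.ids)
        if self.reference_id is not None:
            if self.reference_id not in self.sequences:
                raise ValidationError(
                    f"{self.locus}: reference {self.reference_id!r} not in records"
                )
            every = every + [self.reference_id]
        lengths = {len(self.sequences[i]) for i in every}
        if len(lengths) != 1:
            raise ValidationError(
                f"{self.locus}: not aligned — sequence lengths {sorted(lengths)}"
            )
        for sid in every:
            bad = set(self.sequences[sid]) - IUPAC_DNA
            if bad:
                raise ValidationError(
                    f"{self.locus}: illegal character(s) {sorted(bad)} in {sid!r}"
                )


def read_alignment(
    path: str | Path, locus: str, reference_id: Optional[str] = None
) -> LocusAlignment:
    """Read an aligned FASTA file; sequences are upper-cased on read."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: empty FASTA file")
    sequences: dict[str, str] = {}
    ids: list[str] = []
    for rec in records:
        if rec.id in sequences:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
        if rec.id != reference_id:
            ids.append(rec.id)
    return LocusAlignment(locus, ids, sequences, reference_id)


def write_alignment(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        order = list(aln.ids)
        if aln.reference_id is not None:
            order = [aln.reference_id] + order
        for sid in order:
            fh.write(f">{sid}\n{aln.sequences[sid]}\n")


# ---------------------------------------------------------------------------
# Band matrix (dominant markers)
# ---------------------------------------------------------------------------


@dataclass
class BandMatrix:
    """Sample x band-locus 0/1 matrix with a locus -> primer map."""

    data: pd.DataFrame  # index sample_id, columns locus names, values 0/1
    primer_of: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    @property
    def primers(self) -> list[str]:
        seen: dict[str, None] = {}
        for locus in self.loci:
            seen.setdefault(self.primer_of[locus], None)
        return list(seen)

    def loci_of(self, primer: str) -> list[str]:
        return [l for l in self.loci if self.primer_of[l] == primer]

    def validate(self) -> None:
        self.data.index.name = "sample_id"
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample_id: {list(dups)}")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            r, c = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValidationError(
                f"band cell not 0/1 at sample {self.data.index[r]!r}, "
                f"locus {self.data.columns[c]!r}"
            )
        unmapped = [l for l in self.loci if l not in self.primer_of]
        if unmapped:
            raise ValidationError(f"loci missing from primer map: {unmapped}")


def read_band_matrix(path: str | Path, primer_map: str | Path) -> BandMatrix:
    """Read the 0/1 band matrix plus its locus -> primer map."""
    df = _read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'sample_id' column")
    body = df.set_index("sample_id")
    for col in body.columns:
        coerced = pd.to_numeric(body[col], errors="coerce")
        if coerced.isna().any():
            raise ValidationError(f"{path}: non-numeric cell in locus {col!r}")
        body[col] = coerced.astype(int)
    pm = _read_csv(primer_map)
    for col in ("locus", "primer"):
        if col not in pm.columns:
            raise ValidationError(f"{primer_map}: missing '{col}' column")
    if pm["locus"].duplicated().any():
        raise ValidationError(f"{primer_map}: a locus maps to more than one primer")
    mapping = dict(zip(pm["locus"], pm["primer"]))
    return BandMatrix(body, mapping)


def write_band_matrix(m: BandMatrix, path: str | Path, primer_map: str | Path) -> None:
    m.data.to_csv(path, index_label="sample_id")
    pd.DataFrame(
        {"locus": m.loci, "primer": [m.primer_of[l] for l in m.loci]}
    ).to_csv(primer_map, index=False)


# ---------------------------------------------------------------------------
# Resistance table
# ---------------------------------------------------------------------------


@dataclass
class ResistanceTable:
    """Long-format population x herbicide inhibition percentages.

    ``data`` has columns population_id, herbicide, inhibition (percent in
    [0, 100]).  Fresh-weight inputs are converted on read.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def herbicides(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.data["herbicide"]:
            seen.setdefault(h, None)
        return list(seen)

    def wide(self) -> pd.DataFrame:
        """Population x herbicide inhibition matrix, first-appearance order."""
        pops = list(dict.fromkeys(self.data["population_id"]))
        return (
            self.data.pivot(
                index="population_id", columns="herbicide", values="inhibition"
            )
            .loc[pops, self.herbicides]
        )

    def validate(self) -> None:
        for col in ("population_id", "herbicide", "inhibition"):
            if col not in self.data.columns:
                raise ValidationError(f"resistance table missing column '{col}'")
        v = self.data["inhibition"]
        if ((v < 0) | (v > 100)).any() or v.isna().any():
            raise ValidationError("inhibition must lie in [0, 100]")
        if self.data.duplicated(["population_id", "herbicide"]).any():
            raise ValidationError("duplicate (population, herbicide) rows")


def read_resistance_table(path: str | Path) -> ResistanceTable:
    """Read inhibition percentages, or treated/control fresh weights (g).

    Accepts either columns (population_id, herbicide, inhibition) or
    (population_id, herbicide, treated_fw, control_fw); the latter is
    converted via :func:`echinodiv.resistance.inhibition_rate`.
    """
    from .resistance import inhibition_rate

    df = _read_csv(path)
    for col in ("population_id", "herbicide"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing '{col}' column")
    if "inhibition" in df.columns:
        df["inhibition"] = pd.to_numeric(df["inhibition"], errors="raise")
        return ResistanceTable(df[["population_id", "herbicide", "inhibition"]])
    if {"treated_fw", "control_fw"} <= set(df.columns):
        inhib = [
            inhibition_rate(float(t), float(c))
            for t, c in zip(df["treated_fw"], df["control_fw"])
        ]
        out = df[["population_id", "herbicide"]].copy()
        out["inhibition"] = inhib
        return ResistanceTable(out)
    raise ValidationError(
        f"{path}: need either 'inhibition' or 'treated_fw'+'control_fw' columns"
    )


# ---------------------------------------------------------------------------
# Trees and cluster tables
# ---------------------------------------------------------------------------


def write_newick(tree: Tree, path: str | Path) -> None:
    """Write a tree as Newick; re-reading reproduces topology, branch lengths
    (to 6 decimals) and integer supports."""
    tree.validate()
    Path(path).write_text(tree.to_newick() + "\n")


def write_assignment(assignment, path: str | Path) -> None:
    """Write a ClusterAssignment as a two-column CSV."""
    pd.DataFrame(
        {"sample_id": assignment.ids, "cluster": assignment.labels}
    ).to_csv(path, index=False)


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc
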