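"""Dominant-marker (SCoT-style 0/1 band) diversity analysis.

A band locus is polymorphic when both presence and absence occur among the
scored samples.  Informativeness of a dominant locus with band frequency p is
measured by PIC = 1 - p^2 - (1-p)^2, the two-class form of 1 - sum(p_i^2)
(maximum 0.5 at p = 0.5 — a dominant band cannot distinguish heterozygotes).
Primer-level summaries report band counts, polymorphic counts, mean band
frequency and mean PIC over polymorphic loci (monomorphic loci contribute
PIC 0 and are excluded by default; switchable).

Sample relatedness uses the Simple Matching coefficient over all scored
loci, SM(a, b) = (# loci where the 0/1 profiles agree) / (# loci), counting
shared absences; 1 - SM is a scaled Hamming distance.  Clustering is UPGMA
on 1 - SM, cut at a dissimilarity threshold into integer-labelled groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import (
    ClusterAssignment,
    Dendrogram,
    cut_dendrogram,
    upgma_dendrogram,
)
from .errors import ValidationError
from .io import BandMatrix


@dataclass
class SimilarityMatrix:
    """Symmetric sample x sample similarity in [0, 1] (SM coefficient)."""

    ids: list[str]
    matrix: np.ndarray
    coefficient: str = "SM"

    def validate(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("similarity matrix shape mismatch")
        if np.max(np.abs(m - m.T)) > 1e-12:
            raise ValidationError("similarity matrix not symmetric")
        if np.any((m < 0) | (m > 1)):
            raise ValidationError("similarities must lie in [0, 1]")
        if np.max(np.abs(np.diag(m) - 1)) > 1e-12:
            raise ValidationError("self-similarity must be 1")

    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.matrix


def polymorphic_loci(m: BandMatrix) -> tuple[pd.Series, float, pd.Series]:
    """Locus polymorphism mask, overall rate (%) and per-primer rates (%)."""
    if len(m.samples) < 2:
        raise ValidationError("need at least 2 samples")
    cols = m.data.to_numpy()
    mask = pd.Series(
        (cols.min(axis=0) == 0) & (cols.max(axis=0) == 1), index=m.loci
    )
    overall = polymorphism_rate(int(mask.sum()), len(m.loci))
    per_primer = pd.Series(
        {
            primer: polymorphism_rate(
                int(mask[m.loci_of(primer)].sum()), len(m.loci_of(primer))
            )
            for primer in m.primers
        }
    )
    return mask, overall, per_primer


def polymorphism_rate(n_polymorphic: int, n_loci: int) -> float:
    """Percentage of polymorphic loci, 100 * n_polymorphic / n_loci."""
    if n_loci <= 0:
        raise ValidationError("n_loci must be positive")
    if not 0 <= n_polymorphic <= n_loci:
        raise ValidationError("0 <= n_polymorphic <= n_loci required")
    return 100.0 * n_polymorphic / n_loci


def pic_locus(p: float) -> float:
    """PIC of a dominant band locus with presence frequency p.

    The two observable allele classes of a dominant marker are band presence
    (p) and absence (1-p): PIC = 1 - p^2 - (1-p)^2.  Symmetric in p <-> 1-p,
    zero for monomorphic loci, maximal 0.5 at p = 0.5.
    """
    if not 0 <= p <= 1:
        raise ValidationError(f"band frequency {p} outside [0, 1]")
    return 1.0 - p**2 - (1.0 - p) ** 2


def primer_summary(
    m: BandMatrix, include_monomorphic: bool = False
) -> pd.DataFrame:
    """Per-primer band counts, polymorphism, mean band frequency and PIC.

    PIC per primer is the mean of per-locus PIC over its polymorphic loci
    (over all loci with ``include_monomorphic=True``).  Appends ``Mean`` and
    ``Total`` rows: Mean averages the numeric columns, Total sums the counts.
    """
    mask, _, _ = polymorphic_loci(m)
    freqs = m.data.mean(axis=0)
    rows = {}
    for primer in m.primers:
        loci = m.loci_of(primer)
        if not loci:
            continue
        poly = [l for l in loci if mask[l]]
        pic_loci = loci if include_monomorphic else poly
        pic = (
            float(np.mean([pic_locus(freqs[l]) for l in pic_loci]))
            if pic_loci
            else 0.0
        )
        rows[primer] = {
            "n_bands": len(loci),
            "n_polymorphic": len(poly),
            "polymorphism_rate": polymorphism_rate(len(poly), len(loci)),
            "mean_band_frequency": float(freqs[loci].mean()),
            "PIC": pic,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    mean_row = out.mean()
    total_row = pd.Series(
        {
            "n_bands": out["n_bands"].sum(),
            "n_polymorphic": out["n_polymorphic"].sum(),
            "polymorphism_rate": polymorphism_rate(
                int(out["n_polymorphic"].sum()), int(out["n_bands"].sum())
            ),
            "mean_band_frequency": np.nan,
            "PIC": np.nan,
        }
    )
    out.loc["Mean"] = mean_row
    out.loc["Total"] = total_row
    return out


def sm_similarity(m: BandMatrix) -> SimilarityMatrix:
    """Simple Matching similarity over all scored loci (1-1 and 0-0 agree)."""
    if len(m.samples) < 2:
        raise ValidationError("need at least 2 samples")
    x = m.data.to_numpy(dtype=int)
    n = x.shape[0]
    agree = np.zeros((n, n))
    for i in range(n):
        agree[i] = (x == x[i]).sum(axis=1)
    sm = agree / x.shape[1]
    np.fill_diagonal(sm, 1.0)
    out = SimilarityMatrix(list(m.samples), sm)
    out.validate()
    return out


def scot_cluster(
    s: SimilarityMatrix, threshold: float
) -> tuple[Dendrogram, ClusterAssignment]:
    """UPGMA on 1 - SM, cut at a dissimilarity threshold.

    Labels 1..k by first appearance in sample order; a threshold of 1.0 (or
    anything above the root height) yields a single cluster.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError("dissimilarity threshold must lie in [0, 1]")
    dend = upgma_dendrogram(s.dissimilarity(), s.ids)
    # threshold 1.0 must merge everything even if the root sits exactly at 1
    cut_at = np.nextafter(threshold, np.inf) if threshold == 1.0 else threshold
    assignment = cut_dendrogram(dend, cut_at)
    return dend, assignment
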