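"""Agglomerative clustering shared by the trait and dominant-marker stages.

Wraps :func:`scipy.cluster.hierarchy.linkage` in a :class:`Dendrogram` whose
merge heights are on the scale each linkage naturally defines:

* Ward: cumulative squared-Euclidean (minimum-variance) merge cost, i.e. the
  Lance-Williams recurrence applied to squared Euclidean distances;
* UPGMA (average linkage): arithmetic-average dissimilarity, which for the
  1 - simple-matching input used by the dominant-marker stage stays in [0, 1].

An optional proportional rescaling of heights onto a 0-25 axis mimics the
SPSS dendrogram axis on which published trait-cluster cut values (e.g. 15.0)
are expressed; it is monotone and zero-preserving, so cut semantics are
unchanged.  Cutting keeps every merge *strictly below* the threshold and
labels groups 1..k by first appearance in leaf (input row) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError

SPSS_AXIS_MAX = 25.0


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` is a scipy-style (n-1, 4) array: row i merges clusters with
    ids ``merges[i, 0]`` and ``merges[i, 1]`` (ids < n are leaves, id n+i is
    the cluster formed at row i) at height ``merges[i, 2]`` into a cluster of
    size ``merges[i, 3]``.
    """

    merges: np.ndarray
    labels: list[str]
    method: str
    rescaled: bool = False

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def validate(self) -> None:
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValidationError("merge list must have n-1 rows for n leaves")
        if np.any(np.diff(self.heights) < -1e-9):
            raise ValidationError(f"{self.method} merge heights must be non-decreasing")

    def rescale_spss(self) -> "Dendrogram":
        """Proportionally map heights onto [0, 25] (max height -> 25)."""
        top = self.heights.max()
        if top <= 0:
            scaled = self.merges.copy()
        else:
            scaled = self.merges.copy()
            scaled[:, 2] = SPSS_AXIS_MAX * scaled[:, 2] / top
        return Dendrogram(scaled, list(self.labels), self.method, rescaled=True)

    def cophenetic(self) -> np.ndarray:
        """Cophenetic distance matrix (height at which two leaves merge)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for row, (a, b, h, _) in enumerate(self.merges):
            left, right = members.pop(int(a)), members.pop(int(b))
            for i in left:
                for j in right:
                    out[i, j] = out[j, i] = h
            members[n + row] = left + right
        return out


@dataclass
class ClusterAssignment:
    """Sample -> integer cluster label (1..k) for one marker system."""

    ids: list[str]
    labels: np.ndarray
    method: str
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(self.labels):
            raise ValidationError("one label per sample required")
        uniq = np.unique(self.labels)
        if len(uniq) == 0 or uniq[0] != 1 or uniq[-1] != len(uniq):
            raise ValidationError("labels must be consecutive integers from 1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.ids, self.labels) if l == label]

    def as_partition(self) -> frozenset[frozenset]:
        return frozenset(
            frozenset(self.members(k)) for k in range(1, self.n_clusters + 1)
        )


def first_appearance_labels(raw: Sequence) -> np.ndarray:
    """Relabel arbitrary group keys as 1..k by first appearance order."""
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, key in enumerate(raw):
        if key not in mapping:
            mapping[key] = len(mapping) + 1
        out[i] = mapping[key]
    return out


def ward_dendrogram(z: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """Ward minimum-variance dendrogram over Euclidean row distances.

    Heights are the Lance-Williams merge costs on squared Euclidean
    distances (scipy's Euclidean-scale heights, squared).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(z).all():
        raise ValidationError("NaN/inf in clustering input")
    merges = linkage(z, method="ward", metric="euclidean")
    merges = merges.copy()
    merges[:, 2] = merges[:, 2] ** 2
    d = Dendrogram(merges, list(labels), "ward")
    d.validate()
    return d


def upgma_dendrogram(dissimilarity: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """UPGMA (average-linkage SAHN) dendrogram from a square dissimilarity."""
    dmat = np.asarray(dissimilarity, dtype=float)
    if dmat.shape[0] != dmat.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.isfinite(dmat).all():
        raise ValidationError("NaN/inf in dissimilarity matrix")
    merges = linkage(squareform(dmat, checks=False), method="average")
    d = Dendrogram(merges, list(labels), "upgma")
    d.validate()
    return d


def cut_dendrogram(d: Dendrogram, threshold: float) -> ClusterAssignment:
    """Cut at ``threshold``: merges with height strictly below it survive.

    Labels 1..k are assigned by first appearance in leaf order, so the
    assignment is deterministic for a given input row order.
    """
    if threshold < 0:
        raise ValidationError("cut threshold must be >= 0")
    n = d.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row, (a, b, h, _) in enumerate(d.merges):
        if h < threshold:
            new = n + row
            parent[find(int(a))] = new
            parent[find(int(b))] = new
    roots = [find(i) for i in range(n)]
    return ClusterAssignment(
        list(d.labels), first_appearance_labels(roots), d.method, threshold
    )


def cut_dendrogram_k(d: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into exactly ``k`` clusters (threshold between merge heights)."""
    if not 1 <= k <= d.n_leaves:
        raise ValidationError(f"k must be in 1..{d.n_leaves}")
    if k == d.n_leaves:
        return cut_dendrogram(d, 0.0)
    # keep the first n-k merges: threshold just above merge n-k-1
    h = d.heights
    thr = np.nextafter(h[d.n_leaves - k - 1], np.inf)
    out = cut_dendrogram(d, thr)
    return ClusterAssignment(out.ids, out.labels, d.method, float(thr))
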