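"""DNA-barcode analysis: variable sites, haplotypes, K2P distances, NJ trees.

Variable sites are alignment columns where at least two distinct unambiguous
bases (A/C/G/T) occur among the samples; gaps, N and ambiguity codes are
ignored at that column.  Samples sharing identical states across all variable
sites form a haplotype group — the unit of barcode-based classification.
When a reference accession is attached to the alignment, site positions are
reported in the reference's ungapped 1-based coordinates (GenBank style);
otherwise in 1-based alignment columns.

Pairwise distances use the Kimura 2-parameter model,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with transition proportion P and transversion proportion Q counted over
sites where both sequences carry unambiguous bases (pairwise deletion).
Saturated pairs (a log argument <= 0) are flagged undefined rather than
clamped; tree building refuses matrices containing them.

Trees come from Saitou-Nei neighbor joining with a deterministic
lexicographic tie-break; negative branch lengths are clamped to zero with
the deficit moved to the sibling edge, preserving the pair's summed length.
Bootstrap support for each internal bipartition of the original NJ topology
is the percentage of column-resampled replicates whose NJ tree contains it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cluster import ClusterAssignment, first_appearance_labels
from .errors import SaturationError, ValidationError
from .io import LocusAlignment, UNAMBIGUOUS
from .trees import Node, Tree

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


# ---------------------------------------------------------------------------
# Variable sites and haplotypes
# ---------------------------------------------------------------------------


@dataclass
class SnpProfile:
    """Variable positions of one locus plus per-sample states.

    ``positions`` are 1-based (reference coordinates when the alignment has a
    reference, else alignment columns).  ``states[sid]`` is the tuple of
    bases a sample shows at those positions; ``haplotype[sid]`` numbers the
    equivalence classes of identical state vectors 1..k by first appearance.
    """

    locus: str
    positions: list[int]
    states: dict[str, tuple[str, ...]]
    haplotype: dict[str, int]

    @property
    def n_haplotypes(self) -> int:
        return max(self.haplotype.values()) if self.haplotype else 0


def _reference_coordinates(aln: LocusAlignment, columns: list[int]) -> list[int]:
    """Map 0-based alignment columns to 1-based ungapped reference positions."""
    ref = aln.reference
    pos_map = {}
    pos = 0
    for col, base in enumerate(ref):
        if base != "-":
            pos += 1
        pos_map[col] = pos  # position of the last reference base at/before col
    return [pos_map[c] for c in columns]


def variable_sites(aln: LocusAlignment) -> SnpProfile:
    """Find columns with >= 2 distinct unambiguous bases among samples."""
    if aln.n_samples < 2:
        raise ValidationError("need at least 2 samples to find variable sites")
    seqs = [aln.sequences[sid] for sid in aln.ids]
    columns = []
    for col in range(aln.length):
        bases = {s[col] for s in seqs} & UNAMBIGUOUS
        if len(bases) >= 2:
            columns.append(col)
    if aln.reference_id is not None:
        positions = _reference_coordinates(aln, columns)
    else:
        positions = [c + 1 for c in columns]
    states = {
        sid: tuple(aln.sequences[sid][c] for c in columns) for sid in aln.ids
    }
    hap_labels = first_appearance_labels([states[sid] for sid in aln.ids])
    haplotype = dict(zip(aln.ids, (int(h) for h in hap_labels)))
    return SnpProfile(aln.locus, positions, states, haplotype)


def barcode_cluster(aln: LocusAlignment) -> ClusterAssignment:
    """Group samples by haplotype identity; labels 1..k by first appearance."""
    profile = variable_sites(aln)
    labels = np.array([profile.haplotype[sid] for sid in aln.ids])
    return ClusterAssignment(list(aln.ids), labels, aln.locus)


def concatenate_barcodes(alns: Sequence[LocusAlignment]) -> LocusAlignment:
    """Concatenate loci per sample, in the given order.

    Sample sets must match exactly across loci.  Locus boundaries (1-based,
    inclusive) are recorded on the result as ``.boundaries``.
    """
    if not alns:
        raise ValidationError("no alignments to concatenate")
    base_ids = set(alns[0].ids)
    for aln in alns[1:]:
        if set(aln.ids) != base_ids:
            diff = set(aln.ids) ^ base_ids
            raise ValidationError(
                f"sample sets differ between loci (mismatch: {sorted(diff)})"
            )
    order = list(alns[0].ids)
    sequences = {
        sid: "".join(aln.sequences[sid] for aln in alns) for sid in order
    }
    combined = LocusAlignment(
        "+".join(a.locus for a in alns), order, sequences, None
    )
    boundaries = {}
    start = 1
    for aln in alns:
        boundaries[aln.locus] = (start, start + aln.length - 1)
        start += aln.length
    combined.boundaries = boundaries
    return combined


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------


@dataclass
class PairwiseSiteCounts:
    """Comparable sites and transition/transversion proportions for a pair."""

    sites: int
    P: float  # transition proportion
    Q: float  # transversion proportion


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str = "K2P"
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape mismatch")
        if np.nanmax(np.abs(m - m.T)) > 1e-12:
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal must be zero")


def site_counts(a: str, b: str) -> PairwiseSiteCounts:
    """Count transitions/transversions over pairwise-deleted sites."""
    if len(a) != len(b):
        raise ValidationError("sequences differ in length")
    sites = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in UNAMBIGUOUS or y not in UNAMBIGUOUS:
            continue
        sites += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValidationError("no comparable sites after pairwise deletion")
    return PairwiseSiteCounts(sites, transitions / sites, transversions / sites)


def k2p_distance(a: str, b: str) -> tuple[float, PairwiseSiteCounts]:
    """Kimura 2-parameter distance; raises SaturationError when undefined."""
    counts = site_counts(a, b)
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined (saturation): P={counts.P:.4f}, Q={counts.Q:.4f}"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d, counts


def k2p_matrix(aln: LocusAlignment) -> DistanceMatrix:
    """All pairwise K2P distances; saturated pairs flagged as undefined NaN."""
    n = aln.n_samples
    m = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d, _ = k2p_distance(
                    aln.sequences[aln.ids[i]], aln.sequences[aln.ids[j]]
                )
            except SaturationError:
                d = np.nan
                undefined.append((aln.ids[i], aln.ids[j]))
            m[i, j] = m[j, i] = d
    out = DistanceMatrix(list(aln.ids), m, "K2P", undefined)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root).

    Among minimal Q-criterion pairs the lexicographically smallest (i, j) by
    current node index is joined, making the output deterministic.
    """
    if d.undefined:
        raise ValidationError(
            f"distance matrix contains undefined pairs: {d.undefined}"
        )
    n = len(d.ids)
    if n < 3:
        raise ValidationError("need at least 3 samples for NJ")
    if not np.isfinite(d.matrix).all():
        raise ValidationError("non-finite distances")

    # active nodes keyed by creation index; distances in a dict-of-dicts
    nodes: dict[int, Node] = {
        i: Node(name=d.ids[i]) for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.matrix[i, j])
    active = list(range(n))
    next_id = n

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        r = len(active)
        totals = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * get(i, j) - totals[i] - totals[j]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best is None or (i, j) < best)
                ):
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        new = Node(children=[nodes[i], nodes[j]])
        nodes[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(k, next_id)] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # join the final three around a trifurcating root
    i, j, k = active
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    li, lj = _clamp_pair(li, lj)
    lk = max(lk, 0.0)
    nodes[i].length = li
    nodes[j].length = lj
    nodes[k].length = lk
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    tree = Tree(root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _resample_alignment(aln: LocusAlignment, rng: np.random.Generator) -> LocusAlignment:
    cols = rng.integers(0, aln.length, size=aln.length)
    sequences = {
        sid: "".join(aln.sequences[sid][c] for c in cols) for sid in aln.ids
    }
    return LocusAlignment(aln.locus, list(aln.ids), sequences, None)


def bootstrap_support(
    aln: LocusAlignment, replicates: int = 1000, seed: int = 0
) -> Tree:
    """NJ tree with bootstrap supports on its internal bipartitions.

    Columns are resampled with replacement; replicate r draws from the
    deterministic substream ``default_rng([seed, r])``, so supports are
    reproducible and adding replicates never perturbs earlier ones.
    Replicates whose K2P matrix contains saturated pairs are skipped and the
    support denominator reduced accordingly.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    tree = nj_tree(k2p_matrix(aln))
    if aln.n_samples < 4:
        return tree  # no non-trivial bipartitions: supports undefined
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    valid = 0
    for r in range(replicates):
        rng = np.random.default_rng([seed, r])
        boot = _resample_alignment(aln, rng)
        dmat = k2p_matrix(boot)
        if dmat.undefined:
            continue
        rep_splits = set(nj_tree(dmat).bipartitions())
        valid += 1
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    if valid == 0:
        raise ValidationError("all bootstrap replicates were saturated")
    for split, node in splits.items():
        node.support = int(round(100.0 * counts[split] / valid))
    return tree
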