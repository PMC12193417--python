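import numpy as np
import pandas as pd
import pytest

from echinodiv.io import TRAIT_COLUMNS, BandMatrix, TraitTable
from echinodiv.synth import reference_survey_config, simulate_study


@pytest.fixture(scope="session")
def study():
    """One survey-scale synthetic study shared across tests (seed 0)."""
    return simulate_study(reference_survey_config(seed=0))


@pytest.fixture()
def small_trait_table():
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.uniform(0.5, 10, size=(6, 9)), columns=TRAIT_COLUMNS,
        index=[f"P{i}" for i in range(6)],
    )
    data["M7"] = rng.uniform(0.3, 0.6, size=6)
    return TraitTable(data)


@pytest.fixture()
def tiny_band_matrix():
    data = pd.DataFrame(
        [[1, 0, 1, 1, 0], [1, 0, 0, 1, 1], [1, 1, 0, 0, 1]],
        index=["S1", "S2", "S3"],
        columns=[f"L{i}" for i in range(1, 6)],
    )
    primer_of = {f"L{i}": "PrA" if i <= 3 else "PrB" for i in range(1, 6)}
    return BandMatrix(data, primer_of)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def naive_lance_williams(dist2: np.ndarray, method: str) -> list[float]:
    """Naive agglomeration via the Lance-Williams recurrence.

    ``method='ward'`` operates on squared Euclidean distances with the Ward
    coefficients; ``method='average'`` on plain dissimilarities with UPGMA
    coefficients.  Returns the sorted merge heights.
    """
    d = {
        (i, j): dist2[i, j]
        for i in range(len(dist2))
        for j in range(i + 1, len(dist2))
    }
    sizes = {i: 1 for i in range(len(dist2))}
    heights = []
    next_id = len(dist2)
    while len(sizes) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        ni, nj = sizes.pop(i), sizes.pop(j)
        new = {}
        for k in sizes:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            if method == "ward":
                nk = sizes[k]
                t = ni + nj + nk
                new[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / t
            else:
                new[k] = (ni * dik + nj * djk) / (ni + nj)
        d.pop((i, j))
        for k, v in new.items():
            d[(min(k, next_id), max(k, next_id))] = v
        sizes[next_id] = ni + nj
        next_id += 1
    return sorted(heights)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths and its leaf distances.

    Returns (names, distance matrix, set of non-trivial bipartitions keyed
    like Tree.bipartitions()).
    """
    names = [chr(ord("A") + i) for i in range(n_leaves)]
    # grow by random edge subdivision: start from a 3-leaf star
    # represent as adjacency dict node -> {neighbor: length}
    adj = {"A": {}, "B": {}, "C": {}, "x0": {}}
    for leaf in ("A", "B", "C"):
        w = float(rng.uniform(0.5, 2.0))
        adj["x0"][leaf] = w
        adj[leaf]["x0"] = w
    internal = 1
    for leaf in names[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        mid = f"x{internal}"
        internal += 1
        s = float(rng.uniform(0.2, 0.8)) * w
        adj[mid] = {a: s, b: w - s}
        adj[a][mid] = s
        adj[b][mid] = w - s
        wl = float(rng.uniform(0.5, 2.0))
        adj[mid][leaf] = wl
        adj[leaf] = {mid: wl}

    # all-pairs path lengths by BFS over the tree
    import heapq

    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    m = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(names):
        da = dist_from(a)
        for j, b in enumerate(names):
            m[i, j] = da[b]
    m = (m + m.T) / 2  # exact symmetry despite float summation order

    # bipartitions: removing each internal-internal edge splits the leaves
    leafset = frozenset(names)
    anchor = min(leafset)
    splits = set()
    for a in adj:
        for b in adj[a]:
            if a.startswith("x") and b.startswith("x") and a < b:
                # side of b when edge (a,b) removed
                seen = {a, b}
                stack = [b]
                side = set()
                while stack:
                    u = stack.pop()
                    for v in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                            if not v.startswith("x"):
                                side.add(v)
                side = frozenset(side)
                if anchor in side:
                    side = leafset - side
                if len(side) >= 2 and len(leafset - side) >= 2:
                    splits.add(side)
    return names, m, splits
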