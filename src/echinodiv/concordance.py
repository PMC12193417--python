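"""Cross-marker concordance of cluster assignments.

Each marker system (morphological traits, ITS barcode, SCoT bands, ...)
yields integer cluster labels per population.  Encoding every method's
labels in one shared sample order, pairwise Pearson correlation with
two-sided t-distribution p-values (n-2 df) measures how far the
classifications agree.

Pearson-on-labels is deliberately label-numbering sensitive (labels follow
each method's own first-appearance order), so the module also reports a
relabeling-maximized Pearson — the maximum r over all permutations of one
method's label values — as a robustness diagnostic.  The raw value stays the
primary statistic; the diagnostic is always >= it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterAssignment
from .errors import ValidationError

MAX_RELABEL_CLASSES = 8  # 8! = 40320 permutations; beyond this refuse


@dataclass
class ConcordanceResult:
    methods: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def significance_flags(self) -> pd.DataFrame:
        flags = self.p.map(
            lambda v: "**" if v <= 0.01 else "*" if v <= 0.05 else ""
        )
        np.fill_diagonal(flags.values, "")
        return flags

    def table(self) -> pd.DataFrame:
        """Upper triangle r, lower triangle p — the conventional layout."""
        out = pd.DataFrame("", index=self.methods, columns=self.methods)
        for i, a in enumerate(self.methods):
            for j, b in enumerate(self.methods):
                if i < j:
                    out.loc[a, b] = f"{self.r.loc[a, b]:.2f}"
                elif i > j:
                    out.loc[a, b] = f"{self.p.loc[a, b]:.3f}"
                else:
                    out.loc[a, b] = "\\"
        return out


def encode_labels(
    assignment: ClusterAssignment, sample_order: Sequence[str]
) -> np.ndarray:
    """Labels of one method re-ordered into the shared sample order."""
    lookup = dict(zip(assignment.ids, assignment.labels))
    missing = [s for s in sample_order if s not in lookup]
    extra = set(assignment.ids) - set(sample_order)
    if missing or extra:
        raise ValidationError(
            f"sample-order mismatch: missing {missing}, extra {sorted(extra)}"
        )
    return np.array([lookup[s] for s in sample_order], dtype=int)


def pearson_concordance(vectors: dict[str, np.ndarray]) -> ConcordanceResult:
    """Pairwise Pearson r and two-sided p among method label vectors.

    Constant vectors make r undefined for their pairs; those entries are
    reported as NaN.
    """
    methods = list(vectors)
    if len(methods) < 2:
        raise ValidationError("need at least 2 methods")
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValidationError("label vectors differ in length")
    n = lengths.pop()
    if n < 3:
        raise ValidationError("need at least 3 samples")
    r = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    p = pd.DataFrame(np.zeros((len(methods), len(methods))), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for j in range(i + 1, len(methods)):
            b = methods[j]
            x = np.asarray(vectors[a], dtype=float)
            y = np.asarray(vectors[b], dtype=float)
            if x.std() == 0 or y.std() == 0:
                rv = pv = np.nan
            else:
                rv, pv = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return ConcordanceResult(methods, r, p, n)


def relabel_maximized_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Maximum Pearson r over permutations of b's label values.

    Diagnostic bounding the effect of the arbitrary label numbering; always
    >= the raw r of (a, b).  Exhaustive over k! permutations, refused for
    more than 8 classes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=int)
    classes = sorted(set(b.tolist()))
    if len(classes) > MAX_RELABEL_CLASSES:
        raise ValidationError(
            f"too many classes ({len(classes)}) for exhaustive relabeling"
        )
    if a.std() == 0:
        raise ValidationError("constant vector: r undefined")
    best = -1.0
    for perm in permutations(classes):
        remap = dict(zip(classes, perm))
        y = np.array([remap[v] for v in b], dtype=float)
        if y.std() == 0:
            continue
        r, _ = stats.pearsonr(a, y)
        best = max(best, float(r))
    return best
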