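"""Partition-agreement and cluster-quality metrics.

Small self-contained implementations (adjusted Rand index, mean silhouette)
so the pipeline's tuning criterion has no dependency beyond numpy/scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (1.0 = identical
    up to renaming, ~0 for independent labelings)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # degenerate: both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def mean_silhouette(points, labels) -> float:
    """Mean silhouette coefficient over all points, Euclidean metric.

    Requires at least 2 clusters; singleton-cluster points score 0 by
    convention.
    """
    X = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    masks = {u: lab == u for u in uniq}
    sizes = {u: int(masks[u].sum()) for u in uniq}
    s = np.zeros(n)
    for u in uniq:
        m = masks[u]
        if sizes[u] == 1:
            s[m] = 0.0
            continue
        intra = D[np.ix_(m, m)].sum(axis=1) / (sizes[u] - 1)
        inter = np.full(sizes[u], np.inf)
        for v in uniq:
            if v == u:
                continue
            inter = np.minimum(inter, D[np.ix_(m, masks[v])].mean(axis=1))
        denom = np.maximum(intra, inter)
        with np.errstate(invalid="ignore"):
            sil = np.where(denom > 0, (inter - intra) / denom, 0.0)
        s[m] = sil
    return float(s.mean())
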