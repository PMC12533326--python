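"""Clustering agreement metrics (ARI, NMI)."""

from __future__ import annotations

import numpy as np
from sklearn import metrics as _skm

__all__ = ["adjusted_rand_index", "normalized_mutual_information"]


def _check_pair(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty label vectors")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Permutation-model-adjusted Rand index between two partitions.

    Ranges over [-1, 1]; 1 means identical partitions, 0 is the chance
    level under random labelings with the same cluster sizes.
    """
    a, b = _check_pair(a, b)
    return float(_skm.adjusted_rand_score(a, b))


def normalized_mutual_information(a, b, average_method: str = "arithmetic") -> float:
    """Mutual information between two partitions normalized by the
    ``average_method`` ("arithmetic" by default; also "min", "geometric",
    "max") of their entropies.  Ranges over [0, 1]; 1 means identical
    partitions.
    """
    a, b = _check_pair(a, b)
    return float(_skm.normalized_mutual_info_score(a, b, average_method=average_method))
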