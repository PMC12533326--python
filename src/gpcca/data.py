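"""Multi-modal dataset container.

A dataset is an ordered collection of feature-by-sample matrices (one per
modality) measured on the same samples, together with a binary observation
mask over the stacked feature space.  Missing entries are carried as NaN in
the data and as 0 in the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultiModalDataset"]


@dataclass
class MultiModalDataset:
    """Ordered feature-by-sample matrices over shared samples.

    Parameters
    ----------
    modalities
        List of ``(m_r, n)`` float arrays sharing the same sample columns.
        Missing entries are NaN (alternatively supply an explicit ``mask``).
    sample_ids
        Optional length-``n`` identifiers (defaults to ``s1..sn``).
    feature_ids
        Optional per-modality feature identifier lists.
    mask
        Optional explicit ``(m, n)`` binary observation indicator over the
        stacked rows (modalities stacked in declared order).  When omitted it
        is derived from NaN positions.
    """

    modalities: list
    sample_ids: list = None
    feature_ids: list = None
    mask: np.ndarray = None

    # derived, filled in __post_init__
    X: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.modalities) < 1:
            raise ValueError("at least one modality is required")
        mods = [np.asarray(M, dtype=float) for M in self.modalities]
        for r, M in enumerate(mods):
            if M.ndim != 2:
                raise ValueError(f"modality {r} is not a 2-D matrix")
            if M.shape[0] < 1:
                raise ValueError(f"modality {r} has no features")
        n = mods[0].shape[1]
        for r, M in enumerate(mods):
            if M.shape[1] != n:
                raise ValueError(
                    f"modality {r} has {M.shape[1]} samples, expected {n} "
                    "(all modalities must share the same sample columns)"
                )
        self.modalities = mods
        X = np.vstack(mods)
        if self.mask is None:
            mask = ~np.isnan(X)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != X.shape:
                raise ValueError(f"mask shape {mask.shape} != data shape {X.shape}")
            if np.isnan(X[mask]).any():
                raise ValueError("mask marks NaN entries as observed")
        if not np.isfinite(X[mask]).all():
            raise ValueError("non-finite observed values in data")
        empty = ~mask.any(axis=0)
        if empty.any():
            bad = np.flatnonzero(empty)[:5].tolist()
            raise ValueError(
                f"samples with no observed entries in any modality: columns {bad}"
            )
        X = np.where(mask, X, np.nan)
        self.X = X
        self.mask = mask
        if self.sample_ids is None:
            self.sample_ids = [f"s{j + 1}" for j in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if self.feature_ids is None:
            self.feature_ids = [
                [f"m{r + 1}_f{i + 1}" for i in range(M.shape[0])]
                for r, M in enumerate(mods)
            ]
        else:
            if len(self.feature_ids) != len(mods) or any(
                len(f) != M.shape[0] for f, M in zip(self.feature_ids, mods)
            ):
                raise ValueError("feature_ids do not match modality shapes")

    # ---- basic geometry -------------------------------------------------
    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def modality_dims(self) -> tuple:
        return tuple(M.shape[0] for M in self.modalities)

    @property
    def offsets(self) -> np.ndarray:
        """Row offset of each modality in the stacked matrix (length R+1)."""
        return np.concatenate([[0], np.cumsum(self.modality_dims)])

    def block_slice(self, r: int) -> slice:
        off = self.offsets
        return slice(int(off[r]), int(off[r + 1]))

    # ---- convenience ----------------------------------------------------
    @property
    def stacked_filled(self) -> np.ndarray:
        """Stacked data with missing entries replaced by 0 (for masked algebra)."""
        return np.where(self.mask, self.X, 0.0)

    def observed_fraction(self) -> float:
        return float(self.mask.mean())

    def modality_view(self, r: int):
        """(data, mask) pair for modality ``r`` as views on the stacked arrays."""
        sl = self.block_slice(r)
        return self.X[sl], self.mask[sl]

    def replace_values(self, X_new: np.ndarray, mask=None) -> "MultiModalDataset":
        """New dataset with the same layout/ids but different values."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape != self.X.shape:
            raise ValueError("replacement matrix shape mismatch")
        off = self.offsets
        mods = [X_new[off[r]: off[r + 1]] for r in range(self.n_modalities)]
        return MultiModalDataset(
            mods,
            sample_ids=list(self.sample_ids),
            feature_ids=[list(f) for f in self.feature_ids],
            mask=mask,
        )
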