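"""Synthetic multi-modal data generators with ground-truth labels.

The default design has six clusters of 100 samples observed on three
modalities of 60/120/180 features.  One fifth of the features in each
modality are informative: within a modality, each cluster draws its
informative features from one of two multivariate distributions f_u / f_v
that share an AR(1)-structured covariance but differ in mean.  The u/v
assignment pattern across clusters differs between modalities, so each
modality carries only partial information about the clustering.  The
remaining features are cluster-independent noise.

Four cases are provided:

* ``A`` -- Gaussian informative features, entrywise MCAR missingness;
* ``B`` -- multivariate t (3 df) informative features and t3 noise, MCAR;
* ``C`` -- Gaussian data with modality-wise missing-not-at-random dropout
  driven by a hidden standard-normal variable per subject (drop probability
  ``p`` when the hidden value is non-negative, ``2p`` otherwise);
* ``D`` -- Gaussian data where a sixth of the within-modality correlation
  entries are swapped with zero cross-modality entries, violating the
  block-diagonal error assumption; MCAR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import MultiModalDataset

__all__ = [
    "SimulationSpec",
    "SyntheticDataset",
    "ar1_correlation",
    "informative_covariance",
    "generate_case",
    "introduce_mcar",
]

#: u/v distribution assignment per (cluster, modality).
CLUSTER_PATTERN = (
    ("u", "u", "u"),
    ("v", "v", "u"),
    ("u", "v", "u"),
    ("v", "u", "v"),
    ("v", "u", "u"),
    ("u", "v", "v"),
)

_SIGMA_FLOOR = 1e-3


@dataclass
class SimulationSpec:
    """Study design for one synthetic dataset.

    ``missing_rate`` is the entrywise MCAR rate (cases A, B, D);
    ``mnar_p`` is the base modality-dropout probability (case C).
    """

    case: str = "A"
    rho: float = 0.7
    missing_rate: float = 0.2
    mnar_p: float = 0.1
    n_per_cluster: int = 100
    modality_dims: tuple = (60, 120, 180)
    signal_fraction: float = 0.2   # informative:noisy = 1:4
    seed: int = 0

    def validate(self) -> None:
        if self.case not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown simulation case {self.case!r}")
        if not (0.0 < abs(self.rho) < 1.0) and self.rho != 0.0:
            raise ValueError("rho must satisfy |rho| < 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.mnar_p <= 0.5):
            raise ValueError("mnar_p must lie in [0, 0.5] (2p is also a probability)")
        if self.n_per_cluster < 1:
            raise ValueError("n_per_cluster must be positive")

    @property
    def n_clusters(self) -> int:
        return len(CLUSTER_PATTERN)

    @property
    def n(self) -> int:
        return self.n_clusters * self.n_per_cluster

    def informative_dims(self) -> tuple:
        return tuple(int(round(m * self.signal_fraction)) for m in self.modality_dims)


@dataclass
class SyntheticDataset:
    """Simulated modalities plus everything a validation needs: true labels,
    the generative parameters, the complete (pre-masking) data, and -- for
    case C -- the hidden dropout variable (diagnostics only; never an input
    to fitting)."""

    dataset: MultiModalDataset
    labels: np.ndarray
    truth: dict = field(repr=False)
    spec: SimulationSpec = None
    hidden: np.ndarray = None


def ar1_correlation(size: int, rho: float) -> np.ndarray:
    """First-order autoregressive correlation matrix, entry (i,j) = rho^|i-j|."""
    if abs(rho) >= 1.0:
        raise ValueError(f"AR(1) parameter must satisfy |rho| < 1, got {rho}")
    if size < 1:
        raise ValueError("size must be positive")
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def informative_covariance(m_info: int, rho: float, rng) -> tuple:
    """Covariance ``D @ AR1(rho) @ D`` with ``D = diag(sigma)``,
    ``sigma ~ 4 Beta(1,1) = U[0,4]`` (floored away from zero).

    Returns ``(Sigma, sigma)``.
    """
    rng = np.random.default_rng(rng)
    sigma = np.maximum(4.0 * rng.beta(1.0, 1.0, size=m_info), _SIGMA_FLOOR)
    Sigma = ar1_correlation(m_info, rho) * np.outer(sigma, sigma)
    return Sigma, sigma


def _sample_mvn(rng, mean, chol, size):
    z = rng.standard_normal((size, mean.size))
    return mean + z @ chol.T


def _sample_mvt3(rng, mean, chol, size):
    """Multivariate t with 3 df: location + scatter-Cholesky scaled normal
    over sqrt(chi2_3 / 3), one mixing draw per sample."""
    z = rng.standard_normal((size, mean.size))
    g = rng.chisquare(3.0, size=(size, 1)) / 3.0
    return mean + (z @ chol.T) / np.sqrt(g)


def _swap_correlations(R: np.ndarray, info_dims, rng) -> dict:
    """Case D: swap 1/6 of the strictly-lower within-block correlation
    entries with zero cross-block entries (symmetrically), in place.

    Returns swap metadata (index pairs and the multiset of moved values).
    """
    m = R.shape[0]
    off = np.concatenate([[0], np.cumsum(info_dims)])
    block_id = np.zeros(m, dtype=int)
    for r in range(len(info_dims)):
        block_id[off[r]: off[r + 1]] = r
    ii, jj = np.tril_indices(m, k=-1)
    within = block_id[ii] == block_id[jj]
    win_pairs = np.column_stack([ii[within], jj[within]])
    cross_pairs = np.column_stack([ii[~within], jj[~within]])
    n_swap = len(win_pairs) // 6
    sel_w = rng.choice(len(win_pairs), size=n_swap, replace=False)
    sel_c = rng.choice(len(cross_pairs), size=n_swap, replace=False)
    wi, wj = win_pairs[sel_w].T
    ci, cj = cross_pairs[sel_c].T
    moved = R[wi, wj].copy()
    R[wi, wj] = R[wj, wi] = 0.0
    R[ci, cj] = R[cj, ci] = moved
    return dict(
        within_pairs=win_pairs[sel_w],
        cross_pairs=cross_pairs[sel_c],
        moved_values=moved,
    )


def _repair_pd(Sigma: np.ndarray, target: float = 1e-6) -> np.ndarray:
    """Add the smallest power-of-ten diagonal jitter making the smallest
    eigenvalue at least ``target``."""
    w = np.linalg.eigvalsh(Sigma)[0]
    if w >= target:
        return Sigma
    jitter = 1e-12
    while jitter < 1e6:
        if np.linalg.eigvalsh(Sigma + jitter * np.eye(len(Sigma)))[0] >= target:
            return Sigma + jitter * np.eye(len(Sigma))
        jitter *= 10.0
    raise np.linalg.LinAlgError("could not repair covariance to positive definite")


def generate_case(spec: SimulationSpec) -> SyntheticDataset:
    """Generate one synthetic dataset under the given design."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R = len(spec.modality_dims)
    if R != len(CLUSTER_PATTERN[0]):
        raise ValueError("the cluster design is defined for three modalities")
    info_dims = spec.informative_dims()
    n_c = spec.n_per_cluster
    n = spec.n
    labels = np.repeat(np.arange(spec.n_clusters), n_c)

    # generative parameters per modality
    mu_u, mu_v, Sigmas, sigmas = [], [], [], []
    for r in range(R):
        mi = info_dims[r]
        mu_u.append(rng.uniform(1.0, 2.0, size=mi))
        mu_v.append(rng.uniform(-2.0, -1.0, size=mi))
        Sigma, sigma = informative_covariance(mi, spec.rho, rng)
        Sigmas.append(Sigma)
        sigmas.append(sigma)

    truth = dict(
        mu_u=mu_u, mu_v=mu_v, Sigma=Sigmas, sigma=sigmas,
        info_dims=info_dims, pattern=CLUSTER_PATTERN,
    )

    heavy = spec.case == "B"
    sampler = _sample_mvt3 if heavy else _sample_mvn

    if spec.case == "D":
        # joint informative covariance with swapped cross-modality entries
        m_info = sum(info_dims)
        off = np.concatenate([[0], np.cumsum(info_dims)])
        R_full = np.eye(m_info)
        for r in range(R):
            sl = slice(off[r], off[r + 1])
            R_full[sl, sl] = ar1_correlation(info_dims[r], spec.rho)
        swap = _swap_correlations(R_full, info_dims, rng)
        sig_full = np.concatenate(sigmas)
        Sigma_full = _repair_pd(R_full * np.outer(sig_full, sig_full))
        chol_full = np.linalg.cholesky(Sigma_full)
        truth["swap"] = swap
        truth["Sigma_joint"] = Sigma_full
        info_parts = []
        for c in range(spec.n_clusters):
            mean = np.concatenate([
                mu_u[r] if CLUSTER_PATTERN[c][r] == "u" else mu_v[r]
                for r in range(R)
            ])
            info_parts.append(_sample_mvn(rng, mean, chol_full, n_c).T)
        info_full = np.concatenate(info_parts, axis=1)   # (m_info, n)
        info_per_mod = [info_full[off[r]: off[r + 1]] for r in range(R)]
    else:
        info_per_mod = []
        for r in range(R):
            chol = np.linalg.cholesky(Sigmas[r])
            parts = []
            for c in range(spec.n_clusters):
                mean = mu_u[r] if CLUSTER_PATTERN[c][r] == "u" else mu_v[r]
                parts.append(sampler(rng, mean, chol, n_c).T)
            info_per_mod.append(np.concatenate(parts, axis=1))

    modalities = []
    for r in range(R):
        m_noise = spec.modality_dims[r] - info_dims[r]
        if heavy:
            noise = rng.standard_t(3.0, size=(m_noise, n))
        else:
            noise = rng.standard_normal((m_noise, n))
        modalities.append(np.vstack([info_per_mod[r], noise]))

    complete = MultiModalDataset([M.copy() for M in modalities])
    truth["complete"] = complete
    hidden = None

    if spec.case == "C":
        hidden = rng.standard_normal(n)
        p_k = np.where(hidden >= 0.0, spec.mnar_p, 2.0 * spec.mnar_p)
        drop = rng.random((R, n)) < p_k[None, :]
        # subjects losing every modality are degenerate for any method;
        # redraw their dropout indicators
        all_gone = drop.all(axis=0)
        while all_gone.any():
            drop[:, all_gone] = (
                rng.random((R, int(all_gone.sum()))) < p_k[None, all_gone]
            )
            all_gone = drop.all(axis=0)
        masked = []
        for r in range(R):
            M = modalities[r].copy()
            M[:, drop[r]] = np.nan
            masked.append(M)
        ds = MultiModalDataset(masked)
        truth["dropped"] = drop
    else:
        ds = introduce_mcar(complete, spec.missing_rate,
                            seed=rng.integers(2**31))

    return SyntheticDataset(dataset=ds, labels=labels, truth=truth,
                            spec=spec, hidden=hidden)


def introduce_mcar(dataset: MultiModalDataset, rate: float,
                   seed=None) -> MultiModalDataset:
    """Mask each entry independently with the given probability.

    Columns that would lose every entry have their masks redrawn (with a
    warning) so that no sample becomes completely empty.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"MCAR rate must lie in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    if rate == 0.0:
        return dataset.replace_values(np.where(dataset.mask, dataset.X, np.nan))
    drop = rng.random(dataset.X.shape) < rate
    keep = dataset.mask & ~drop
    empty = ~keep.any(axis=0)
    if empty.any():
        warnings.warn(
            f"MCAR masking emptied {int(empty.sum())} column(s); redrawing "
            "their masks",
            RuntimeWarning,
        )
    while empty.any():
        cols = np.flatnonzero(empty)
        drop[:, cols] = rng.random((dataset.m, cols.size)) < rate
        keep = dataset.mask & ~drop
        empty = ~keep.any(axis=0)
    X_new = np.where(keep, dataset.X, np.nan)
    return dataset.replace_values(X_new)
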