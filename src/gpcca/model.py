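"""Probabilistic CCA generalized to R >= 2 modalities, fitted by EM.

Model
-----
Stacking the R feature-by-sample matrices gives ``X = W Z + U + E`` where the
columns of ``Z`` (d x n) are i.i.d. standard Gaussian latent factors shared by
all modalities, ``U`` repeats the mean vector ``mu``, and the error columns
are Gaussian with block-diagonal covariance ``Psi`` (one block per modality:
correlated errors are allowed within a modality but not across modalities).

Estimation handles arbitrary missingness patterns: for each subject the
marginal of the observed sub-vector is Gaussian with covariance
``W~ W~' + Psi~`` restricted to observed rows, and the EM algorithm works on
the conditional moments of the latent factors and missing entries given the
observed ones.  All per-subject linear algebra is routed through the d x d
Woodbury matrix ``M~ = (I + W~' Psi~^{-1} W~)^{-1}`` and blockwise inversion
of ``Psi~``; inversion of observed sub-blocks is done by a Schur complement
against the full per-modality precision so the per-subject cost scales with
the number of *missing* rows, not observed ones.

The M-step optionally applies ridge shrinkage to the error correlation
matrix: the covariance update is ``Psi_ridge = lam * Psi_hat +
(1 - lam) * diag(Psi_hat)``, whose correlation matrix is exactly
``lam * R_hat + (1 - lam) * I`` while the variances stay at their
maximum-likelihood values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import MultiModalDataset
from ._kernels import HAVE_NUMBA, partial_phase1, partial_phase2

__all__ = [
    "FitConfig",
    "GPCCAParameters",
    "PartialSubjectView",
    "EStepMoments",
    "FittedModel",
    "initialize_parameters",
    "extract_partial",
    "e_step",
    "m_step",
    "observed_log_likelihood",
    "penalized_objective",
    "fit",
    "embed",
    "impute",
]

#: Lower bound applied to the diagonal of Psi to keep every block invertible.
VARIANCE_FLOOR = 1e-6

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# configuration and parameter containers
# ---------------------------------------------------------------------------
@dataclass
class FitConfig:
    """EM settings.

    Attributes
    ----------
    d
        Latent dimension, ``1 <= d <= min_r m_r``.
    lam
        Ridge shrinkage weight in ``(0, 1]``; ``lam = 1`` disables shrinkage
        (it corresponds to ``lam = 1 - c/n`` for penalty weight ``c``).
    max_iter, tol
        EM stops when the relative change of the observed-data log-likelihood
        drops below ``tol`` or after ``max_iter`` iterations.
    seed
        Seed for the random loading initialization.
    covariance_mode
        ``"block"`` keeps full within-modality error covariance blocks;
        ``"diagonal"`` truncates them to their diagonal each M-step.
    init_scale
        Standard deviation of the i.i.d. Gaussian entries of ``W^(0)``.
    """

    d: int
    lam: float = 0.5
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    covariance_mode: str = "block"
    init_scale: float = 0.1

    def validate(self) -> None:
        if not (isinstance(self.d, (int, np.integer)) and self.d >= 1):
            raise ValueError(f"latent dimension d must be a positive integer, got {self.d}")
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"ridge weight lam must lie in (0, 1], got {self.lam}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.covariance_mode not in ("block", "diagonal"):
            raise ValueError(f"unknown covariance_mode {self.covariance_mode!r}")


@dataclass
class GPCCAParameters:
    """Loadings ``W`` (m x d), mean ``mu`` (m,), block-diagonal ``Psi``."""

    W: np.ndarray
    mu: np.ndarray
    Psi_blocks: list
    dims: tuple
    covariance_mode: str = "block"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.Psi_blocks = [np.asarray(B, dtype=float) for B in self.Psi_blocks]
        self.dims = tuple(int(v) for v in self.dims)
        m = sum(self.dims)
        if self.W.shape[0] != m or self.mu.shape != (m,):
            raise ValueError("W/mu shapes inconsistent with modality dims")
        if len(self.Psi_blocks) != len(self.dims) or any(
            B.shape != (mr, mr) for B, mr in zip(self.Psi_blocks, self.dims)
        ):
            raise ValueError("Psi blocks inconsistent with modality dims")

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.dims)])

    def block_slice(self, r: int) -> slice:
        off = self.offsets
        return slice(int(off[r]), int(off[r + 1]))

    def modality_of_row(self, i: int) -> tuple:
        """Map a stacked row index to ``(modality, local index)``."""
        off = self.offsets
        r = int(np.searchsorted(off, i, side="right") - 1)
        return r, int(i - off[r])

    def Psi_full(self) -> np.ndarray:
        """Dense m x m block-diagonal error covariance (small models only)."""
        out = np.zeros((self.m, self.m))
        for r, B in enumerate(self.Psi_blocks):
            sl = self.block_slice(r)
            out[sl, sl] = B
        return out

    def correlation_blocks(self) -> list:
        """Error correlation matrix of each block."""
        out = []
        for B in self.Psi_blocks:
            s = np.sqrt(np.diag(B))
            out.append(B / np.outer(s, s))
        return out

    def copy(self) -> "GPCCAParameters":
        return GPCCAParameters(
            self.W.copy(), self.mu.copy(), [B.copy() for B in self.Psi_blocks],
            self.dims, self.covariance_mode,
        )


@dataclass
class PartialSubjectView:
    """Observed-row restriction of the model for one subject.

    ``M_tilde`` is the Woodbury matrix ``(I + W~' Psi~^{-1} W~)^{-1}``; the
    inverse of ``Psi~`` is taken blockwise by modality (valid because ``Psi``
    is block diagonal, hence so is any observed-row restriction).
    """

    subject_index: int
    observed_rows: np.ndarray
    x_tilde: np.ndarray
    W_tilde: np.ndarray
    mu_tilde: np.ndarray
    Psi_tilde_blocks: list
    M_tilde: np.ndarray

    @property
    def m_obs(self) -> int:
        return int(self.observed_rows.size)


def initialize_parameters(dataset: MultiModalDataset, config: FitConfig) -> GPCCAParameters:
    """Moment-based starting point for EM.

    ``mu0`` holds per-feature means over observed entries, ``Psi0`` is the
    diagonal matrix of per-feature observed variances (floored), and ``W0``
    has i.i.d. ``N(0, init_scale^2)`` entries drawn under ``config.seed``.
    """
    config.validate()
    dims = dataset.modality_dims
    if config.d > min(dims):
        raise ValueError(
            f"d={config.d} exceeds the smallest modality dimension {min(dims)}"
        )
    obs_count = dataset.mask.sum(axis=1)
    if (obs_count == 0).any():
        i = int(np.flatnonzero(obs_count == 0)[0])
        r, j = _row_to_modality(dims, i)
        raise ValueError(
            f"feature {dataset.feature_ids[r][j]!r} (modality {r + 1}) has no "
            "observed entries; drop it before fitting"
        )
    Xf = dataset.stacked_filled
    mu0 = Xf.sum(axis=1) / obs_count
    resid2 = ((Xf - mu0[:, None]) ** 2) * dataset.mask
    var0 = np.maximum(resid2.sum(axis=1) / obs_count, VARIANCE_FLOOR)
    rng = np.random.default_rng(config.seed)
    W0 = rng.normal(0.0, config.init_scale, size=(dataset.m, config.d))
    off = np.concatenate([[0], np.cumsum(dims)])
    blocks = [np.diag(var0[off[r]: off[r + 1]]) for r in range(len(dims))]
    return GPCCAParameters(W0, mu0, blocks, dims, config.covariance_mode)


def _row_to_modality(dims, i):
    off = np.concatenate([[0], np.cumsum(dims)])
    r = int(np.searchsorted(off, i, side="right") - 1)
    return r, int(i - off[r])


def extract_partial(
    params: GPCCAParameters, dataset: MultiModalDataset, k: int
) -> PartialSubjectView:
    """Observed-row quantities and Woodbury matrix for subject ``k``."""
    mask_k = dataset.mask[:, k]
    rows = np.flatnonzero(mask_k)
    if rows.size == 0:
        raise ValueError(f"subject {k} has no observed entries")
    x_t = dataset.X[rows, k]
    W_t = params.W[rows]
    mu_t = params.mu[rows]
    blocks = []
    Q = np.zeros((params.d, params.d))
    for r, B in enumerate(params.Psi_blocks):
        sl = params.block_slice(r)
        loc = np.flatnonzero(mask_k[sl])
        Bt = B[np.ix_(loc, loc)]
        blocks.append(Bt)
        if loc.size == 0:
            continue
        Wr = params.W[sl][loc]
        try:
            L = np.linalg.cholesky(Bt)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular observed error-covariance block for modality {r + 1}, "
                f"subject {k}"
            ) from exc
        half = np.linalg.solve(L, Wr)
        Q += half.T @ half
    M = np.linalg.inv(np.eye(params.d) + Q)
    M = 0.5 * (M + M.T)
    return PartialSubjectView(int(k), rows, x_t, W_t, mu_t, blocks, M)


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------
@dataclass
class EStepMoments:
    """Conditional expectations given the observed data, at fixed parameters.

    Per-subject first/second latent moments and completed data are stored
    densely; the modality-block second moments and the ``G_k`` matrices are
    produced on demand (they are only ever needed within blocks, which is
    what the block-diagonal M-step consumes).
    """

    Ez: np.ndarray              # (d, n) posterior latent means
    Mk: np.ndarray              # (n, d, d) posterior latent covariances
    Ex: np.ndarray              # (m, n) completed data
    loglik: float               # observed-data log-likelihood at params
    # accumulated sufficient statistics for the M-step
    sum_Ez: np.ndarray          # (d,)
    sum_Ezz: np.ndarray         # (d, d)  = sum_k E(z z')
    sum_Exz: np.ndarray         # (m, d)  = sum_k E(x z')
    sum_xx_blocks: list         # per modality (m_r, m_r) = sum_k E(x x') block
    params: GPCCAParameters = field(repr=False)
    dataset: MultiModalDataset = field(repr=False)

    @property
    def n(self) -> int:
        return self.Ez.shape[1]

    def Ezz(self, k: int) -> np.ndarray:
        ez = self.Ez[:, k]
        return self.Mk[k] + np.outer(ez, ez)

    def Exz(self, k: int) -> np.ndarray:
        """E(X_.k z_k') -- ``W_i M~ + Ex_i Ez'`` on missing rows, data-weighted
        posterior mean on observed rows."""
        out = np.outer(self.Ex[:, k], self.Ez[:, k])
        miss = ~self.dataset.mask[:, k]
        out[miss] += self.params.W[miss] @ self.Mk[k]
        return out

    def second_moment_block(self, k: int, r: int) -> np.ndarray:
        """E(X_ik X_jk) for rows (i, j) inside modality block ``r``."""
        sl = self.params.block_slice(r)
        ex = self.Ex[sl, k]
        out = np.outer(ex, ex)
        miss = ~self.dataset.mask[sl, k]
        if miss.any():
            Wm = self.params.W[sl][miss]
            out[np.ix_(miss, miss)] += (
                Wm @ self.Mk[k] @ Wm.T + self.params.Psi_blocks[r][np.ix_(miss, miss)]
            )
        return out

    def Gk_blocks(self, k: int) -> list:
        """Modality blocks of the residual second-moment matrix ``G_k``
        evaluated at the parameters the E-step was run with."""
        p = self.params
        out = []
        ez = self.Ez[:, k]
        Ezz = self.Ezz(k)
        for r in range(len(p.dims)):
            sl = p.block_slice(r)
            Wr, mur = p.W[sl], p.mu[sl]
            ex = self.Ex[sl, k]
            exz = self.Exz(k)[sl]
            G = (
                self.second_moment_block(k, r)
                + np.outer(mur, mur)
                + Wr @ Ezz @ Wr.T
                - np.outer(ex, mur) - np.outer(mur, ex)
                + np.outer(Wr @ ez, mur) + np.outer(mur, Wr @ ez)
                - exz @ Wr.T - Wr @ exz.T
            )
            out.append(0.5 * (G + G.T))
        return out


def _missing_csr(pidx: np.ndarray, missing: np.ndarray) -> dict:
    """CSR layout of per-subject missing-row indices within one block.

    ``missing`` is (n_partial, m_r) boolean; row order follows ``pidx``.
    """
    counts = missing.sum(axis=1)
    mptr = np.zeros(len(pidx) + 1, dtype=np.int64)
    np.cumsum(counts, out=mptr[1:])
    _, midx = np.nonzero(missing)
    return dict(
        cols=pidx.astype(np.int64),
        mptr=mptr,
        midx=midx.astype(np.int64),
        missing=missing,
    )


def _phase1_padded(P, W_r, A, U, d, part, missing, Qsum, ssum, quad, logdet):
    """Batched numpy version of :func:`gpcca._kernels.partial_phase1`:
    subjects are padded to the largest per-block missing count, with padding
    rows carrying an identity sub-matrix so they contribute nothing."""
    pidx = part["cols"]
    s_max = int(missing.sum(axis=1).max())
    order = np.argsort(~missing, axis=1, kind="stable")
    idx = order[:, :s_max]
    pm = np.take_along_axis(missing, idx, axis=1)
    pmf = pm.astype(float)
    pair = pmf[:, :, None] * pmf[:, None, :]
    Pmm = P[idx[:, :, None], idx[:, None, :]] * pair
    ar = np.arange(s_max)
    Pmm[:, ar, ar] = np.where(pm, np.diag(P)[idx], 1.0)
    Wm = W_r[idx] * pmf[:, :, None]
    Am = A[idx] * pmf[:, :, None]
    g = U[idx, pidx[:, None]] * pmf
    Lm = np.linalg.cholesky(Pmm)
    PmmWm = Pmm @ Wm
    T = Am - PmmWm
    rhs = np.concatenate([T, g[:, :, None]], axis=2)
    sol = np.linalg.solve(Pmm, rhs)
    H, h = sol[:, :, :d], sol[:, :, d]
    WtAm = np.einsum("ksd,kse->kde", Wm, Am)
    Qsum[pidx] += (
        -WtAm - WtAm.transpose(0, 2, 1)
        + np.einsum("ksd,kse->kde", Wm, PmmWm)
        - np.einsum("ksd,kse->kde", T, H)
    )
    ssum[pidx] -= (
        np.einsum("ksd,ks->kd", Wm, g) + np.einsum("ksd,ks->kd", T, h)
    )
    quad[pidx] -= np.einsum("ks,ks->k", g, h)
    logdet[pidx] += 2.0 * np.log(Lm[:, ar, ar]).sum(axis=1)


def _phase2_padded(W_r, Psi_r, Mk, part, CorrXX, CorrXZ):
    """Batched numpy version of :func:`gpcca._kernels.partial_phase2`."""
    pidx, missing = part["cols"], part["missing"]
    m_r = W_r.shape[0]
    s_max = int(missing.sum(axis=1).max())
    order = np.argsort(~missing, axis=1, kind="stable")
    idx = order[:, :s_max]
    pm = np.take_along_axis(missing, idx, axis=1)
    pmf = pm.astype(float)
    Wm = W_r[idx] * pmf[:, :, None]
    WmM = Wm @ Mk[pidx]
    V = WmM @ Wm.transpose(0, 2, 1)
    pair = pmf[:, :, None] * pmf[:, None, :]
    V += Psi_r[idx[:, :, None], idx[:, None, :]] * pair
    flat = (idx[:, :, None] * m_r + idx[:, None, :]).ravel()
    CorrXX += np.bincount(flat, weights=V.ravel(),
                          minlength=m_r * m_r).reshape(m_r, m_r)
    np.add.at(CorrXZ, idx.ravel(),
              (WmM * pmf[:, :, None]).reshape(-1, WmM.shape[2]))


def _estep_core(params: GPCCAParameters, dataset: MultiModalDataset,
                want_sums: bool = True):
    """Single pass over the data computing latent moments, completed data,
    the observed-data log-likelihood, and (optionally) the M-step sums.

    Per modality block, subjects are split into three classes: block fully
    observed (closed forms from the full-block precision), block fully
    missing (no contribution to the posterior; closed-form contribution to
    the second-moment sums), and partially observed (Schur complement of the
    full-block precision on the missing rows, batched over subjects with a
    shared padding so the cost is driven by the largest per-block missing
    count).
    """
    X = dataset.X
    O = dataset.mask
    m, n = X.shape
    d = params.d
    R = len(params.dims)

    Qsum = np.zeros((n, d, d))
    ssum = np.zeros((n, d))
    quad = np.zeros(n)
    logdet_psi = np.zeros(n)
    m_obs = O.sum(axis=0).astype(float)

    # per-block precomputation and per-subject accumulation
    block_cache = []
    for r in range(R):
        sl = params.block_slice(r)
        Psi_r = params.Psi_blocks[r]
        m_r = Psi_r.shape[0]
        try:
            Lr = np.linalg.cholesky(Psi_r)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"error covariance block of modality {r + 1} is not positive "
                "definite"
            ) from exc
        logdet_r = 2.0 * float(np.log(np.diag(Lr)).sum())
        Linv = np.linalg.inv(Lr)
        P = Linv.T @ Linv                       # Psi_r^{-1}
        W_r = params.W[sl]
        A = P @ W_r                             # Psi^{-1} W
        Q_r = W_r.T @ A

        O_r = O[sl]
        nobs = O_r.sum(axis=0)
        none_cols = nobs == 0
        obs_cols = ~none_cols
        part_cols = obs_cols & (nobs < m_r)

        D0 = np.where(O_r, X[sl] - params.mu[sl][:, None], 0.0)
        U = P @ D0                              # (m_r, n)
        S = A.T @ D0                            # (d, n); exact for full columns
        q0 = np.einsum("in,in->n", D0, U)

        # base terms for every column with at least one observed row; the
        # partial-missingness corrections are added on top below
        Qsum[obs_cols] += Q_r
        ssum[obs_cols] += S[:, obs_cols].T
        quad[obs_cols] += q0[obs_cols]
        logdet_psi[obs_cols] += logdet_r

        part = {}
        if part_cols.any():
            pidx = np.flatnonzero(part_cols)
            missing = ~O_r[:, pidx].T           # (np, m_r)
            part = _missing_csr(pidx, missing)
            if HAVE_NUMBA:
                partial_phase1(P, W_r, A, U, part["cols"], part["mptr"],
                               part["midx"], Qsum, ssum, quad, logdet_psi)
            else:
                _phase1_padded(P, W_r, A, U, d, part, missing,
                               Qsum, ssum, quad, logdet_psi)
        block_cache.append(
            dict(sl=sl, P=P, W_r=W_r, Psi_r=Psi_r, m_r=m_r, part=part,
                 none_cols=none_cols)
        )

    Id = np.eye(d)
    C = np.linalg.cholesky(Id + Qsum)
    logdet_M = -2.0 * np.log(C[:, np.arange(d), np.arange(d)]).sum(axis=1)
    Mk = np.linalg.inv(Id + Qsum)
    Mk = 0.5 * (Mk + Mk.transpose(0, 2, 1))
    Ez_n = np.einsum("kde,ke->kd", Mk, ssum)    # (n, d)
    sMs = np.einsum("kd,kd->k", ssum, Ez_n)
    loglik = -0.5 * float(
        np.sum(m_obs * _LOG2PI + logdet_psi - logdet_M + quad - sMs)
    )
    Ez = Ez_n.T                                  # (d, n)

    WEz = params.W @ Ez
    Ex = np.where(O, np.nan_to_num(X), WEz + params.mu[:, None])

    if not want_sums:
        return EStepMoments(Ez, Mk, Ex, loglik, None, None, None, None,
                            params, dataset)

    sum_Ez = Ez.sum(axis=1)
    sum_Mk = Mk.sum(axis=0)
    sum_Ezz = sum_Mk + Ez @ Ez.T
    sum_Exz = Ex @ Ez.T
    sum_xx_blocks = []
    for r, bc in enumerate(block_cache):
        sl, m_r = bc["sl"], bc["m_r"]
        Exb = Ex[sl]
        Sxx = Exb @ Exb.T
        part = bc["part"]
        if part:
            CorrXX = np.zeros((m_r, m_r))
            CorrXZ = np.zeros((m_r, d))
            if HAVE_NUMBA:
                partial_phase2(bc["W_r"], bc["Psi_r"], Mk, part["cols"],
                               part["mptr"], part["midx"], CorrXX, CorrXZ)
            else:
                _phase2_padded(bc["W_r"], bc["Psi_r"], Mk, part,
                               CorrXX, CorrXZ)
            Sxx += CorrXX
            sum_Exz[sl] += CorrXZ
        none_cols = bc["none_cols"]
        if none_cols.any():
            Mno = Mk[none_cols].sum(axis=0)
            W_r = bc["W_r"]
            Sxx += W_r @ Mno @ W_r.T + none_cols.sum() * bc["Psi_r"]
            sum_Exz[sl] += W_r @ Mno
        sum_xx_blocks.append(0.5 * (Sxx + Sxx.T))

    return EStepMoments(Ez, Mk, Ex, loglik, sum_Ez, sum_Ezz, sum_Exz,
                        sum_xx_blocks, params, dataset)


def e_step(params: GPCCAParameters, dataset: MultiModalDataset) -> EStepMoments:
    """Conditional expectations of the latent factors and missing entries."""
    mom = _estep_core(params, dataset, want_sums=True)
    if not np.isfinite(mom.Ez).all():
        bad = int(np.flatnonzero(~np.isfinite(mom.Ez).all(axis=0))[0])
        raise FloatingPointError(f"non-finite E-step moments for subject {bad}")
    return mom


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------
def m_step(
    moments: EStepMoments,
    params: GPCCAParameters,
    dataset: MultiModalDataset,
    lam: float,
    covariance_mode: str = None,
) -> GPCCAParameters:
    """Parameter updates from the E-step sums, with ridge shrinkage.

    The three updates are applied as successive conditional maximizations:
    ``mu`` from the current loadings, ``W`` from the fresh mean, and ``Psi``
    as the block-restricted residual second moment at the fresh ``(mu, W)``.
    The ridge step then replaces ``Psi_hat`` by
    ``lam * Psi_hat + (1 - lam) * diag(Psi_hat)``, i.e. shrinks the error
    correlations toward the identity while keeping the variance estimates.
    """
    if covariance_mode is None:
        covariance_mode = params.covariance_mode
    if not (0.0 < lam <= 1.0):
        raise ValueError("ridge weight lam must lie in (0, 1]")
    n = moments.n
    d = params.d

    sum_Ez = moments.sum_Ez
    sum_Ezz = moments.sum_Ezz
    sum_Exz = moments.sum_Exz
    sum_Ex = moments.Ex.sum(axis=1)

    mu_new = (sum_Ex - params.W @ sum_Ez) / n

    try:
        W_new = np.linalg.solve(
            sum_Ezz.T, (sum_Exz - np.outer(mu_new, sum_Ez)).T
        ).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sum of latent second moments is singular; consider a smaller "
            "latent dimension d"
        ) from exc

    blocks = []
    for r in range(len(params.dims)):
        sl = params.block_slice(r)
        mur = mu_new[sl]
        Wr = W_new[sl]
        e_r = sum_Ex[sl]
        C_r = sum_Exz[sl]
        Sres = (
            moments.sum_xx_blocks[r]
            - np.outer(e_r, mur) - np.outer(mur, e_r)
            + n * np.outer(mur, mur)
            - C_r @ Wr.T - Wr @ C_r.T
            + Wr @ sum_Ezz @ Wr.T
            + np.outer(mur, sum_Ez) @ Wr.T + Wr @ np.outer(sum_Ez, mur)
        )
        Psi_hat = Sres / n
        Psi_hat = 0.5 * (Psi_hat + Psi_hat.T)
        if covariance_mode == "diagonal":
            Psi_hat = np.diag(np.diag(Psi_hat))
        dg = np.maximum(np.diag(Psi_hat), VARIANCE_FLOOR)
        np.fill_diagonal(Psi_hat, dg)
        if lam < 1.0:
            # shrink the error correlations toward the identity while keeping
            # the maximum-likelihood variances: the correlation matrix of the
            # result is exactly lam * R_hat + (1 - lam) * I
            Psi_hat = lam * Psi_hat + (1.0 - lam) * np.diag(dg)
        blocks.append(Psi_hat)

    return GPCCAParameters(W_new, mu_new, blocks, params.dims, covariance_mode)


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------
def observed_log_likelihood(
    params: GPCCAParameters, dataset: MultiModalDataset
) -> float:
    """Sum over subjects of the Gaussian log-density of the observed
    sub-vector under ``N(mu~, W~ W~' + Psi~)``."""
    return _estep_core(params, dataset, want_sums=False).loglik


def _trace_inv_correlation(params: GPCCAParameters) -> float:
    """tr(R^{-1}) of the block error correlation matrix."""
    total = 0.0
    for B in params.Psi_blocks:
        s = np.sqrt(np.diag(B))
        Rb = B / np.outer(s, s)
        total += float(np.trace(np.linalg.inv(Rb)))
    return total


def penalized_objective(
    params: GPCCAParameters, dataset: MultiModalDataset, lam: float
) -> float:
    """Observed log-likelihood minus the ridge penalty
    ``(c/2) tr(R^{-1})`` with ``c = n (1 - lam)``; equals the plain
    log-likelihood when ``lam = 1``."""
    ll = observed_log_likelihood(params, dataset)
    if lam >= 1.0:
        return ll
    c = dataset.n * (1.0 - lam)
    return ll - 0.5 * c * _trace_inv_correlation(params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
@dataclass
class FittedModel:
    """EM output: final parameters, objective traces, and the embedding
    (posterior latent means at the final parameters)."""

    params: GPCCAParameters
    loglik_trace: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    embedding: np.ndarray        # (d, n)
    config: FitConfig

    def embed(self, dataset: MultiModalDataset) -> np.ndarray:
        return embed(self, dataset)

    def impute(self, dataset: MultiModalDataset) -> MultiModalDataset:
        return impute(self, dataset)


def fit(dataset: MultiModalDataset, config: FitConfig) -> FittedModel:
    """EM estimation from :func:`initialize_parameters` to convergence.

    The relative-change stopping rule is applied to the observed-data
    log-likelihood; with ``lam < 1`` a separate trace of the penalized
    objective is recorded as well.  Non-convergence raises a warning, not an
    error.
    """
    config.validate()
    params = initialize_parameters(dataset, config)
    lam = config.lam
    c_pen = dataset.n * (1.0 - lam)
    ll_trace = []
    obj_trace = []
    prev = -np.inf
    converged = False
    mom = None
    for it in range(config.max_iter):
        mom = _estep_core(params, dataset, want_sums=True)
        ll = mom.loglik
        if not np.isfinite(ll):
            raise FloatingPointError(f"log-likelihood became non-finite at iteration {it}")
        ll_trace.append(ll)
        if lam < 1.0:
            obj_trace.append(ll - 0.5 * c_pen * _trace_inv_correlation(params))
        else:
            obj_trace.append(ll)
        if it > 0 and abs(ll - prev) <= config.tol * abs(prev):
            converged = True
            break
        prev = ll
        if it < config.max_iter - 1:
            params = m_step(mom, params, dataset, lam, config.covariance_mode)
    if not converged:
        delta = (
            abs(ll_trace[-1] - ll_trace[-2]) / max(abs(ll_trace[-2]), 1e-300)
            if len(ll_trace) > 1
            else np.inf
        )
        warnings.warn(
            f"EM did not converge in {config.max_iter} iterations "
            f"(last relative change {delta:.3g})",
            RuntimeWarning,
        )
    return FittedModel(
        params=params,
        loglik_trace=np.asarray(ll_trace),
        objective_trace=np.asarray(obj_trace),
        n_iter=len(ll_trace),
        converged=converged,
        embedding=mom.Ez.copy(),
        config=config,
    )


def embed(model: FittedModel, dataset: MultiModalDataset) -> np.ndarray:
    """Posterior latent means ``E(z_k | observed data)`` at the fitted
    parameters; works for new subjects with any missingness pattern."""
    if dataset.m != model.params.m:
        raise ValueError(
            f"dataset has {dataset.m} stacked features, model expects {model.params.m}"
        )
    return _estep_core(model.params, dataset, want_sums=False).Ez


def impute(model: FittedModel, dataset: MultiModalDataset) -> MultiModalDataset:
    """Complete the dataset: observed entries pass through unchanged, missing
    entries are replaced by ``W_i E(z_k | observed) + mu_i``."""
    if dataset.m != model.params.m:
        raise ValueError(
            f"dataset has {dataset.m} stacked features, model expects {model.params.m}"
        )
    mom = _estep_core(model.params, dataset, want_sums=False)
    return dataset.replace_values(mom.Ex)
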