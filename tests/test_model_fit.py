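"""EM fitting: monotonicity, ridge behavior, recovery, embedding, imputation."""

import warnings

import numpy as np
import pytest

from gpcca.data import MultiModalDataset
from gpcca.model import (FitConfig, e_step, embed, fit, impute,
                         initialize_parameters, m_step, penalized_objective)

from conftest import random_dataset
from oracles import factor_analysis_em_step, principal_angles


def _objective_trace(ds, cfg, iters):
    params = initialize_parameters(ds, cfg)
    objs = []
    for _ in range(iters):
        mom = e_step(params, ds)
        objs.append(penalized_objective(params, ds, cfg.lam))
        params = m_step(mom, params, ds, cfg.lam, cfg.covariance_mode)
    return np.asarray(objs)


@pytest.mark.parametrize("lam", [1.0, 2 / 3, 0.5])
@pytest.mark.parametrize("regime", ["complete", "blockwise", "diag_entrywise"])
def test_objective_monotone_in_exact_em_regimes(lam, regime):
    """The (penalized) objective never decreases when the moment formulas
    are exact: complete data, modality-wise missingness, or diagonal error
    covariance with entrywise missingness."""
    rng = np.random.default_rng(7)
    if regime == "complete":
        ds = random_dataset(rng, n=40, miss=0.0)
        mode = "block"
    elif regime == "blockwise":
        ds = random_dataset(rng, n=40, miss=0.3, blockwise=True)
        mode = "block"
    else:
        ds = random_dataset(rng, n=40, miss=0.3)
        mode = "diagonal"
    cfg = FitConfig(d=2, lam=lam, seed=11, covariance_mode=mode)
    objs = _objective_trace(ds, cfg, 50)
    rel = np.diff(objs) / np.abs(objs[:-1])
    assert rel.min() >= -1e-8


def test_loglik_near_monotone_with_entrywise_block_missingness():
    """With entrywise missingness and block covariance the printed moment
    formulas neglect the residual coupling between missing and observed
    errors within a block, so ascent is only approximate; drops stay tiny."""
    rng = np.random.default_rng(3)
    ds = random_dataset(rng, n=50, miss=0.25)
    cfg = FitConfig(d=2, lam=1.0, seed=5)
    objs = _objective_trace(ds, cfg, 60)
    rel = np.diff(objs) / np.abs(objs[:-1])
    assert rel.min() >= -1e-4
    assert objs[-1] > objs[0]


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------
def test_ridge_identities(rng, small_missing_dataset):
    """lam=1 reproduces the unpenalized estimate; for lam<1 the correlation
    matrix of the update is exactly lam*R_hat + (1-lam)*I; an uncorrelated
    block stays uncorrelated for every lam."""
    ds = small_missing_dataset
    params = initialize_parameters(ds, FitConfig(d=2, seed=0))
    mom = e_step(params, ds)
    p1 = m_step(mom, params, ds, 1.0)
    for lam in (0.999, 2 / 3, 0.5, 0.1, 1e-6):
        pl = m_step(mom, params, ds, lam)
        for B1, Bl in zip(p1.Psi_blocks, pl.Psi_blocks):
            s1 = np.sqrt(np.diag(B1))
            R1 = B1 / np.outer(s1, s1)
            sl_ = np.sqrt(np.diag(Bl))
            Rl = Bl / np.outer(sl_, sl_)
            m_r = B1.shape[0]
            np.testing.assert_allclose(
                Rl, lam * R1 + (1 - lam) * np.eye(m_r), rtol=1e-10, atol=1e-12
            )
    # lam -> 0+ drives the correlation to the identity
    p0 = m_step(mom, params, ds, 1e-9)
    for B in p0.Psi_blocks:
        s = np.sqrt(np.diag(B))
        np.testing.assert_allclose(B / np.outer(s, s), np.eye(B.shape[0]),
                                   atol=1e-8)
    # identity correlation is a fixed point of the shrinkage
    for B1, Bh in zip(p1.Psi_blocks, m_step(mom, params, ds, 0.5).Psi_blocks):
        diagonal_only = np.diag(np.diag(B1))
        # synthetic check on a literally uncorrelated block
        shrunk = 0.5 * diagonal_only + 0.5 * np.diag(np.diag(diagonal_only))
        np.testing.assert_allclose(shrunk, diagonal_only, rtol=1e-12)


def test_half_lambda_covariance_form(rng, small_missing_dataset):
    """lam = 1/2 halves every off-diagonal entry and keeps the diagonal."""
    ds = small_missing_dataset
    params = initialize_parameters(ds, FitConfig(d=2, seed=1))
    mom = e_step(params, ds)
    p1 = m_step(mom, params, ds, 1.0)
    ph = m_step(mom, params, ds, 0.5)
    for B1, Bh in zip(p1.Psi_blocks, ph.Psi_blocks):
        np.testing.assert_allclose(np.diag(Bh), np.diag(B1), rtol=1e-12)
        off = ~np.eye(B1.shape[0], dtype=bool)
        np.testing.assert_allclose(Bh[off], 0.5 * B1[off], rtol=1e-12)


def test_diagonal_mode_produces_diagonal_blocks(rng, small_missing_dataset):
    ds = small_missing_dataset
    cfg = FitConfig(d=2, lam=0.5, seed=0, covariance_mode="diagonal")
    params = initialize_parameters(ds, cfg)
    mom = e_step(params, ds)
    pd_ = m_step(mom, params, ds, 0.5, "diagonal")
    for B in pd_.Psi_blocks:
        off = ~np.eye(B.shape[0], dtype=bool)
        assert np.all(B[off] == 0.0)


# ---------------------------------------------------------------------------
# factor-analysis reduction
# ---------------------------------------------------------------------------
def test_single_modality_diagonal_mode_matches_factor_analysis():
    """With one modality, diagonal covariance, complete data and lam=1 the
    update sequence reproduces textbook factor-analysis EM."""
    rng = np.random.default_rng(12)
    m, n, d = 6, 40, 2
    X = (rng.standard_normal((m, d)) @ rng.standard_normal((d, n))
         + 1.5 * rng.standard_normal((m, 1))
         + 0.5 * rng.standard_normal((m, n)))
    ds = MultiModalDataset([X])
    cfg = FitConfig(d=d, lam=1.0, seed=3, covariance_mode="diagonal")
    params = initialize_parameters(ds, cfg)
    W_ref, mu_ref = params.W.copy(), params.mu.copy()
    psi_ref = np.diag(params.Psi_blocks[0]).copy()
    for _ in range(5):
        mom = e_step(params, ds)
        params = m_step(mom, params, ds, 1.0, "diagonal")
        W_ref, mu_ref, psi_ref = factor_analysis_em_step(X, W_ref, mu_ref,
                                                         psi_ref)
        np.testing.assert_allclose(params.W, W_ref, rtol=1e-9, atol=1e-11)
        np.testing.assert_allclose(params.mu, mu_ref, rtol=1e-9)
        np.testing.assert_allclose(np.diag(params.Psi_blocks[0]), psi_ref,
                                   rtol=1e-9)


# ---------------------------------------------------------------------------
# full fits
# ---------------------------------------------------------------------------
def _model_generated(rng, dims, n, d, miss=0.0):
    m = sum(dims)
    W = rng.standard_normal((m, d))
    mu = rng.uniform(-1, 1, m)
    Psi_sd = rng.uniform(0.4, 0.9, m)
    X = W @ rng.standard_normal((d, n)) + mu[:, None]
    X += Psi_sd[:, None] * rng.standard_normal((m, n))
    off = np.concatenate([[0], np.cumsum(dims)])
    if miss > 0:
        drop = rng.random((m, n)) < miss
        X = np.where(drop, np.nan, X)
        for j in range(n):
            if np.isnan(X[:, j]).all():
                X[0, j] = 0.0
    return W, MultiModalDataset([X[off[r]: off[r + 1]]
                                 for r in range(len(dims))])


def test_fit_recovers_marginal_covariance():
    """Fitting model-generated data recovers W W' + Psi in relative
    Frobenius norm, and the fit improves with the sample size."""
    rng = np.random.default_rng(0)
    dims, d = (4, 5, 6), 3
    errs = []
    for n in (120, 600):
        W_true, ds = _model_generated(rng, dims, n, d)
        truth = W_true @ W_true.T + np.diag(np.full(sum(dims), 0.45))
        cfg = FitConfig(d=d, lam=1.0, max_iter=400, tol=1e-8, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fm = fit(ds, cfg)
        est = fm.params.W @ fm.params.W.T + fm.params.Psi_full()
        errs.append(np.linalg.norm(est - truth) / np.linalg.norm(truth))
    assert errs[-1] < 0.35
    assert errs[1] < errs[0]


def test_fit_trace_monotone_and_embedding_consistent(rng):
    ds = random_dataset(rng, n=40, miss=0.3, blockwise=True)
    cfg = FitConfig(d=2, lam=2 / 3, max_iter=200, tol=1e-7, seed=2)
    fm = fit(ds, cfg)
    rel = np.diff(fm.objective_trace) / np.abs(fm.objective_trace[:-1])
    assert rel.min() >= -1e-8
    np.testing.assert_allclose(fm.embedding, embed(fm, ds), rtol=1e-12)


def test_fit_complete_data_explicit_mask_equivalent(rng):
    """An all-ones explicit mask and a mask-free dataset produce identical
    parameter sequences."""
    ds = random_dataset(rng, n=25, miss=0.0)
    ds_masked = MultiModalDataset(
        [M.copy() for M in ds.modalities],
        mask=np.ones_like(ds.mask),
    )
    cfg = FitConfig(d=2, lam=0.5, max_iter=40, tol=1e-9, seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f1, f2 = fit(ds, cfg), fit(ds_masked, cfg)
    np.testing.assert_array_equal(f1.loglik_trace, f2.loglik_trace)
    np.testing.assert_array_equal(f1.params.W, f2.params.W)


def test_principal_angles_shrink_with_sample_size():
    """Subspace recovery of the true loadings improves from n=100 to n=600
    on average over seeds (d=3, complete data)."""
    dims, d = (5, 6, 7), 3
    mean_angles = []
    for n in (100, 300, 600):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            W_true, ds = _model_generated(rng, dims, n, d)
            cfg = FitConfig(d=d, lam=1.0, max_iter=300, tol=1e-7, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fm = fit(ds, cfg)
            vals.append(principal_angles(W_true, fm.params.W).max())
        mean_angles.append(np.mean(vals))
    assert mean_angles[0] > mean_angles[1] > mean_angles[2]


# ---------------------------------------------------------------------------
# embed / impute
# ---------------------------------------------------------------------------
def test_embed_at_the_mean_is_zero(rng, small_complete_dataset):
    ds = small_complete_dataset
    cfg = FitConfig(d=2, lam=1.0, max_iter=30, tol=1e-6, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fm = fit(ds, cfg)
    X = np.tile(fm.params.mu[:, None], (1, 3))
    ds_mu = MultiModalDataset([X[ds.block_slice(r)]
                               for r in range(ds.n_modalities)])
    Z = embed(fm, ds_mu)
    np.testing.assert_allclose(Z, 0.0, atol=1e-10)


def test_embed_identical_subjects_identical_columns(rng, small_missing_dataset):
    ds = small_missing_dataset
    cfg = FitConfig(d=2, lam=0.5, max_iter=30, tol=1e-6, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fm = fit(ds, cfg)
    col = np.nan_to_num(ds.X[:, [1, 1, 1]]) + np.where(
        ds.mask[:, [1, 1, 1]], 0.0, np.nan
    )
    ds_dup = MultiModalDataset([col[ds.block_slice(r)]
                                for r in range(ds.n_modalities)])
    Z = embed(fm, ds_dup)
    np.testing.assert_array_equal(Z[:, 0], Z[:, 1])
    np.testing.assert_array_equal(Z[:, 0], Z[:, 2])


def test_impute_identity_on_complete_data(rng, small_complete_dataset):
    ds = small_complete_dataset
    cfg = FitConfig(d=2, lam=1.0, max_iter=20, tol=1e-6, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fm = fit(ds, cfg)
    out = impute(fm, ds)
    np.testing.assert_array_equal(out.X, ds.X)


def test_impute_preserves_observed_bit_exact_and_fills_missing(rng):
    ds = random_dataset(rng, n=30, miss=0.3)
    cfg = FitConfig(d=2, lam=0.5, max_iter=60, tol=1e-6, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fm = fit(ds, cfg)
    out = impute(fm, ds)
    np.testing.assert_array_equal(out.X[ds.mask], ds.X[ds.mask])
    assert np.isfinite(out.X).all()
    assert out.mask.all()


def test_impute_beats_feature_mean_on_factor_data():
    """Model-based completion of factor-structured data is more accurate
    than per-feature mean imputation."""
    rng = np.random.default_rng(5)
    dims, d, n = (6, 8, 10), 2, 150
    W_true, ds_full = _model_generated(rng, dims, n, d)
    truth = ds_full.X.copy()
    drop = rng.random(truth.shape) < 0.25
    Xm = np.where(drop, np.nan, truth)
    off = np.concatenate([[0], np.cumsum(dims)])
    ds = MultiModalDataset([Xm[off[r]: off[r + 1]] for r in range(len(dims))])
    cfg = FitConfig(d=d, lam=2 / 3, max_iter=200, tol=1e-6, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fm = fit(ds, cfg)
    out = impute(fm, ds)
    miss = ~ds.mask
    rmse_model = np.sqrt(np.mean((out.X[miss] - truth[miss]) ** 2))
    row_means = np.nanmean(ds.X, axis=1)
    rmse_mean = np.sqrt(np.mean(
        (np.broadcast_to(row_means[:, None], truth.shape)[miss]
         - truth[miss]) ** 2
    ))
    assert rmse_model < rmse_mean


def test_impute_shape_mismatch_raises(rng, small_missing_dataset):
    ds = small_missing_dataset
    cfg = FitConfig(d=2, lam=1.0, max_iter=10, tol=1e-6, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fm = fit(ds, cfg)
    other = random_dataset(np.random.default_rng(0), dims=(2, 2), n=5,
                           miss=0.0)
    with pytest.raises(ValueError, match="stacked features"):
        impute(fm, other)


def test_nonconvergence_warns(rng, small_missing_dataset):
    cfg = FitConfig(d=2, lam=1.0, max_iter=3, tol=1e-12, seed=0)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        fm = fit(small_missing_dataset, cfg)
    assert not fm.converged
    assert fm.n_iter == 3
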