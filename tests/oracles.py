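"""Independent brute-force reference implementations used by the tests.

Everything here works on dense m x m matrices with direct inversion --
no Woodbury identities, no blockwise or Schur-complement shortcuts -- so it
is an independent check of the package's structured linear algebra.
"""

import numpy as np


def dense_posterior(W, mu, Psi, x, observed):
    """Latent posterior and completed-data moments for one subject, by
    direct dense inversion of the observed-row covariance.

    Returns a dict with Ez, Mz (posterior covariance of z), Ex (completed
    vector with factor-based imputation of missing rows), loglik.
    """
    W = np.asarray(W, float)
    mu = np.asarray(mu, float)
    Psi = np.asarray(Psi, float)
    x = np.asarray(x, float)
    o = np.flatnonzero(observed)
    mi = np.flatnonzero(~np.asarray(observed, bool))
    Wo = W[o]
    So = Wo @ Wo.T + Psi[np.ix_(o, o)]
    Soi = np.linalg.inv(So)
    delta = x[o] - mu[o]
    Ez = Wo.T @ Soi @ delta
    Mz = np.eye(W.shape[1]) - Wo.T @ Soi @ Wo
    Ex = x.copy()
    Ex[mi] = mu[mi] + W[mi] @ Ez
    sign, ld = np.linalg.slogdet(So)
    ll = -0.5 * (len(o) * np.log(2 * np.pi) + ld + delta @ Soi @ delta)
    return dict(Ez=Ez, Mz=Mz, Ex=Ex, loglik=ll)


def dense_loglik(W, mu, Psi, X, mask):
    """Observed-data log-likelihood summed over subjects, densely."""
    total = 0.0
    for k in range(X.shape[1]):
        total += dense_posterior(W, mu, Psi, np.nan_to_num(X[:, k]),
                                 mask[:, k])["loglik"]
    return total


def factor_analysis_em_step(X, W, mu, psi_diag):
    """One EM update of plain (single-block, diagonal-noise) factor analysis
    on complete data, written from the conditional-Gaussian identities:
    successive conditional updates of mu (at current W), then W, then the
    diagonal residual variances at the fresh (mu, W).
    """
    m, n = X.shape
    d = W.shape[1]
    Psi_inv = np.diag(1.0 / psi_diag)
    M = np.linalg.inv(np.eye(d) + W.T @ Psi_inv @ W)
    Ez = M @ W.T @ Psi_inv @ (X - mu[:, None])          # (d, n)
    sum_Ezz = n * M + Ez @ Ez.T
    mu_new = (X - W @ Ez).mean(axis=1)
    Xc = X - mu_new[:, None]
    W_new = (Xc @ Ez.T) @ np.linalg.inv(sum_Ezz)
    resid = Xc - W_new @ Ez
    psi_new = (resid * Xc).sum(axis=1) / n + np.einsum(
        "id,de,ie->i", W_new, M, W_new
    )
    # equivalent full form kept for clarity of what is being floored
    psi_full = (
        (Xc @ Xc.T) - Xc @ Ez.T @ W_new.T - W_new @ Ez @ Xc.T
        + W_new @ sum_Ezz @ W_new.T
    ) / n
    psi_new = np.diag(psi_full)
    return W_new, mu_new, np.maximum(psi_new, 1e-6)


def consensus_by_counting(labels):
    """Consensus matrix by literal pair counting (O(n^2 B))."""
    n, B = labels.shape
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = np.mean([labels[i, b] == labels[j, b] for b in range(B)])
    return C


def principal_angles(A, B):
    """Principal angles (radians) between the column spaces of A and B."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.arccos(np.clip(s, -1.0, 1.0))
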