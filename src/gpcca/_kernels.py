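"""Compiled inner loops for the per-subject missing-row corrections.

The E-step handles a partially observed modality block through a Schur
complement of the block precision on the *missing* rows, so the per-subject
work scales with the number of missing rows.  These loops are the only part
of the E-step that cannot be expressed as a handful of large BLAS calls;
with numba available they run as compiled per-subject loops over a CSR
layout of missing-row indices, otherwise the caller falls back to a padded,
batched numpy formulation.

All kernels accumulate in place into caller-provided arrays.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if len(args) == 1 and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def partial_phase1(P, W, A, U, cols, mptr, midx,
                   Qsum, ssum, quad, logdet):
    """Posterior corrections for subjects with a partially observed block.

    For each listed subject ``k`` with missing-row set ``mm`` inside this
    block, accumulates the exact corrections turning the full-block
    quantities (already added by the caller) into observed-row quantities:

      Q~ = Q_full + [-Wm'Am - Am'Wm + Wm'Pmm Wm - T' Pmm^{-1} T]
      s~ = s_full + [-Wm' g - T' Pmm^{-1} g]
      d'Psi~^{-1}d = d0'U  - g' Pmm^{-1} g
      log|Psi~|    = log|Psi| + log|Pmm|

    with ``P`` the block precision, ``A = P W``, ``U = P d0`` (d0 zero at
    missing rows), ``g = U[mm, k]``, ``T = A[mm] - Pmm W[mm]``.
    """
    d = W.shape[1]
    for t in range(cols.shape[0]):
        k = cols[t]
        lo, hi = mptr[t], mptr[t + 1]
        s = hi - lo
        idx = midx[lo:hi]
        Pmm = np.empty((s, s))
        g = np.empty(s)
        for a in range(s):
            ia = idx[a]
            g[a] = U[ia, k]
            for b in range(s):
                Pmm[a, b] = P[ia, idx[b]]
        Wm = W[idx]
        Am = A[idx]
        L = np.linalg.cholesky(Pmm)
        ld = 0.0
        for a in range(s):
            ld += np.log(L[a, a])
        T = Am - Pmm @ Wm
        rhs = np.empty((s, d + 1))
        rhs[:, :d] = T
        rhs[:, d] = g
        # forward then backward triangular solves against L L'
        for c in range(d + 1):
            for a in range(s):
                acc = rhs[a, c]
                for b in range(a):
                    acc -= L[a, b] * rhs[b, c]
                rhs[a, c] = acc / L[a, a]
            for a in range(s - 1, -1, -1):
                acc = rhs[a, c]
                for b in range(a + 1, s):
                    acc -= L[b, a] * rhs[b, c]
                rhs[a, c] = acc / L[a, a]
        H = np.ascontiguousarray(rhs[:, :d])
        h = np.ascontiguousarray(rhs[:, d])
        WmT = np.ascontiguousarray(Wm.T)
        TT = np.ascontiguousarray(T.T)
        WtAm = WmT @ Am
        Qc = -WtAm - WtAm.T + WmT @ (Pmm @ Wm) - TT @ H
        sc = WmT @ g + TT @ h
        Qsum[k] += Qc
        for a in range(d):
            ssum[k, a] -= sc[a]
        qc = 0.0
        for a in range(s):
            qc += g[a] * h[a]
        quad[k] -= qc
        logdet[k] += 2.0 * ld


@njit(cache=False)
def partial_phase2(W, Psi, Mk, cols, mptr, midx, CorrXX, CorrXZ):
    """Second-moment corrections on the missing rows of a block.

    Accumulates ``Wm M_k Wm' + Psi[mm, mm]`` into ``CorrXX`` and
    ``Wm M_k`` into ``CorrXZ`` for every listed subject.
    """
    for t in range(cols.shape[0]):
        k = cols[t]
        lo, hi = mptr[t], mptr[t + 1]
        s = hi - lo
        idx = midx[lo:hi]
        Wm = W[idx]
        WmM = Wm @ Mk[k]
        V = WmM @ Wm.T
        for a in range(s):
            ia = idx[a]
            for c in range(WmM.shape[1]):
                CorrXZ[ia, c] += WmM[a, c]
            for b in range(s):
                ib = idx[b]
                CorrXX[ia, ib] += V[a, b] + Psi[ia, ib]
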