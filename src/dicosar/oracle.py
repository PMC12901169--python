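"""Brute-force verification oracle for the worst-case ratio.

Independent of the semidefinite-relaxation solver: samples isotropic
complex Gaussian excitations on the feasible boundary (largest measured
quadratic form equal to one, where the maximum of a convex objective
lives), tracks per-objective-branch records, and polishes each
record-holder with a deterministic constrained local maximization.  The
result is a certified *lower* bound on the worst-case ratio, suitable for
sandwiching the solver on small instances (N <= 4-8; sampling is
exponentially inefficient in dimension, so this is a test instrument, not
a production path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize

from .array_model import VOPSet

__all__ = ["OracleResult", "oracle_max_ratio", "generalized_eig_ratio"]


@dataclass
class OracleResult:
    lower_bound_ratio: float
    best_excitation: np.ndarray
    n_samples: int
    seed: int


def _embed(Q: np.ndarray) -> np.ndarray:
    """Real 2N x 2N embedding of a Hermitian matrix (kept local so the
    oracle shares no code with the solver it checks)."""
    R, I = Q.real, Q.imag
    return np.block([[R, -I], [I, R]])


def _polish_branch(QR_j, QtR, z0, maxiter: int = 200):
    """Locally maximize ``z^T Q_j z`` over the measured ellipsoid
    intersection with SLSQP, then renormalize onto the boundary.

    SLSQP tracks the active constraint set, so corner maxima (several
    measured VOPs simultaneously tight) are reachable; plain gradient
    ascent on the boundary stalls there.  Deterministic for a fixed start.
    """
    cons = [
        {
            "type": "ineq",
            "fun": (lambda z, A=A: 1.0 - z @ A @ z),
            "jac": (lambda z, A=A: -2.0 * A @ z),
        }
        for A in QtR
    ]
    res = minimize(
        lambda z: -(z @ QR_j @ z),
        z0,
        jac=lambda z: -2.0 * QR_j @ z,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": maxiter, "ftol": 1e-12},
    )
    z = res.x if np.all(np.isfinite(res.x)) else z0
    m = max(z @ A @ z for A in QtR)
    if m <= 0:
        return None
    return z / np.sqrt(m)


def oracle_max_ratio(
    actual_vops: VOPSet,
    measured_vops: VOPSet,
    n_samples: int,
    seed: int,
) -> OracleResult:
    """Sampling + polish lower bound on the worst-case SAR ratio.

    Samples are normalized onto the boundary ``max_k x^H Qt_k x = 1`` and
    scored by every actual VOP separately.  Each time a sample sets a new
    record for some branch ``x^H Q_j x``, a deterministic constrained
    local maximization of that branch starts from it.  Because the polish
    starts are exactly the record-improvement events of the sample stream,
    extending the stream can only add starts, so the bound is
    non-decreasing in ``n_samples`` for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if actual_vops.n_channels != measured_vops.n_channels:
        raise ValueError("actual and measured VOP sets have different channel counts")
    n = actual_vops.n_channels
    actual = actual_vops.matrices
    measured = measured_vops.matrices
    QR = [_embed(Q) for Q in actual]
    QtR = [_embed(Q) for Q in measured]
    rng = np.random.default_rng(seed)

    n_actual = actual.shape[0]
    best_per_j = np.full(n_actual, -np.inf)
    best_val = -np.inf
    best_raw = None
    best_polished: tuple[float, np.ndarray] | None = None

    def consider(z):
        nonlocal best_polished
        vals = [z @ Q @ z for Q in QR]
        f = float(np.max(vals))
        if best_polished is None or f > best_polished[0]:
            best_polished = (f, z.copy())

    batch = 4096
    remaining = n_samples
    while remaining > 0:
        m = min(batch, remaining)
        remaining -= m
        X = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
        # boundary normalization: max_k x^H Qt_k x = 1
        mvals = np.einsum("si,kij,sj->ks", np.conj(X), measured, X).real.max(axis=0)
        ok = mvals > 0
        if not ok.any():
            continue
        X = X[ok] / np.sqrt(mvals[ok])[:, None]
        per_j = np.einsum("si,kij,sj->ks", np.conj(X), actual, X).real
        avals = per_j.max(axis=0)
        for i in range(avals.shape[0]):
            improved = np.nonzero(per_j[:, i] > best_per_j)[0]
            if improved.size:
                best_per_j = np.maximum(best_per_j, per_j[:, i])
                z0 = np.concatenate([X[i].real, X[i].imag])
                consider(z0)
                for j in improved:
                    z = _polish_branch(QR[j], QtR, z0)
                    if z is not None:
                        consider(z)
            if avals[i] > best_val:
                best_val = float(avals[i])
                best_raw = X[i]

    if best_raw is None:
        return OracleResult(0.0, np.zeros(n, complex), n_samples, seed)
    fbest, zbest = best_polished
    xbest = zbest[:n] + 1j * zbest[n:]
    return OracleResult(float(fbest), xbest, n_samples, seed)


def generalized_eig_ratio(Q, Qt) -> float:
    """Largest generalized eigenvalue of the Hermitian pencil (Q, Qt).

    Exact worst-case ratio for the single-constraint problem
    ``max x^H Q x s.t. x^H Qt x <= 1`` with positive-definite Qt.
    Computed by Cholesky whitening: ``lambda_max(L^-1 Q L^-H)`` with
    ``Qt = L L^H``.
    """
    Q = np.asarray(Q, dtype=complex)
    Qt = np.asarray(Qt, dtype=complex)
    try:
        L = cholesky(Qt, lower=True)
    except Exception as exc:
        raise ValueError(
            "constraint matrix is not positive definite; the ratio is "
            "unbounded (see the UNBOUNDED semantics of the worst-case solver)"
        ) from exc
    W = solve_triangular(L, Q, lower=True)
    W = solve_triangular(L, W.conj().T, lower=True).conj().T
    return float(np.linalg.eigvalsh(0.5 * (W + W.conj().T))[-1])
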