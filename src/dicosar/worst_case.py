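"""Worst-case SAR and forward-power underestimation solver.

The safety question: over *all* complex excitation vectors x, by how much
can the actual local SAR ``max_j x^H Q_j x`` exceed the SAR the supervision
system infers from coupler measurements, ``max_k x^H Q~_k x`` with
``Q~_k = M^H Q_k M``?  That worst-case ratio, per reference-plane phase
offset phi, is

    r(phi) = max_j  max_x  x^H Q_j x   subject to   x^H Q~_k x <= 1  for all k

For each actual VOP Q_j the inner problem maximizes a convex quadratic over
an intersection of ellipsoids.  The primary solution path is the
semidefinite relaxation (SDR): maximize ``tr(Q_j X)`` over Hermitian PSD X
with ``tr(Q~_k X) <= 1``.  We solve its *dual*,

    min  sum_k lambda_k   s.t.   sum_k lambda_k Q~_k >= Q_j  (PSD order),
    lambda >= 0,

by Kelley cutting planes: the semidefinite constraint is replaced by the
scalar cuts ``sum_k lambda_k v^H Q~_k v >= v^H Q_j v`` generated from the
most-negative eigenvectors of ``sum lambda Q~ - Q`` at each LP iterate.
Any dual-feasible point upper-bounds the true maximum; an epsilon-infeasible
iterate is certified by shifting lambda along the all-ones direction (valid
because ``sum_k Q~_k`` is positive definite on the working subspace).  A
feasible excitation is extracted from the null direction of the dual slack
matrix and polished by projected ascent, giving a lower bound.  The result
carries both: ``ratio`` is the relaxation bound and ``certificate_gap`` the
relative distance to the extracted feasible point, so the answer is
sandwiched rather than trusted.

The total-forward-power error is the same question with the identity
matrix in place of the VOP set and has the closed form
``1 / lambda_min(M^H M)``.

The phase offset enters non-convexly, so phi is swept on a uniform grid
(360 steps over [0, 2pi) by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

try:  # incremental HiGHS interface: warm-started LP re-solves in the
    # cutting-plane loop; fall back to repeated linprog calls without it
    from scipy.optimize._highspy import _core as _highs_core
except ImportError:  # pragma: no cover - depends on scipy build
    _highs_core = None

from .array_model import SMatrix, VOPSet
from .config import DEFAULT, Tolerances
from .coupler import CouplerModel, ErrorMatrix, build_error_matrix, transform_vops

__all__ = [
    "RealEmbeddedMatrix",
    "WorstCaseResult",
    "PhaseSweepResult",
    "UnboundedError",
    "SolverFailure",
    "real_embed",
    "max_ratio_at_phase",
    "max_ratio_for_error_matrix",
    "phase_sweep",
    "power_error_at_phase",
    "power_error_sweep",
]


class UnboundedError(RuntimeError):
    """A direction exists with positive actual SAR but zero measured SAR.

    Possible only with a singular custom error matrix or a rank-deficient
    measured VOP set; the worst-case ratio is infinite.
    """


class SolverFailure(RuntimeError):
    """The worst-case optimizer did not converge; diagnostics in the message."""


@dataclass(frozen=True)
class RealEmbeddedMatrix:
    """Real 2N x 2N embedding of a Hermitian matrix.

    Block structure ``[[Re Q, -Im Q], [Im Q, Re Q]]``; for the real
    stacking z = (Re x; Im x) of any complex vector, ``z^T Q_R z`` equals
    ``x^H Q x``.
    """

    values: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.values.shape[0] // 2


def real_embed(Q, tol: Tolerances = DEFAULT) -> RealEmbeddedMatrix:
    """Embed a complex Hermitian matrix as a real symmetric 2N x 2N matrix."""
    Q = np.asarray(Q, dtype=complex)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {Q.shape}")
    scale = max(np.abs(Q).max(), 1e-300)
    if np.abs(Q - Q.conj().T).max() > tol.hermiticity * scale:
        raise ValueError("matrix is not Hermitian within tolerance")
    R, I = Q.real, Q.imag
    top = np.hstack([R, -I])
    bot = np.hstack([I, R])
    return RealEmbeddedMatrix(np.vstack([top, bot]))


@dataclass
class WorstCaseResult:
    """Worst-case underestimation ratio with its optimality certificate.

    ``ratio`` is the semidefinite-relaxation upper bound (the safe value to
    build a safety factor from); ``argmax_excitation`` is a feasible
    excitation achieving at least ``ratio * (1 - certificate_gap)``,
    normalized so the largest measured-VOP quadratic form equals one.
    """

    ratio: float
    argmax_vop_index: int
    argmax_excitation: np.ndarray
    solver_status: str
    certificate_gap: float
    per_vop_ratios: np.ndarray | None = None


@dataclass
class PhaseSweepResult:
    """Worst-case ratio as a function of the reference-plane phase offset."""

    phases_rad: np.ndarray
    ratios: np.ndarray
    results: list = field(default_factory=list)

    def __post_init__(self):
        self.phases_rad = np.asarray(self.phases_rad, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.phases_rad.shape != self.ratios.shape:
            raise ValueError("phase grid and ratio vector lengths differ")

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.ratios))

    @property
    def peak_ratio(self) -> float:
        return float(self.ratios[self.peak_index])

    @property
    def peak_phase_rad(self) -> float:
        return float(self.phases_rad[self.peak_index])

    def percent(self, convention: str = "of-actual") -> np.ndarray:
        from .coupler import ratio_to_percent

        return ratio_to_percent(self.ratios, convention)

    def peak_percent(self, convention: str = "of-actual") -> float:
        from .coupler import ratio_to_percent

        return float(ratio_to_percent(self.peak_ratio, convention))


# ---------------------------------------------------------------------------
# inner QCQP via the dual of the semidefinite relaxation
# ---------------------------------------------------------------------------


def _quad(Q: np.ndarray, x: np.ndarray) -> float:
    return float(np.real(np.conj(x) @ Q @ x))


class _DualLP:
    """Restricted dual LP ``min sum(lam) s.t. B lam >= a, lam >= 0``.

    Rows (cuts) are added incrementally; with the HiGHS handle available
    each re-solve warm-starts from the previous simplex basis.
    """

    def __init__(self, K: int):
        self.K = K
        self._a: list[float] = []
        self._b: list[np.ndarray] = []
        self._idx = np.arange(K, dtype=np.int64)
        if _highs_core is not None:
            h = _highs_core._Highs()
            h.setOptionValue("output_flag", False)
            empty_i = np.array([], dtype=np.int64)
            h.addCols(
                K,
                np.ones(K),
                np.zeros(K),
                np.full(K, _highs_core.kHighsInf),
                0,
                empty_i,
                empty_i,
                np.array([]),
            )
            self._h = h
        else:
            self._h = None

    def add_row(self, a_v: float, b_row: np.ndarray) -> None:
        self._a.append(a_v)
        self._b.append(b_row)
        if self._h is not None:
            self._h.addRow(a_v, _highs_core.kHighsInf, self.K, self._idx, b_row)

    def solve(self) -> np.ndarray:
        if self._h is not None:
            status = self._h.run()
            model_status = self._h.getModelStatus()
            if model_status != _highs_core.HighsModelStatus.kOptimal:
                raise SolverFailure(
                    f"dual LP failed (HiGHS status {status}, model {model_status})"
                )
            return np.asarray(self._h.getSolution().col_value)
        res = linprog(
            c=np.ones(self.K),
            A_ub=-np.asarray(self._b),
            b_ub=-np.asarray(self._a),
            bounds=[(0, None)] * self.K,
            method="highs",
        )
        if res.status != 0:
            raise SolverFailure(f"dual LP failed (status {res.status}): {res.message}")
        return res.x

    def row_slacks(self, lam: np.ndarray) -> np.ndarray:
        return np.asarray(self._b) @ lam - np.asarray(self._a)

    @property
    def a_scale(self) -> float:
        return max(1.0, float(np.abs(np.asarray(self._a)).max()))


def _dual_sdr(Q, Qts, tol: float, max_iter: int = 400, initial_cuts=None):
    """Cutting-plane solution of ``min sum(lam) s.t. sum lam_k Qt_k >= Q``.

    Requires ``sum_k Qt_k`` positive definite (caller reduces to that
    subspace).  Returns ``(upper_bound, slack_null_vector, n_iter)`` where
    the upper bound is certified dual-feasible and the null vector spans
    the near-null space of the optimal slack matrix (the primal support).
    """
    Qts = np.asarray(Qts)
    K, n = Qts.shape[0], Qts.shape[1]
    Tsum = Qts.sum(axis=0)
    sigma = float(np.linalg.eigvalsh(Tsum)[0])
    if sigma <= 0:
        raise SolverFailure("measured VOP sum not positive definite on subspace")

    # initial cuts: leading eigenvectors of Q (directions of large actual SAR)
    w_q, V_q = np.linalg.eigh(Q)
    n_init = min(n, 4)
    cuts = [np.ascontiguousarray(V_q[:, -(i + 1)]) for i in range(n_init)]

    lp = _DualLP(K)
    cut_vecs: list[np.ndarray] = []

    def add_cut(v: np.ndarray):
        nv = np.linalg.norm(v)
        if nv == 0:
            return
        v = v / nv
        lp.add_row(_quad(Q, v), np.array([_quad(Qts[k], v) for k in range(K)]))
        cut_vecs.append(v)

    for v in cuts:
        add_cut(v)
    if initial_cuts is not None:
        for v in initial_cuts:
            add_cut(np.asarray(v, dtype=complex))

    def active_cuts(lam):
        """Cut vectors whose LP constraints are tight at lam (warm-start set)."""
        idx = np.nonzero(lp.row_slacks(lam) <= 1e-6 * lp.a_scale)[0]
        return [cut_vecs[i] for i in idx[: 3 * K]]

    lam = np.zeros(K)
    best_ub = np.inf
    best_vmin = cuts[0]
    stall = 0
    for it in range(max_iter):
        lam = lp.solve()
        A = np.tensordot(lam, Qts, axes=1) - Q
        w, V = np.linalg.eigh(A)
        delta = float(w[0])
        vmin = np.ascontiguousarray(V[:, 0])
        obj = float(lam.sum())
        slack = max(0.0, -delta)
        # certify dual feasibility by the cheaper of two shifts:
        # additive along ones (sum Qt >= sigma I) or multiplicative along
        # lam (sum lam Qt = A + Q >= omega I)
        ub_now = obj + slack / sigma * K
        omega = float(np.linalg.eigvalsh(A + Q)[0])
        if omega > 0:
            ub_now = min(ub_now, obj * (1.0 + slack / omega))
        if ub_now < best_ub - tol * max(obj, tol) * 0.01:
            best_ub, best_vmin, stall = ub_now, vmin, 0
        else:
            best_ub = min(best_ub, ub_now)
            stall += 1
        if best_ub - obj <= tol * max(obj, tol):
            return best_ub, best_vmin, it + 1, active_cuts(lam)
        if stall >= 15:
            # Kelley tail exhausted; the certified bound is still valid,
            # only its distance to the LP objective exceeds the target
            return best_ub, best_vmin, it + 1, active_cuts(lam)
        # cut on every appreciably violated eigen-direction (at most 4)
        neg = np.nonzero(w < -0.25 * slack)[0][:4]
        for idx in neg:
            add_cut(np.ascontiguousarray(V[:, idx]))
    return best_ub, best_vmin, max_iter, active_cuts(lam)


def _polish_excitation(Q, Qts, x, n_iter: int = 100):
    """Projected-ascent polish of the ratio ``x^H Q x / max_k x^H Qt_k x``.

    Deterministic: fixed iteration count, step grown on improvement and
    halved otherwise.  Returns the excitation normalized to unit measured
    SAR and the achieved (lower-bound) ratio.
    """

    def measured(xv):
        return max(_quad(Qt, xv) for Qt in Qts)

    m = measured(x)
    if m <= 0:
        return x, 0.0
    x = x / np.sqrt(m)
    f = _quad(Q, x)
    step = 0.2
    for _ in range(n_iter):
        forms = [_quad(Qt, x) for Qt in Qts]
        kstar = int(np.argmax(forms))
        g = Q @ x - f * (Qts[kstar] @ x)
        gn = np.linalg.norm(g)
        if gn < 1e-14:
            break
        cand = x + step * (g / gn)
        mc = measured(cand)
        if mc <= 0:
            step *= 0.5
            continue
        cand = cand / np.sqrt(mc)
        fc = _quad(Q, cand)
        if fc > f:
            x, f = cand, fc
            step *= 1.2
        else:
            step *= 0.5
    return x, f


def _reduce_subspace(actual, measured, tol_null: float):
    """Restrict to the orthogonal complement of the common null space of
    the measured VOPs.

    Directions with zero measured SAR are safe only if the actual SAR there
    is also zero; otherwise the worst-case ratio is unbounded.
    Returns ``(basis, actual_r, measured_r)`` with ``basis`` mapping reduced
    coordinates back to channel space, or ``None`` for the basis when no
    reduction is needed.
    """
    T = measured.sum(axis=0)
    w, V = np.linalg.eigh(T)
    scale = max(float(w[-1]), 0.0)
    null_mask = w <= tol_null * max(scale, tol_null)
    if not null_mask.any():
        return None, actual, measured
    act_scale = max(float(np.abs(actual).max()), tol_null)
    for v in V[:, null_mask].T:
        worst_actual = max(_quad(Qj, v) for Qj in actual)
        if worst_actual > 1e-8 * act_scale:
            raise UnboundedError(
                "a direction with positive actual SAR has zero measured SAR "
                "for every VOP; the worst-case ratio is unbounded"
            )
    B = V[:, ~null_mask]
    if B.shape[1] == 0:
        return B, None, None  # everything is null and harmless
    Bh = B.conj().T
    actual_r = np.einsum("ij,kjl,lm->kim", Bh, actual, B)
    measured_r = np.einsum("ij,kjl,lm->kim", Bh, measured, B)
    return B, actual_r, measured_r


def max_ratio_for_error_matrix(
    vops: VOPSet, M: ErrorMatrix, tol: Tolerances = DEFAULT, _warm=None
) -> WorstCaseResult:
    """Worst-case ratio of actual to measured SAR bound for a given error matrix.

    Runs the inner SDR maximization once per actual VOP and takes the
    maximum (ties broken toward the lowest index).  Works for any square
    error matrix, not only the coupler model.
    """
    if len(vops) < 1:
        raise ValueError("need at least one VOP")
    measured_set = transform_vops(vops, M)

    # scale-free: normalize by the largest spectral norm in the actual set
    norms = [float(np.linalg.norm(Q, 2)) for Q in vops]
    s = max(norms)
    if s <= 0:
        # all-zero SAR everywhere; measurement cannot misestimate nothing
        n = vops.n_channels
        return WorstCaseResult(1.0, 0, np.zeros(n, complex), "degenerate", 0.0)
    actual = vops.matrices / s
    measured = measured_set.matrices / s

    basis, actual_r, measured_r = _reduce_subspace(actual, measured, tol.psd)
    if actual_r is None:
        n = vops.n_channels
        return WorstCaseResult(1.0, 0, np.zeros(n, complex), "degenerate", 0.0)

    K = actual_r.shape[0]
    ratios = np.empty(K)
    best = None
    warm_out = []
    for j in range(K):
        init = None
        if _warm is not None and _warm[j] is not None:
            if basis is None:
                init = list(_warm[j])
            else:
                init = [basis.conj().T @ v for v in _warm[j]]
        ub, vnull, _, active = _dual_sdr(
            actual_r[j], measured_r, tol.solver, initial_cuts=init
        )
        x_j, lb = _polish_excitation(actual_r[j], measured_r, vnull)
        back = (lambda v: v) if basis is None else (lambda v: basis @ v)
        warm_out.append([back(x_j)] + [back(v) for v in active])
        ratios[j] = ub
        if best is None or ub > best[0]:
            best = (ub, lb, j, x_j)

    ub, lb, j_star, x_r = best
    gap = max(0.0, (ub - lb) / ub) if ub > 0 else 0.0
    x = x_r if basis is None else basis @ x_r
    status = "optimal" if gap <= 1e-4 else "optimal_with_gap"
    result = WorstCaseResult(
        ratio=float(ub),
        argmax_vop_index=int(j_star),
        argmax_excitation=x,
        solver_status=status,
        certificate_gap=float(gap),
        per_vop_ratios=ratios,
    )
    result._warm_out = warm_out
    return result


def max_ratio_at_phase(
    vops: VOPSet, S: SMatrix, coupler: CouplerModel, tol: Tolerances = DEFAULT
) -> WorstCaseResult:
    """Worst-case SAR underestimation ratio at one reference-plane phase."""
    if S.n_channels != vops.n_channels:
        raise ValueError(
            f"S-matrix has {S.n_channels} channels, VOP set has {vops.n_channels}"
        )
    M = build_error_matrix(S, coupler)
    return max_ratio_for_error_matrix(vops, M, tol)


def phase_sweep(
    vops: VOPSet,
    S: SMatrix,
    directivity_db,
    n_steps: int = 360,
    attenuation: float = 1.0,
    tol: Tolerances = DEFAULT,
) -> PhaseSweepResult:
    """Sweep the reference-plane phase offset over a uniform grid on [0, 2pi).

    The worst case over phi is non-convex, so it is located by exhaustive
    grid search; 360 steps (1 degree) is the default resolution.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    phases = 2.0 * np.pi * np.arange(n_steps) / n_steps
    ratios = np.empty(n_steps)
    results = []
    warm = None  # feasible excitations from the previous phase seed the cuts
    for i, phi in enumerate(phases):
        coupler = CouplerModel(directivity_db, phi, attenuation)
        M = build_error_matrix(S, coupler)
        try:
            res = max_ratio_for_error_matrix(vops, M, tol, _warm=warm)
        except (UnboundedError, SolverFailure) as exc:
            raise type(exc)(f"{exc} [at phase {phi:.6f} rad, step {i}]") from exc
        warm = res._warm_out
        ratios[i] = res.ratio
        results.append(res)
    return PhaseSweepResult(phases, ratios, results)


def power_error_at_phase(
    S: SMatrix, coupler: CouplerModel, tol: Tolerances = DEFAULT
) -> float:
    """Worst-case underestimation ratio of *total forward power*.

    The measured total power is ``x^H M^H M x`` against an actual
    ``x^H x``, so the worst ratio over excitations is
    ``1 / lambda_min(M^H M)`` — identical to running the SAR solver with a
    single identity VOP, but in closed form.
    """
    M = build_error_matrix(S, coupler).values
    lam_min = float(np.linalg.eigvalsh(M.conj().T @ M)[0])
    if lam_min <= tol.psd:
        raise UnboundedError(
            "error matrix is singular: measured total power can vanish for a "
            "nonzero excitation"
        )
    return 1.0 / lam_min


def power_error_sweep(
    S: SMatrix,
    directivity_db,
    n_steps: int = 360,
    attenuation: float = 1.0,
    tol: Tolerances = DEFAULT,
) -> PhaseSweepResult:
    """Phase sweep of the total-forward-power underestimation ratio."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    phases = 2.0 * np.pi * np.arange(n_steps) / n_steps
    ratios = np.empty(n_steps)
    for i, phi in enumerate(phases):
        coupler = CouplerModel(directivity_db, phi, attenuation)
        try:
            ratios[i] = power_error_at_phase(S, coupler, tol)
        except UnboundedError as exc:
            raise UnboundedError(f"{exc} [at phase {phi:.6f} rad, step {i}]") from exc
    return PhaseSweepResult(phases, ratios, [])
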