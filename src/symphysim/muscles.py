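"""Hill-type muscle force evaluation and static optimization of muscle redundancy.

Each muscle produces ``F = a * F0 * f_L(L/L_opt) * f_v(v) * cos(alpha)`` with
activation ``a``, maximum isometric force ``F0``, active force-length factor
``f_L``, force-velocity factor ``f_v`` and pennation angle ``alpha`` (rigid
tendon).  Static optimization distributes prescribed joint moments across the
muscles by minimizing the sum of squared activations

    min sum_i a_i^2   s.t.   sum_i a_i F_i^max r_ij = Q_j,   0.01 <= a_i <= 1,

where ``F_i^max = F0_i f_L f_v cos(alpha_i)`` is the force at full activation
at the frozen (static) length and velocity, and ``r_ij`` the moment arm of
muscle ``i`` about joint axis ``j``.  The quadratic program has a diagonal
Hessian and is solved exactly with an active-set scheme; infeasible moment
targets raise :class:`InfeasibleMomentsError` carrying the minimal-residual
bounded least-squares solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MuscleDef",
    "StaticOptProblem",
    "ActivationSolution",
    "InfeasibleMomentsError",
    "fl_gaussian",
    "fv_hyperbolic",
    "hill_force",
    "max_force_factor",
    "solve_static_opt",
    "force_table",
]

ACTIVATION_BOUNDS = (0.01, 1.0)

#: Width of the Gaussian active force-length curve (normalized fiber length).
FL_WIDTH = 0.45


def fl_gaussian(l_norm, width: float = FL_WIDTH):
    """Gaussian active force-length factor, peak 1 at optimal fiber length."""
    l_norm = np.asarray(l_norm, dtype=float)
    out = np.exp(-(((l_norm - 1.0) / width) ** 2))
    return float(out) if out.ndim == 0 else out


def fv_hyperbolic(v_norm, kappa: float = 0.25):
    """Saturating hyperbolic force-velocity factor, f_v(0) = 1.

    ``v_norm`` is the contraction velocity normalized by the maximum
    shortening velocity (positive = shortening).  Shortening follows the
    classic hyperbola ``(1 - v)/(1 + v/kappa)``; lengthening saturates at 1.4.
    """
    v = np.asarray(v_norm, dtype=float)
    shortening = np.clip((1.0 - v) / (1.0 + v / kappa), 0.0, None)
    lengthening = 1.4 - 0.4 * (1.0 + v) / (1.0 - 7.56 * v / kappa)
    out = np.where(v >= 0, shortening, lengthening)
    return float(out) if out.ndim == 0 else out


@dataclass
class MuscleDef:
    """One muscle-tendon actuator (rigid tendon, static configuration)."""

    name: str
    F0: float  # maximum isometric force, N
    L_opt: float = 100.0  # optimal fiber length, mm
    L: float | None = None  # current fiber length, mm (default: optimal)
    v: float = 0.0  # contraction velocity, mm/s (positive = shortening)
    alpha: float = 0.0  # pennation angle, rad
    Lslack: float = 0.0  # tendon slack length, mm
    attachment: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm
    moment_arms: np.ndarray = field(default_factory=lambda: np.zeros(1))  # mm, per axis
    v_max_factor: float = 10.0  # max shortening velocity in optimal lengths / s

    def __post_init__(self):
        if self.F0 <= 0:
            raise ValueError(f"{self.name}: F0 must be positive")
        if self.L_opt <= 0:
            raise ValueError(f"{self.name}: L_opt must be positive")
        if abs(self.alpha) >= math.pi / 2:
            raise ValueError(f"{self.name}: |alpha| must be below pi/2")
        if self.L is None:
            self.L = self.L_opt
        self.attachment = np.asarray(self.attachment, dtype=float)
        self.moment_arms = np.atleast_1d(np.asarray(self.moment_arms, dtype=float))


def max_force_factor(
    m: MuscleDef,
    f_L: Callable[[float], float] = fl_gaussian,
    f_v: Callable[[float], float] = fv_hyperbolic,
) -> float:
    """Force at full activation: F0 * f_L(L/L_opt) * f_v(v_norm) * cos(alpha)."""
    v_norm = m.v / (m.v_max_factor * m.L_opt)
    return m.F0 * f_L(m.L / m.L_opt) * f_v(v_norm) * math.cos(m.alpha)


def hill_force(
    m: MuscleDef,
    a: float,
    f_L: Callable[[float], float] = fl_gaussian,
    f_v: Callable[[float], float] = fv_hyperbolic,
) -> float:
    """Muscle force (N) at activation ``a`` in [0, 1]."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    return a * max_force_factor(m, f_L, f_v)


@dataclass
class StaticOptProblem:
    """Moment-matching activation problem over a set of muscles."""

    muscles: Sequence[MuscleDef]
    Q: np.ndarray  # target joint moments, N*mm, one per axis
    bounds: tuple[float, float] = ACTIVATION_BOUNDS
    f_L: Callable[[float], float] = fl_gaussian
    f_v: Callable[[float], float] = fv_hyperbolic

    def __post_init__(self):
        self.Q = np.atleast_1d(np.asarray(self.Q, dtype=float))
        lo, hi = self.bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("activation bounds must satisfy 0 <= lo < hi <= 1")
        if self.Q.size < 1:
            raise ValueError("at least one moment axis required")

    def moment_matrix(self) -> np.ndarray:
        """R[j, i] = F_i^max * r_ij so that R @ a = Q."""
        R = np.empty((self.Q.size, len(self.muscles)))
        for i, m in enumerate(self.muscles):
            arms = m.moment_arms
            if arms.size != self.Q.size:
                raise ValueError(
                    f"{m.name}: {arms.size} moment arms for {self.Q.size} axes"
                )
            R[:, i] = max_force_factor(m, self.f_L, self.f_v) * arms
        return R


@dataclass
class ActivationSolution:
    a: np.ndarray  # activation per muscle
    forces: np.ndarray  # N per muscle
    residual: float  # max moment-constraint violation, N*mm
    objective: float  # sum a_i^2
    converged: bool = True


class InfeasibleMomentsError(RuntimeError):
    """Moment targets unreachable within activation bounds.

    Carries ``solution``: the minimal-residual activation vector found by
    bounded least squares.
    """

    def __init__(self, msg: str, solution: ActivationSolution):
        super().__init__(msg)
        self.solution = solution


def _qp_box_eq(R: np.ndarray, Q: np.ndarray, lo: float, hi: float, tol: float = 1e-10):
    """min ||a||^2 s.t. R a = Q, lo <= a <= hi — exact active-set on bounds.

    With a diagonal Hessian, the free variables of any working set solve the
    minimum-norm equality problem on the reduced system; bound multipliers are
    checked from the KKT stationarity 2 a + R^T lam + mu = 0.
    """
    n = R.shape[1]
    at_lo = np.zeros(n, dtype=bool)
    at_hi = np.zeros(n, dtype=bool)
    for _ in range(4 * n + 8):
        free = ~(at_lo | at_hi)
        a = np.where(at_lo, lo, 0.0) + np.where(at_hi, hi, 0.0)
        rhs = Q - R @ a
        if free.any():
            Rf = R[:, free]
            # minimum-norm solution of Rf x = rhs
            x, *_ = np.linalg.lstsq(Rf, rhs, rcond=None)
            a[free] = x
        # equality constraints must hold for the working set to be valid
        if np.max(np.abs(R @ a - Q)) > tol * max(1.0, np.max(np.abs(Q))):
            return a, False
        viol_lo = free & (a < lo - 1e-12)
        viol_hi = free & (a > hi + 1e-12)
        if viol_lo.any() or viol_hi.any():
            # clamp the worst violator and re-solve
            dev = np.where(viol_lo, lo - a, 0.0) + np.where(viol_hi, a - hi, 0.0)
            k = int(np.argmax(dev))
            if a[k] < lo:
                at_lo[k] = True
            else:
                at_hi[k] = True
            continue
        # KKT: recover lam from the free block, check bound multipliers
        if free.any():
            lam, *_ = np.linalg.lstsq(R[:, free].T, -2.0 * a[free], rcond=None)
        else:
            lam = np.zeros(R.shape[0])
        g = 2.0 * a + R.T @ lam  # = -mu_lo + mu_hi
        release = None
        worst = -1e-9
        for k in range(n):
            if at_lo[k] and g[k] < worst:  # mu_lo < 0
                worst, release = g[k], ("lo", k)
            if at_hi[k] and -g[k] < worst:
                worst, release = -g[k], ("hi", k)
        if release is None:
            return a, True
        side, k = release
        (at_lo if side == "lo" else at_hi)[k] = False
    return a, False


def solve_static_opt(p: StaticOptProblem, tol: float = 1e-6) -> ActivationSolution:
    """Solve the static-optimization quadratic program.

    Returns the activation vector minimizing ``sum a_i^2`` under the joint
    moment-balance equalities and the activation box; KKT conditions hold to
    the solver tolerance.  Deterministic (no random initialization).

    Raises
    ------
    InfeasibleMomentsError
        If no activation in the box balances the moments; the error carries
        the minimal-residual bounded least-squares solution.
    """
    from scipy.optimize import lsq_linear

    R = p.moment_matrix()
    lo, hi = p.bounds
    a, ok = _qp_box_eq(R, p.Q, lo, hi)
    if ok:
        a = np.clip(a, lo, hi)
        resid = float(np.max(np.abs(R @ a - p.Q)))
        if resid <= tol * max(1.0, float(np.max(np.abs(p.Q)))):
            forces = np.array([hill_force(m, ai, p.f_L, p.f_v) for m, ai in zip(p.muscles, a)])
            return ActivationSolution(a, forces, resid, float(a @ a))
    res = lsq_linear(R, p.Q, bounds=(lo, hi))
    a = np.clip(res.x, lo, hi)
    resid = float(np.max(np.abs(R @ a - p.Q)))
    if resid <= tol * max(1.0, float(np.max(np.abs(p.Q)))):
        # feasible but the active-set pass stalled: polish the objective
        from scipy.optimize import minimize

        res2 = minimize(
            lambda x: x @ x,
            a,
            jac=lambda x: 2.0 * x,
            bounds=[(lo, hi)] * R.shape[1],
            constraints={"type": "eq", "fun": lambda x: R @ x - p.Q, "jac": lambda x: R},
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        a = np.clip(res2.x, lo, hi)
        resid = float(np.max(np.abs(R @ a - p.Q)))
        forces = np.array([hill_force(m, ai, p.f_L, p.f_v) for m, ai in zip(p.muscles, a)])
        return ActivationSolution(a, forces, resid, float(a @ a))
    forces = np.array([hill_force(m, ai, p.f_L, p.f_v) for m, ai in zip(p.muscles, a)])
    fallback = ActivationSolution(a, forces, resid, float(a @ a), converged=False)
    raise InfeasibleMomentsError(
        f"moment targets infeasible within activation bounds "
        f"(minimal residual {resid:.4g} N*mm)",
        fallback,
    )


def force_table(sol: ActivationSolution, muscles: Sequence[MuscleDef]) -> pd.DataFrame:
    """Per-muscle force table (name, activation, force_N), CSV-serializable."""
    return pd.DataFrame(
        {
            "name": [m.name for m in muscles],
            "activation": sol.a,
            "force_N": sol.forces,
        }
    )
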