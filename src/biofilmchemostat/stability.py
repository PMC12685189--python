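"""Equilibria, linear stability, mu sweeps, and Hopf detection.

The maximum growth rate ``mu`` acts as a bifurcation parameter.  Sweeping it
produces four regimes in order: washout (growth cannot offset dilution),
cheater exclusion (cooperators persist, the cheater cannot invade), a narrow
band of stable limit cycles, and steady full coexistence.  The cycles are
born at a supercritical Hopf bifurcation: a complex-conjugate eigenvalue pair
of the Jacobian at the coexistence equilibrium crosses the imaginary axis.

``detect_hopf`` locates the crossing by bisection on the real part of the
leading complex pair, following the equilibrium branch by continuation
(each equilibrium solve is seeded from the previous ``mu``'s solution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import (ParameterSet, SystemState, rhs_array,
                    analytic_jacobian, STABLE_MEDIANS)
from .simulate import SolverSettings, integrate, final_window_extrema
from .classify import classify_final_state

__all__ = [
    "EquilibriumPoint",
    "BifurcationScan",
    "find_equilibrium",
    "linearize",
    "numerical_jacobian",
    "leading_complex_eigenvalue",
    "mu_sweep",
    "detect_hopf",
    "SWEEP_PARAMS",
    "CYCLE_TOLERANCE",
]

#: Modified reference parameter set for the growth-rate sweep: biofilm enzyme
#: capacity reduced to 0.13 and influent nutrient to 0.5 (mu is overridden
#: per scan point).
SWEEP_PARAMS = STABLE_MEDIANS.replace(E2_max=0.13, S0=0.5)

RESIDUAL_TOL = 1e-10    # equilibrium residual norm to count as converged
CYCLE_TOLERANCE = 1e-3  # max-min amplitude above which a variant "cycles"


@dataclass(frozen=True)
class EquilibriumPoint:
    state: SystemState
    residual_norm: float
    converged: bool


@dataclass
class BifurcationScan:
    """Per-mu records of final-window extrema, regime label, and spectrum."""

    mu_values: np.ndarray
    extrema: list[dict[str, tuple[float, float]]]
    regimes: list[str]
    eigenvalues: list[np.ndarray]          # full 6-spectrum per mu
    leading_pair: list[complex]            # leading complex eigenvalue per mu
    base_params: ParameterSet
    failures: dict[int, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, mu in enumerate(self.mu_values):
            lead = self.leading_pair[i]
            for var in ("X1", "X2", "X3"):
                lo, hi = self.extrema[i][var]
                rows.append({"mu": float(mu), "variant": var,
                             "min": lo, "max": hi,
                             "regime": self.regimes[i],
                             "re_lambda1": float(np.real(lead)),
                             "im_lambda1": float(np.imag(lead))})
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def find_equilibrium(params: ParameterSet,
                     seed_state: SystemState | np.ndarray,
                     residual_tol: float = RESIDUAL_TOL) -> EquilibriumPoint:
    """Locate a root of the vector field near ``seed_state``.

    Damped Newton iteration (hybrid Powell) from the seed, typically the
    endpoint of a long integration.  Non-convergence is flagged, not raised.
    """
    y0 = seed_state.to_array() if isinstance(seed_state, SystemState) else np.asarray(seed_state, float)
    if np.any(y0 < 0):
        raise ValueError("seed state must be nonnegative")
    sol = root(lambda y: rhs_array(y, params), y0, method="hybr",
               jac=lambda y: analytic_jacobian(y, params), tol=1e-13)
    resid = float(np.linalg.norm(rhs_array(sol.x, params)))
    # the residual is the ground truth; "hybr" may report lack of progress
    # even when it has landed on a root to machine precision
    ok = resid < residual_tol and bool(np.all(sol.x > -1e-12))
    state = SystemState.from_array(np.maximum(sol.x, 0.0))
    return EquilibriumPoint(state=state, residual_norm=resid, converged=ok)


def numerical_jacobian(params: ParameterSet, y: np.ndarray,
                       step: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of the vector field at ``y``.

    Step is relative to each component's magnitude with an absolute floor.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    y = np.asarray(y, dtype=float)
    J = np.zeros((6, 6))
    for j in range(6):
        h = step * max(abs(y[j]), 1.0)
        if h == 0:
            raise ValueError("finite-difference step underflowed")
        yp = y.copy(); yp[j] += h
        ym = y.copy(); ym[j] -= h
        J[:, j] = (rhs_array(yp, params) - rhs_array(ym, params)) / (2 * h)
    return J


def linearize(params: ParameterSet, state: SystemState | np.ndarray,
              step: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Jacobian (finite differences) and its eigenvalue spectrum at a state."""
    y = state.to_array() if isinstance(state, SystemState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    J = numerical_jacobian(params, y, step)
    return J, np.linalg.eigvals(J)


def leading_complex_eigenvalue(eigs: np.ndarray) -> complex:
    """The eigenvalue with largest real part among those with Im != 0.

    Falls back to the overall leading eigenvalue when the spectrum is purely
    real (then its zero imaginary part marks it as non-oscillatory).
    """
    eigs = np.asarray(eigs)
    cplx = eigs[np.abs(eigs.imag) > 1e-12]
    pool = cplx if len(cplx) else eigs
    return complex(pool[np.argmax(pool.real)])


def _classify_regime(extrema: dict[str, tuple[float, float]],
                     final: dict[str, float],
                     params: ParameterSet,
                     cycle_tol: float) -> str:
    persisting = {v: final[v] >= 0.01 for v in ("X1", "X2", "X3")}
    cycling = any((extrema[v][1] - extrema[v][0]) > cycle_tol
                  for v in ("X1", "X2", "X3") if persisting[v])
    if cycling:
        return "limit_cycle"
    label = classify_final_state(final, params, ("X1", "X2", "X3")).category
    if label in ("full_coexistence", "cheater_exclusion"):
        return label
    # anything short of a stable cooperator pair — total collapse or a
    # biofilm-only remnant with the fluid habitat flushed — counts as no
    # stability for the sweep's purposes
    return "washout"


def mu_sweep(base: ParameterSet,
             mu_lo: float, mu_hi: float, n_points: int,
             initial: SystemState,
             settings: SolverSettings | None = None,
             window: int = 2500,
             cycle_tol: float = CYCLE_TOLERANCE) -> BifurcationScan:
    """Sweep ``mu`` on a uniform grid; integrate, measure, label, linearize.

    Default protocol: 10,000 time units per point, extrema over the final
    2,500 grid points.  The spectrum at each point is evaluated at the
    equilibrium continued from the previous point (seeded from the first
    point's endpoint), so the eigenvalues track one branch even where the
    simulation has moved onto a cycle.
    """
    if mu_lo >= mu_hi:
        raise ValueError("mu_lo must be < mu_hi")
    base.validate()
    if settings is None:
        settings = SolverSettings(t_end=10000.0)
    mus = np.linspace(mu_lo, mu_hi, n_points)
    extrema, regimes, eigenvalues, leading = [], [], [], []
    failures: dict[int, str] = {}
    eq_seed: np.ndarray | None = None
    for i, mu in enumerate(mus):
        p = base.replace(mu=float(mu))
        try:
            tail = np.arange(settings.t_end - window + 1, settings.t_end + 0.5,
                             settings.grid_step)
            traj = integrate(p, initial, settings, t_eval=np.concatenate([[0.0], tail]))
            ext = final_window_extrema(traj, window)
            fin = traj.final_state
            final = {"X1": fin.X1, "X2": fin.X2, "X3": fin.X3}
            regime = _classify_regime(ext, final, p, cycle_tol)
        except Exception as exc:  # per-point failure: record and continue
            failures[i] = str(exc)
            extrema.append({v: (np.nan, np.nan) for v in
                            ("S", "E1", "E2", "X1", "X2", "X3")})
            regimes.append("failed")
            eigenvalues.append(np.full(6, np.nan, dtype=complex))
            leading.append(complex(np.nan, np.nan))
            continue
        # the branch scanned is the one the simulation lands on from the
        # reference initial state; inside the cycle band the root solve
        # still pulls in the enclosed focus.  Fall back to continuation from
        # the previous converged equilibrium if the endpoint seed fails.
        eq = find_equilibrium(p, traj.states[-1])
        if not eq.converged and eq_seed is not None:
            eq = find_equilibrium(p, eq_seed)
        if eq.converged:
            eq_seed = eq.state.to_array()
        _, eigs = linearize(p, eq.state)
        extrema.append(ext)
        regimes.append(regime)
        eigenvalues.append(eigs)
        leading.append(leading_complex_eigenvalue(eigs))
    return BifurcationScan(mu_values=mus, extrema=extrema, regimes=regimes,
                           eigenvalues=eigenvalues, leading_pair=leading,
                           base_params=base, failures=failures)


def detect_hopf(scan: BifurcationScan,
                base: ParameterSet | None = None,
                initial: SystemState | None = None,
                settings: SolverSettings | None = None,
                mu_tol: float = 1e-3) -> float:
    """Locate the mu* where the leading complex pair crosses Re = 0.

    Scans the recorded grid for a sign change with nonzero imaginary part on
    both sides (a real-axis crossing is a fold, not a Hopf), then bisects by
    re-solving the equilibrium and spectrum until ``|dmu| < mu_tol``.
    Raises ``ValueError`` when no bracketing sign change exists.
    """
    base = base if base is not None else scan.base_params
    re = np.array([z.real for z in scan.leading_pair])
    im = np.array([z.imag for z in scan.leading_pair])
    bracket = None
    for i in range(len(re) - 1):
        if np.isnan(re[i]) or np.isnan(re[i + 1]):
            continue
        if re[i] * re[i + 1] < 0:
            # both edges must carry a genuine complex pair: a sign change
            # where one side is purely real is a fold or a branch switch
            # (e.g. crossing the cheater-invasion point), not a Hopf
            if abs(im[i]) < 1e-9 or abs(im[i + 1]) < 1e-9:
                continue
            bracket = (scan.mu_values[i], scan.mu_values[i + 1], i)
            break
    if bracket is None:
        raise ValueError("no Hopf found: leading complex pair does not "
                         "cross the imaginary axis on this grid")
    mu_a, mu_b, i0 = bracket

    # continuation seed: converged equilibrium at the left bracket edge
    if initial is None:
        initial = SystemState.from_array(
            np.array([base.S0, 0.1, 0.1, 0.1, 0.1, 0.1]))
    if settings is None:
        settings = SolverSettings(t_end=10000.0)

    def spectrum_at(mu: float, seed: np.ndarray) -> tuple[complex, np.ndarray]:
        p = base.replace(mu=float(mu))
        eq = find_equilibrium(p, seed)
        _, eigs = linearize(p, eq.state)
        return leading_complex_eigenvalue(eigs), eq.state.to_array()

    # seed from a fresh simulation at mu_a for robustness
    p_a = base.replace(mu=float(mu_a))
    tail = np.arange(settings.t_end - 1000, settings.t_end + 0.5)
    traj = integrate(p_a, initial, settings, t_eval=np.concatenate([[0.0], tail]))
    seed = traj.states[-1]
    lead_a, seed = spectrum_at(mu_a, seed)
    sign_a = np.sign(lead_a.real)
    while (mu_b - mu_a) > mu_tol:
        mu_m = 0.5 * (mu_a + mu_b)
        lead_m, seed_m = spectrum_at(mu_m, seed)
        if abs(lead_m.imag) < 1e-9:
            raise ValueError("crossing eigenvalue lost its imaginary part: "
                             "not a Hopf bifurcation")
        if np.sign(lead_m.real) == sign_a:
            mu_a, seed = mu_m, seed_m
        else:
            mu_b = mu_m
    return float(0.5 * (mu_a + mu_b))
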