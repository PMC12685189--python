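"""Numerical integration of the chemostat system.

The integration protocol: LSODA (stiffness-switching) at ``rtol = 2e-10`` and
``atol = 1e-10`` on a unit-spaced output grid, default horizon 20,000 time
units, with a machine-epsilon floor applied inside the derivative callback so
decaying variables never run negative.

The floor is applied only to *enabled* variables.  A variable that is
structurally absent from a scenario (the cheater when ``X3(0) = 0``, the two
biofilm pools when ``alpha = 0``) is pinned at exactly zero; flooring it to
machine epsilon would seed it and let it invade from nothing.  Conversely the
biofilm enzyme pool, whose production term ``eta Q F(S, E2) X2`` vanishes
identically at ``E2 = 0``, can only start growing from the floor, so it must
be enabled (and is, whenever ``alpha > 0``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ParameterSet, SystemState, STATE_VARS, rhs_array

__all__ = [
    "MACHINE_EPS",
    "SolverSettings",
    "Trajectory",
    "IntegrationError",
    "enabled_mask",
    "integrate",
    "final_window_extrema",
]

#: np.finfo(float).eps — the floor value for enabled variables.
MACHINE_EPS = 2.220446049250313e-16


class IntegrationError(RuntimeError):
    """Solver failure; carries the partial trajectory computed so far."""

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 2e-10
    atol: float = 1e-10
    t_end: float = 20000.0
    grid_step: float = 1.0
    epsilon_floor: float = MACHINE_EPS
    method: str = "LSODA"

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
        if self.t_end <= 0 or self.grid_step <= 0:
            raise ValueError("t_end and grid_step must be positive")

    def to_dict(self) -> dict:
        return {"rtol": self.rtol, "atol": self.atol, "t_end": self.t_end,
                "grid_step": self.grid_step, "epsilon_floor": self.epsilon_floor,
                "method": self.method}


@dataclass
class Trajectory:
    """Solution on an output time grid, plus solver diagnostics."""

    times: np.ndarray            # (n,) strictly increasing, starts at 0
    states: np.ndarray           # (n, 6) in STATE_VARS order, floored >= 0
    params: ParameterSet
    success: bool = True
    nfev: int = 0
    message: str = ""

    def __post_init__(self):
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have the same length")

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    def to_json(self, path=None) -> str | None:
        payload = {
            "params": self.params.to_dict(),
            "times": self.times.tolist(),
            "states": self.states.tolist(),
            "success": bool(self.success),
            "nfev": int(self.nfev),
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return None


def enabled_mask(initial: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Which state variables the epsilon floor applies to.

    S and E1 always; X1/X3 when they start positive; the biofilm pools when
    adhesion is switched on (they start at zero by design and are seeded by
    the floor).
    """
    S0, E10, E20, X10, X20, X30 = initial
    biofilm = params.alpha > 0
    return np.array([
        True,                    # S
        True,                    # E1
        biofilm or E20 > 0,      # E2
        X10 > 0,                 # X1
        biofilm or X20 > 0,      # X2
        X30 > 0,                 # X3
    ])


def integrate(params: ParameterSet,
              initial: SystemState | Sequence[float],
              settings: SolverSettings = SolverSettings(),
              t_eval: np.ndarray | None = None) -> Trajectory:
    """Integrate the system from ``initial`` under the stated protocol.

    ``t_eval`` overrides the default unit-spaced output grid; pass a sparse
    grid (for example just the final time) to skip dense output in Monte
    Carlo batches.
    """
    params.validate()
    y0 = initial.to_array() if isinstance(initial, SystemState) else np.asarray(initial, float)
    if y0.shape != (6,):
        raise ValueError("initial state must have six components")
    if np.any(y0 < 0) or not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be nonnegative and finite")

    mask = enabled_mask(y0, params)
    floor = settings.epsilon_floor

    def f(t: float, y: np.ndarray) -> np.ndarray:
        y = y.copy()
        y[mask & (y < floor)] = floor
        return rhs_array(y, params)

    if t_eval is None:
        t_eval = np.arange(0.0, settings.t_end + 0.5 * settings.grid_step,
                           settings.grid_step)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
    # the output grid must include t0 for the trajectory contract; callers
    # passing sparse grids may start later, so prepend when missing
    sol = solve_ivp(f, (0.0, settings.t_end), y0, method=settings.method,
                    rtol=settings.rtol, atol=settings.atol, t_eval=t_eval)

    states = sol.y.T.copy()
    # report floored, nonnegative states: enabled variables at >= floor,
    # disabled ones clipped at 0 (solver noise can be ~ -1e-12)
    for j in range(6):
        col = states[:, j]
        if mask[j]:
            np.maximum(col, floor, out=col)
        else:
            np.maximum(col, 0.0, out=col)

    traj = Trajectory(times=sol.t.copy(), states=states, params=params,
                      success=bool(sol.success), nfev=int(sol.nfev),
                      message=str(sol.message))
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}", traj)
    return traj


def final_window_extrema(traj: Trajectory, window: int) -> dict[str, tuple[float, float]]:
    """Per-variable (min, max) over the trailing ``window`` grid points.

    The cycle detector and the bifurcation diagrams are built on these
    extrema: a steady state has min == max up to solver noise, a limit cycle
    has max - min equal to its amplitude.
    """
    if window <= 0:
        raise ValueError("window must be a positive number of grid points")
    if window > len(traj.times):
        raise ValueError(
            f"window ({window}) exceeds grid length ({len(traj.times)})")
    tail = traj.states[-window:]
    mins = tail.min(axis=0)
    maxs = tail.max(axis=0)
    return {name: (float(mins[j]), float(maxs[j]))
            for j, name in enumerate(STATE_VARS)}
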