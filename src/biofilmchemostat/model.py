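"""Six-variable chemostat model of public-goods cooperation with a biofilm.

The system tracks a nutrient substrate ``S``, a secreted public-good enzyme in
the fluid (``E1``) and in the biofilm (``E2``), enzyme-producing cooperators in
the fluid (``X1``) and in the biofilm (``X2``), and a non-producing cheater in
the fluid (``X3``).  Cooperators devote a fixed fraction ``Q`` of their
metabolic energy to quorum-sensing behaviours (enzyme and biofilm production)
and the remaining ``1 - Q`` to growth; cheaters put everything into growth but
depend on the shared enzyme pool to feed.

Per-capita uptake follows a Monod law in the nutrient, multiplied by the local
enzyme concentration::

    F(S, E) = mu * S * E / (K_S + S)

so uptake vanishes when either nutrient or enzyme is absent and increases in
both (assumption N1).  The biofilm is a per-area compartment with finite
capacities ``E2_max`` and ``X2_max``; the occupancy ratios
``M = E2 / E2_max`` and ``W = X2 / X2_max`` split biofilm production between
retention (fraction ``1 - M`` or ``1 - W``) and leakage into the fluid
(fraction ``M`` or ``W``).  The ratios are deliberately *not* clamped at 1:
above capacity the retention term turns negative, which is exactly the
overflow flux that spills excess enzyme or biomass back into the fluid and
keeps the biofilm pools bounded near their capacities.

Unit conventions: concentrations in the fluid are mass/volume, concentrations
on the biofilm are mass/area, and ``delta`` converts a per-area quantity to a
per-volume one (fluid equivalent of ``X2`` is ``delta * X2``).  Every flux
that crosses the fluid/biofilm boundary carries the matching factor of
``delta`` (biofilm -> fluid) or ``1/delta`` (fluid -> biofilm) so that mass is
conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ParameterSet",
    "SystemState",
    "ParameterError",
    "monod_uptake",
    "occupancy",
    "rhs",
    "rhs_array",
    "validate_parameters",
    "analytic_jacobian",
    "STATE_VARS",
    "STABLE_MEDIANS",
    "REFERENCE_INITIAL",
    "MEDIAN_ALPHA",
    "MEDIAN_X3_INIT",
]

#: State-vector component order used throughout the package.
STATE_VARS = ("S", "E1", "E2", "X1", "X2", "X3")


class ParameterError(ValueError):
    """A parameter violates its biological validity range."""


@dataclass(frozen=True)
class ParameterSet:
    """All model constants.

    Rates (``D``, ``alpha``, ``beta_X``, ``beta_E``) are 1/time and must stay
    below 1 so no more than the whole pool can be transferred per unit time;
    ``Q`` is the dimensionless cost of quorum sensing in ``[0, 1)``;
    ``K_S`` must stay below ``S0`` so growth is not nutrient-limited over the
    whole operating range.  ``alpha == 0`` is the switch that disables the
    biofilm entirely.
    """

    S0: float        # influent nutrient concentration (mass/volume)
    D: float         # dilution rate (1/time)
    Q: float         # fraction of energy to quorum sensing, [0, 1)
    eta: float       # energy -> enzyme conversion efficiency
    gamma: float     # nutrient -> biomass yield constant
    delta: float     # biofilm-area -> fluid-volume conversion
    alpha: float     # fluid -> biofilm adhesion rate (1/time)
    beta_X: float    # cooperator sloughing rate (1/time)
    beta_E: float    # enzyme sloughing rate (1/time)
    E2_max: float    # biofilm enzyme capacity (mass/area)
    X2_max: float    # biofilm cooperator capacity (mass/area)
    mu: float        # maximum growth rate (1/time)
    K_S: float       # Monod half-saturation constant (mass/volume)

    def validate(self) -> "ParameterSet":
        return validate_parameters(self)

    def replace(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, record: dict[str, float]) -> "ParameterSet":
        names = {f.name for f in fields(cls)}
        unknown = set(record) - names
        if unknown:
            raise ParameterError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = names - set(record)
        if missing:
            raise ParameterError(f"missing parameter name(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in record.items()})


@dataclass(frozen=True)
class SystemState:
    """The six concentrations at one time point."""

    S: float
    E1: float
    E2: float
    X1: float
    X2: float
    X3: float

    def to_array(self) -> np.ndarray:
        return np.array([self.S, self.E1, self.E2, self.X1, self.X2, self.X3],
                        dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise ValueError(f"state must have six components, got shape {y.shape}")
        if not np.all(np.isfinite(y)):
            raise ValueError("state components must be finite")
        return cls(*map(float, y))

    def validate(self) -> "SystemState":
        y = self.to_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("state components must be finite")
        if np.any(y < 0):
            raise ValueError("state components must be nonnegative")
        return self


# Median parameter values of the fully stable coexistence ensemble, used as
# the reference operating point for the deterministic scenario panel.
STABLE_MEDIANS = ParameterSet(
    S0=0.76202, delta=0.08377, eta=0.80704, gamma=0.71445,
    E2_max=0.19065, X2_max=0.23565, beta_E=0.02042, beta_X=0.00699,
    D=0.41712, Q=0.47026, mu=68.07673, K_S=0.01, alpha=0.11401,
)

#: Reference initial state (biofilm pools start empty, cheaters via X3).
REFERENCE_INITIAL = SystemState(S=0.14862, E1=0.13806, E2=0.0,
                           X1=0.27003, X2=0.0, X3=0.0)

#: Median adhesion rate / initial cheater concentration used as the on-switches
#: in the four-scenario panel.
MEDIAN_ALPHA = 0.11401
MEDIAN_X3_INIT = 0.11655


def monod_uptake(S: float, E: float, mu: float, K_S: float) -> float:
    """Per-capita uptake rate ``mu * S * E / (K_S + S)``.

    Zero whenever nutrient or enzyme is absent and strictly increasing in
    both when both are positive.
    """
    if S < 0 or E < 0:
        raise ValueError("nutrient and enzyme concentrations must be nonnegative")
    if mu <= 0 or K_S <= 0:
        raise ValueError("mu and K_S must be positive")
    return mu * S * E / (K_S + S)


def occupancy(level: float, capacity: float) -> float:
    """Fraction of biofilm capacity occupied, ``level / capacity``.

    May exceed 1 during transient overshoot; values above 1 flip the sign of
    the retention term in the biofilm balance, which is how overflow drains
    back into the fluid.
    """
    if capacity <= 0:
        raise ValueError("biofilm capacity must be positive")
    if level < 0:
        raise ValueError("biofilm level must be nonnegative")
    return level / capacity


def validate_parameters(p: ParameterSet) -> ParameterSet:
    """Check every validity range; raise :class:`ParameterError` on violation."""
    for name in ("S0", "D", "Q", "eta", "gamma", "delta", "beta_X", "beta_E",
                 "E2_max", "X2_max", "mu", "K_S", "alpha"):
        v = getattr(p, name)
        if not np.isfinite(v):
            raise ParameterError(f"{name} must be finite, got {v}")
    if p.alpha < 0:
        raise ParameterError(f"alpha must be >= 0, got {p.alpha}")
    for name in ("S0", "D", "eta", "gamma", "delta", "beta_X", "beta_E",
                 "E2_max", "X2_max", "mu", "K_S"):
        v = getattr(p, name)
        if v <= 0:
            raise ParameterError(f"{name} must be > 0, got {v}")
    if not (0 <= p.Q < 1):
        raise ParameterError(f"Q must lie in [0, 1), got {p.Q}")
    for name in ("D", "beta_X", "beta_E", "alpha"):
        if getattr(p, name) >= 1:
            raise ParameterError(
                f"{name} must be < 1 (cannot transfer more than the whole pool "
                f"per unit time), got {getattr(p, name)}")
    if p.K_S >= p.S0:
        raise ParameterError(f"K_S must be < S0, got K_S={p.K_S}, S0={p.S0}")
    return p


# --- individual flux terms -------------------------------------------------
#
# Each physical flux lives in its own function so a single term can be
# corrected or instrumented without touching the rest of the balance.

def _uptake_fluid(S, E1, X1, X3, p):
    """Nutrient consumed by all fluid-phase cells (per volume)."""
    F1 = p.mu * S * E1 / (p.K_S + S)
    return F1 * (X1 + X3) / p.gamma


def _uptake_biofilm(S, E2, X2, p):
    """Nutrient consumed by biofilm cells, expressed per fluid volume."""
    F2 = p.mu * S * E2 / (p.K_S + S)
    return p.delta * F2 * X2 / p.gamma


def _enzyme_production_fluid(S, E1, X1, p):
    return p.eta * p.Q * (p.mu * S * E1 / (p.K_S + S)) * X1


def _enzyme_production_biofilm(S, E2, X2, p):
    """Total enzyme output of biofilm cooperators (per area)."""
    return p.eta * p.Q * (p.mu * S * E2 / (p.K_S + S)) * X2


def rhs(state: SystemState, params: ParameterSet) -> np.ndarray:
    """Time derivatives of the six state variables.

    The balance equations (``F_i = F(S, E_i)``, ``M = E2/E2_max``,
    ``W = X2/X2_max``)::

        dS/dt  = D (S0 - S) - [F1 (X1 + X3) + delta F2 X2] / gamma
        dE1/dt = -D E1 + eta Q F1 X1 + delta [beta_E E2 + eta Q F2 X2 M]
        dE2/dt = eta Q F2 X2 (1 - M) - beta_E E2
        dX1/dt = (1-Q) F1 X1 - D X1 - alpha X1
                 + delta [beta_X X2 + (1-Q) F2 X2 W]
        dX2/dt = (1-Q) F2 X2 (1 - W) + (alpha/delta) X1 - beta_X X2
        dX3/dt = F1 X3 - D X3
    """
    y = state.to_array() if isinstance(state, SystemState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    if np.any(y < 0):
        raise ValueError("state must be nonnegative")
    return rhs_array(y, params)


def rhs_array(y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Vector-in/vector-out form of :func:`rhs` without input checks.

    This is the hot path used by the integrator; callers are responsible for
    finiteness.
    """
    S, E1, E2, X1, X2, X3 = y
    monod = p.mu * S / (p.K_S + S)
    F1 = monod * E1
    F2 = monod * E2
    M = E2 / p.E2_max
    W = X2 / p.X2_max
    d = p.delta
    etaQ = p.eta * p.Q
    oneQ = 1.0 - p.Q

    dS = p.D * (p.S0 - S) - (F1 * (X1 + X3) + d * F2 * X2) / p.gamma
    dE1 = -p.D * E1 + etaQ * F1 * X1 + d * (p.beta_E * E2 + etaQ * F2 * X2 * M)
    dE2 = etaQ * F2 * X2 * (1.0 - M) - p.beta_E * E2
    dX1 = (oneQ * F1 - p.D - p.alpha) * X1 + d * (p.beta_X * X2 + oneQ * F2 * X2 * W)
    dX2 = oneQ * F2 * X2 * (1.0 - W) + (p.alpha / d) * X1 - p.beta_X * X2
    dX3 = (F1 - p.D) * X3
    return np.array([dS, dE1, dE2, dX1, dX2, dX3])


def analytic_jacobian(y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Closed-form Jacobian of :func:`rhs_array` at ``y``.

    Serves as the independent cross-check for the finite-difference
    linearization used in the stability analysis.
    """
    S, E1, E2, X1, X2, X3 = np.asarray(y, dtype=float)
    d = p.delta
    etaQ = p.eta * p.Q
    oneQ = 1.0 - p.Q

    g = p.mu * S / (p.K_S + S)                  # monod factor
    gp = p.mu * p.K_S / (p.K_S + S) ** 2        # d(monod)/dS
    F1 = g * E1
    F2 = g * E2
    F1_S = gp * E1
    F2_S = gp * E2
    M = E2 / p.E2_max
    W = X2 / p.X2_max

    J = np.zeros((6, 6))

    # dS row
    J[0, 0] = -p.D - (F1_S * (X1 + X3) + d * F2_S * X2) / p.gamma
    J[0, 1] = -g * (X1 + X3) / p.gamma
    J[0, 2] = -d * g * X2 / p.gamma
    J[0, 3] = -F1 / p.gamma
    J[0, 4] = -d * F2 / p.gamma
    J[0, 5] = -F1 / p.gamma

    # dE1 row
    J[1, 0] = etaQ * F1_S * X1 + d * etaQ * F2_S * X2 * M
    J[1, 1] = -p.D + etaQ * g * X1
    J[1, 2] = d * (p.beta_E + etaQ * X2 * (g * M + F2 / p.E2_max))
    J[1, 3] = etaQ * F1
    J[1, 4] = d * etaQ * F2 * M
    # J[1, 5] = 0

    # dE2 row
    J[2, 0] = etaQ * F2_S * X2 * (1.0 - M)
    J[2, 2] = etaQ * X2 * (g * (1.0 - M) - F2 / p.E2_max) - p.beta_E
    J[2, 4] = etaQ * F2 * (1.0 - M)

    # dX1 row
    J[3, 0] = oneQ * F1_S * X1 + d * oneQ * F2_S * X2 * W
    J[3, 1] = oneQ * g * X1
    J[3, 2] = d * oneQ * g * X2 * W
    J[3, 3] = oneQ * F1 - p.D - p.alpha
    # F2 X2 W = g E2 X2^2 / X2_max, so d/dX2 = 2 g E2 X2 / X2_max
    J[3, 4] = d * (p.beta_X + oneQ * g * E2 * 2.0 * X2 / p.X2_max)

    # dX2 row
    J[4, 0] = oneQ * F2_S * X2 * (1.0 - W)
    J[4, 2] = oneQ * g * X2 * (1.0 - W)
    J[4, 3] = p.alpha / d
    # d/dX2 [(1-Q) F2 X2 (1-W)] with F2 independent of X2:
    J[4, 4] = oneQ * F2 * (1.0 - 2.0 * W) - p.beta_X

    # dX3 row
    J[5, 0] = F1_S * X3
    J[5, 1] = g * X3
    J[5, 5] = F1 - p.D

    return J
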