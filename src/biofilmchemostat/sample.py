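"""Monte Carlo sampling designs for parameters and initial conditions.

The survey draws every quantity independently per simulation:

* log-uniform on ``[0.01, 2)`` — initial conditions ``S(0), E1(0), X1(0),
  X3(0)``, conversion factors ``eta, gamma, delta``, influent nutrient
  ``S0``, and the biofilm capacities ``E2_max, X2_max``;
* log-uniform on ``[0.001, 1)`` — the sloughing and adhesion rates
  ``beta_X, beta_E, alpha``;
* uniform on ``[0.1, 1)`` — dilution ``D`` and quorum-sensing cost ``Q``
  (lower bound raised so slow near-neutral washouts do not masquerade as
  stable states);
* uniform on ``[1, 100)`` — maximum growth rate ``mu``;
* log-uniform on ``[0.001, S0)`` — ``K_S``, coupled to the ``S0`` drawn in
  the same simulation;
* both biofilm pools start empty (``X2(0) = E2(0) = 0``).

Log-uniform means ``exp(U(ln lo, ln hi))``, giving equal weight to each
order of magnitude.

Four growth conditions toggle the biofilm (``alpha`` drawn vs fixed 0) and
the cheater (``X3(0)`` drawn vs fixed 0).  One root seed spawns per-draw
child seeds, so batches are reproducible and each simulation's draw is
independent of batch size or ordering.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .model import ParameterSet, SystemState

__all__ = [
    "Spec",
    "SampleDesign",
    "CONDITIONS",
    "PARAM_NAMES",
    "INIT_NAMES",
    "default_design",
    "restrict_design",
    "cooperator_stable_design",
    "draw",
]

CONDITIONS = ("coop_only", "coop_biofilm", "coop_biofilm_cheater",
              "coop_cheater_no_biofilm")

PARAM_NAMES = ("S0", "D", "Q", "eta", "gamma", "delta", "alpha",
               "beta_X", "beta_E", "E2_max", "X2_max", "mu", "K_S")
INIT_NAMES = ("S_init", "E1_init", "E2_init", "X1_init", "X2_init", "X3_init")

_FAMILIES = ("loguniform", "uniform", "fixed")


@dataclass(frozen=True)
class Spec:
    """Distribution of one quantity: family plus bounds (or a fixed value)."""

    family: str
    lo: float = 0.0
    hi: float = 0.0
    value: float = 0.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family != "fixed":
            if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
                raise ValueError("bounds must be finite")
            if self.lo >= self.hi:
                raise ValueError(f"lower bound must be < upper bound "
                                 f"({self.lo} >= {self.hi})")
            if self.family == "loguniform" and self.lo <= 0:
                raise ValueError("log-uniform lower bound must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.value
        if self.family == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))

    @staticmethod
    def fixed(value: float) -> "Spec":
        return Spec("fixed", value=value)

    def to_dict(self) -> dict:
        if self.family == "fixed":
            return {"family": "fixed", "value": self.value}
        return {"family": self.family, "lo": self.lo, "hi": self.hi}

    @staticmethod
    def from_dict(d: dict) -> "Spec":
        if d["family"] == "fixed":
            return Spec.fixed(float(d["value"]))
        return Spec(d["family"], lo=float(d["lo"]), hi=float(d["hi"]))


@dataclass(frozen=True)
class SampleDesign:
    """Per-quantity distributions plus the K_S <- S0 per-draw coupling.

    ``ks_coupled_to_S0`` caps each draw's ``K_S`` upper bound at the ``S0``
    drawn in the same simulation, keeping ``K_S < S0`` valid draw by draw.
    """

    specs: dict[str, Spec]
    ks_coupled_to_S0: bool = True
    condition: str = "custom"

    def __post_init__(self):
        missing = (set(PARAM_NAMES) | set(INIT_NAMES)) - set(self.specs)
        if missing:
            raise ValueError(f"design is missing quantities: {sorted(missing)}")

    def to_dict(self) -> dict:
        return {"condition": self.condition,
                "ks_coupled_to_S0": self.ks_coupled_to_S0,
                "specs": {k: v.to_dict() for k, v in self.specs.items()}}

    @staticmethod
    def from_dict(d: dict) -> "SampleDesign":
        return SampleDesign(
            specs={k: Spec.from_dict(v) for k, v in d["specs"].items()},
            ks_coupled_to_S0=bool(d.get("ks_coupled_to_S0", True)),
            condition=str(d.get("condition", "custom")))


def default_design(condition: str, seedless: bool = True) -> SampleDesign:
    """The survey design for one of the four growth conditions.

    ``coop_only`` fixes ``alpha = 0`` and ``X3(0) = 0``;
    ``coop_biofilm`` fixes only ``X3(0) = 0``;
    ``coop_biofilm_cheater`` draws everything;
    ``coop_cheater_no_biofilm`` fixes only ``alpha = 0``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {CONDITIONS}")
    lu_wide = lambda: Spec("loguniform", 0.01, 2.0)
    lu_rate = lambda: Spec("loguniform", 0.001, 1.0)
    specs = {
        "S0": lu_wide(), "eta": lu_wide(), "gamma": lu_wide(),
        "delta": lu_wide(), "E2_max": lu_wide(), "X2_max": lu_wide(),
        "beta_X": lu_rate(), "beta_E": lu_rate(), "alpha": lu_rate(),
        "D": Spec("uniform", 0.1, 1.0), "Q": Spec("uniform", 0.1, 1.0),
        "mu": Spec("uniform", 1.0, 100.0),
        # per-draw upper bound is min(hi, S0) when ks_coupled_to_S0
        "K_S": Spec("loguniform", 0.001, 2.0),
        "S_init": lu_wide(), "E1_init": lu_wide(), "X1_init": lu_wide(),
        "X3_init": lu_wide(),
        "E2_init": Spec.fixed(0.0), "X2_init": Spec.fixed(0.0),
    }
    if condition in ("coop_only", "coop_cheater_no_biofilm"):
        specs["alpha"] = Spec.fixed(0.0)
    if condition in ("coop_only", "coop_biofilm"):
        specs["X3_init"] = Spec.fixed(0.0)
    return SampleDesign(specs=specs, ks_coupled_to_S0=True, condition=condition)


def restrict_design(base: SampleDesign,
                    overrides: dict[str, Spec]) -> SampleDesign:
    """Return ``base`` with some quantities overridden.

    Overrides are validated by construction of their :class:`Spec`; unknown
    quantity names are rejected.
    """
    unknown = set(overrides) - set(base.specs)
    if unknown:
        raise ValueError(f"unknown quantities in overrides: {sorted(unknown)}")
    specs = dict(base.specs)
    specs.update(overrides)
    return replace(base, specs=specs, condition="custom")


def cooperator_stable_design(with_cheater: bool = False) -> SampleDesign:
    """The narrowed design on which cooperator-only runs are all stable.

    Loaded from the packaged ``cooperator_stable_ranges.yaml``, a derived
    (synthetic) transcription produced by this package's own calibration run:
    inner-quartile ranges of the stable cooperator survey for the quantities
    the sensitivity analysis perturbs, everything else pinned at its stable
    median.  ``with_cheater=True`` additionally draws the initial cheater
    concentration from the full range [0.01, 2).
    """
    ref = importlib.resources.files("biofilmchemostat").joinpath(
        "data/cooperator_stable_ranges.yaml")
    cfg = yaml.safe_load(ref.read_text())
    specs = {k: Spec.from_dict(v) for k, v in cfg["specs"].items()}
    design = SampleDesign(specs=specs,
                          ks_coupled_to_S0=bool(cfg.get("ks_coupled_to_S0", True)),
                          condition="cooperator_stable")
    if with_cheater:
        design = restrict_design(
            design, {"X3_init": Spec("loguniform", 0.01, 2.0)})
    return design


def _draw_one(design: SampleDesign,
              rng: np.random.Generator) -> tuple[ParameterSet, SystemState]:
    vals: dict[str, float] = {}
    # S0 first so the K_S coupling can see it
    vals["S0"] = design.specs["S0"].sample(rng)
    for name in PARAM_NAMES:
        if name == "S0":
            continue
        spec = design.specs[name]
        if name == "K_S" and design.ks_coupled_to_S0 and spec.family != "fixed":
            hi = min(spec.hi, vals["S0"])
            if hi <= spec.lo:
                # S0 drawn at/below the K_S floor: keep K_S strictly inside
                vals["K_S"] = 0.5 * vals["S0"]
                continue
            spec = Spec(spec.family, spec.lo, hi)
        vals[name] = spec.sample(rng)
    params = ParameterSet(
        S0=vals["S0"], D=vals["D"], Q=vals["Q"], eta=vals["eta"],
        gamma=vals["gamma"], delta=vals["delta"], alpha=vals["alpha"],
        beta_X=vals["beta_X"], beta_E=vals["beta_E"], E2_max=vals["E2_max"],
        X2_max=vals["X2_max"], mu=vals["mu"], K_S=vals["K_S"]).validate()
    initial = SystemState(
        S=design.specs["S_init"].sample(rng),
        E1=design.specs["E1_init"].sample(rng),
        E2=design.specs["E2_init"].sample(rng),
        X1=design.specs["X1_init"].sample(rng),
        X2=design.specs["X2_init"].sample(rng),
        X3=design.specs["X3_init"].sample(rng))
    return params, initial


def draw(design: SampleDesign, n: int,
         seed: int | np.random.SeedSequence) -> list[tuple[ParameterSet, SystemState]]:
    """``n`` reproducible draws from ``design``.

    The root seed spawns one child stream per draw, so draw ``i`` of a batch
    is identical no matter how large the batch is — Monte Carlo runs can be
    chunked or parallelized without changing results.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n)
    return [_draw_one(design, np.random.default_rng(c)) for c in children]
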