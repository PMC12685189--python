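"""Long-run outcome classification.

A finished run is mapped to one of five categories from the final
concentrations of the bacterial variants that were enabled in the scenario:

* ``full_coexistence`` — every enabled variant ends with concentration
  >= 0.01 *and* holds at least 5% of the total population;
* ``cheater_exclusion`` — the two cooperator types pass while the cheater
  is washed out below the concentration floor (three-variant scenarios);
* ``competitive_exclusion_other`` — any other two-pass-one-washed-out case;
* ``tragedy`` — every enabled variant ends below the concentration
  threshold (the commons collapsed);
* ``other`` — anything else, e.g. a stable total population in which some
  variant holds only a sliver of the whole.

Population shares are computed in fluid-volume units by default, i.e. the
biofilm cooperator enters the total as ``delta * X2`` so the three variants
are commensurable; ``basis="raw"`` compares the concentrations as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ParameterSet
from .simulate import Trajectory

__all__ = [
    "CONC_THRESHOLD",
    "FRAC_THRESHOLD",
    "CATEGORIES",
    "OutcomeLabel",
    "variant_fractions",
    "classify_outcome",
    "classify_final_state",
]

CONC_THRESHOLD = 0.01   # minimum final concentration (inclusive)
FRAC_THRESHOLD = 0.05   # minimum population share (inclusive)

CATEGORIES = ("full_coexistence", "cheater_exclusion",
              "competitive_exclusion_other", "tragedy", "other")

VARIANTS = ("X1", "X2", "X3")
_VAR_INDEX = {"X1": 3, "X2": 4, "X3": 5}


@dataclass(frozen=True)
class OutcomeLabel:
    category: str
    final_concentrations: dict[str, float]
    final_fractions: dict[str, float]
    variants_present: tuple[str, ...]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def variant_fractions(final: dict[str, float], delta: float,
                      present: tuple[str, ...] = VARIANTS,
                      basis: str = "delta") -> dict[str, float]:
    """Population shares of the enabled variants.

    With ``basis="delta"`` the biofilm cooperator contributes ``delta * X2``
    (its fluid-volume equivalent); with ``basis="raw"`` the per-area
    concentration is used directly.  Raises ``ValueError`` when the total
    population is not positive — the caller treats that as a degenerate
    (tragedy-like) state.
    """
    if basis not in ("delta", "raw"):
        raise ValueError(f"unknown basis {basis!r}")
    eff = {}
    for v in present:
        c = final[v]
        eff[v] = delta * c if (v == "X2" and basis == "delta") else c
    total = sum(eff.values())
    if total <= 0:
        raise ValueError("total population is not positive")
    return {v: eff[v] / total for v in present}


def classify_final_state(final: dict[str, float],
                         params: ParameterSet,
                         variants_present: tuple[str, ...],
                         conc_threshold: float = CONC_THRESHOLD,
                         frac_threshold: float = FRAC_THRESHOLD,
                         basis: str = "delta") -> OutcomeLabel:
    """Apply the rule table to a set of final variant concentrations."""
    present = tuple(v for v in VARIANTS if v in variants_present)
    if not present:
        raise ValueError("variants_present must name at least one variant")

    conc = {v: float(final[v]) for v in present}
    try:
        frac = variant_fractions(conc, params.delta, present, basis)
    except ValueError:
        frac = {v: 0.0 for v in present}

    passes = {v: conc[v] >= conc_threshold and frac[v] >= frac_threshold
              for v in present}
    n_pass = sum(passes.values())

    if n_pass == len(present):
        category = "full_coexistence"
    elif all(conc[v] < conc_threshold for v in present):
        category = "tragedy"
    elif len(present) == 3 and n_pass == 2:
        # competitive exclusion means the failing variant was actually
        # driven out (below the concentration floor); a variant that
        # persists above the floor but holds under 5% of the population
        # is a small-proportion case, i.e. "other"
        failing = next(v for v in present if not passes[v])
        if conc[failing] < conc_threshold:
            category = ("cheater_exclusion" if failing == "X3"
                        else "competitive_exclusion_other")
        else:
            category = "other"
    else:
        category = "other"
    return OutcomeLabel(category=category, final_concentrations=conc,
                        final_fractions=frac, variants_present=present)


def classify_outcome(traj: Trajectory,
                     variants_present: tuple[str, ...] = VARIANTS,
                     conc_threshold: float = CONC_THRESHOLD,
                     frac_threshold: float = FRAC_THRESHOLD,
                     basis: str = "delta") -> OutcomeLabel:
    """Classify a finished trajectory.

    ``variants_present`` lists the bacterial variants enabled in the
    scenario; a variant named as present must actually appear with a
    nonzero history or initial value somewhere in the trajectory setup
    (enabled-but-extinct is fine, that is what the taxonomy measures).
    """
    final = traj.final_state
    conc = {"X1": final.X1, "X2": final.X2, "X3": final.X3}
    for v in variants_present:
        if v not in _VAR_INDEX:
            raise ValueError(f"unknown variant {v!r}")
    return classify_final_state(conc, traj.params, tuple(variants_present),
                                conc_threshold, frac_threshold, basis)
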