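"""Orchestration of the computational studies.

Five entry points:

* :func:`run_condition_panel` — the four deterministic reference scenarios
  (biofilm on/off x cheaters on/off at the stable-median operating point);
* :func:`run_monte_carlo` — a survey over one growth condition's sampling
  design, one outcome record per draw;
* :func:`run_invasion_experiment` — two-phase cheater-invasion study on the
  cooperator-stable restricted design;
* :func:`run_grid` — a 2-D stability grid over two swept quantities, all
  others pinned at the reference medians;
* :func:`summarize_outcomes` — per-quantity location/spread summaries of the
  stable subsets plus pairwise Mann-Whitney U comparisons across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .model import (ParameterSet, SystemState, STABLE_MEDIANS, REFERENCE_INITIAL,
                    MEDIAN_ALPHA, MEDIAN_X3_INIT, STATE_VARS)
from .simulate import SolverSettings, Trajectory, IntegrationError, integrate
from .classify import OutcomeLabel, classify_outcome, CATEGORIES
from .sample import (SampleDesign, Spec, default_design,
                     cooperator_stable_design, draw, PARAM_NAMES, INIT_NAMES)

__all__ = [
    "OutcomeTable",
    "StabilityGrid",
    "run_condition_panel",
    "run_monte_carlo",
    "run_invasion_experiment",
    "run_grid",
    "summarize_outcomes",
]

log = logging.getLogger(__name__)

_QUANTITY_COLUMNS = list(PARAM_NAMES) + list(INIT_NAMES)


@dataclass
class OutcomeTable:
    """Flat record set: one row per simulation (draw, finals, category)."""

    records: pd.DataFrame
    condition: str
    n_requested: int
    n_failures: int = 0

    def category_fractions(self) -> dict[str, float]:
        counts = self.records["category"].value_counts()
        n = len(self.records)
        return {c: float(counts.get(c, 0)) / n for c in CATEGORIES}

    def stable_subset(self) -> pd.DataFrame:
        return self.records[self.records["category"] == "full_coexistence"]

    def to_csv(self, path_or_buf) -> None:
        self.records.to_csv(path_or_buf, index=False)


@dataclass
class StabilityGrid:
    x_name: str
    y_name: str
    x_values: np.ndarray
    y_values: np.ndarray
    stable: np.ndarray            # (ny, nx) bool, True = full coexistence
    categories: np.ndarray        # (ny, nx) object

    def stable_fraction_by_column(self) -> np.ndarray:
        return self.stable.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iy, yv in enumerate(self.y_values):
            for ix, xv in enumerate(self.x_values):
                rows.append({self.x_name: xv, self.y_name: yv,
                             "stable": bool(self.stable[iy, ix]),
                             "category": self.categories[iy, ix]})
        return pd.DataFrame(rows)


def _variants_present(params: ParameterSet, initial: SystemState) -> tuple[str, ...]:
    present = ["X1"] if initial.X1 > 0 else []
    if params.alpha > 0:
        present.append("X2")
    if initial.X3 > 0:
        present.append("X3")
    return tuple(present)


def run_condition_panel(median: ParameterSet = STABLE_MEDIANS,
                        initial: SystemState = REFERENCE_INITIAL,
                        alpha_on: float = MEDIAN_ALPHA,
                        x3_on: float = MEDIAN_X3_INIT,
                        settings: SolverSettings | None = None
                        ) -> dict[str, tuple[Trajectory, OutcomeLabel]]:
    """The four reference scenarios at the stable-median operating point.

    Returns a dict keyed by scenario name; each value is the trajectory and
    its outcome label.  Scenario keys encode the toggles:
    ``no_biofilm_no_cheater``, ``no_biofilm_cheater``, ``biofilm_no_cheater``,
    ``biofilm_cheater``.
    """
    median.validate()
    settings = settings or SolverSettings()
    panel = {}
    for bf, ch in ((False, False), (False, True), (True, False), (True, True)):
        name = f"{'biofilm' if bf else 'no_biofilm'}_{'cheater' if ch else 'no_cheater'}"
        p = median.replace(alpha=alpha_on if bf else 0.0)
        y0 = SystemState(S=initial.S, E1=initial.E1, E2=initial.E2,
                         X1=initial.X1, X2=initial.X2,
                         X3=x3_on if ch else 0.0)
        traj = integrate(p, y0, settings)
        label = classify_outcome(traj, _variants_present(p, y0))
        panel[name] = (traj, label)
    return panel


def _simulate_and_record(params: ParameterSet, initial: SystemState,
                         settings: SolverSettings, seed_id: int,
                         condition: str) -> dict:
    t_eval = np.array([0.0, settings.t_end])
    traj = integrate(params, initial, settings, t_eval=t_eval)
    label = classify_outcome(traj, _variants_present(params, initial))
    rec = {"seed_id": seed_id, "condition": condition}
    rec.update(params.to_dict())
    rec.update({"S_init": initial.S, "E1_init": initial.E1,
                "E2_init": initial.E2, "X1_init": initial.X1,
                "X2_init": initial.X2, "X3_init": initial.X3})
    fin = traj.final_state
    rec.update({f"{v}_final": getattr(fin, v) for v in STATE_VARS})
    rec["category"] = label.category
    return rec


def run_monte_carlo(design: SampleDesign, n: int, seed: int,
                    settings: SolverSettings | None = None,
                    log_every: int = 0) -> OutcomeTable:
    """Draw, integrate, classify ``n`` simulations of one design.

    Per-draw failures are recorded (row dropped, counter incremented), not
    fatal.  Identical ``(design, n, seed)`` give identical tables.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    settings = settings or SolverSettings()
    draws = draw(design, n, seed)
    rows, failures = [], 0
    for i, (params, initial) in enumerate(draws):
        try:
            rows.append(_simulate_and_record(params, initial, settings, i,
                                             design.condition))
        except (IntegrationError, FloatingPointError) as exc:
            failures += 1
            log.warning("draw %d failed: %s", i, exc)
        if log_every and (i + 1) % log_every == 0:
            log.info("%s: %d/%d simulations done", design.condition, i + 1, n)
    return OutcomeTable(records=pd.DataFrame(rows), condition=design.condition,
                        n_requested=n, n_failures=failures)


def run_invasion_experiment(stable_design: SampleDesign | None, n: int,
                            seed: int,
                            settings: SolverSettings | None = None,
                            max_unstable_fraction: float = 0.01,
                            x3_spec: Spec | None = None,
                            log_every: int = 0) -> OutcomeTable:
    """Two-phase cheater invasion on the cooperator-stable design.

    Phase 1 verifies that each draw, run cooperator-only, reaches full
    stability; more than ``max_unstable_fraction`` of failures aborts with a
    design-quality error.  Phase 2 re-runs each verified draw with an
    initial cheater concentration drawn from the full range [0.01, 2) and
    classifies the outcome.  Phase-2 rows keep their phase-1 parameters
    identically; only ``X3_init`` differs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    settings = settings or SolverSettings()
    design = stable_design or cooperator_stable_design()
    x3_spec = x3_spec or Spec("loguniform", 0.01, 2.0)

    root = np.random.SeedSequence(seed)
    draw_seed, x3_seed = root.spawn(2)
    draws = draw(design, n, draw_seed)
    x3_rng = np.random.default_rng(x3_seed)
    x3_values = [x3_spec.sample(x3_rng) for _ in range(n)]

    unstable = 0
    rows = []
    failures = 0
    for i, (params, initial) in enumerate(draws):
        try:
            rec1 = _simulate_and_record(params, initial, settings, i,
                                        "invasion_phase1")
        except IntegrationError as exc:
            failures += 1
            log.warning("phase-1 draw %d failed: %s", i, exc)
            continue
        if rec1["category"] != "full_coexistence":
            unstable += 1
            continue
        invaded = SystemState(S=initial.S, E1=initial.E1, E2=initial.E2,
                              X1=initial.X1, X2=initial.X2, X3=x3_values[i])
        try:
            rec2 = _simulate_and_record(params, invaded, settings, i,
                                        "invasion_phase2")
        except IntegrationError as exc:
            failures += 1
            log.warning("phase-2 draw %d failed: %s", i, exc)
            continue
        rows.append(rec2)
        if log_every and (i + 1) % log_every == 0:
            log.info("invasion: %d/%d draws done", i + 1, n)
    if unstable > max_unstable_fraction * n:
        raise RuntimeError(
            f"cooperator-stable design failed verification: {unstable}/{n} "
            f"phase-1 runs were not fully stable "
            f"(tolerance {max_unstable_fraction:.1%})")
    return OutcomeTable(records=pd.DataFrame(rows), condition="invasion",
                        n_requested=n, n_failures=failures)


def run_grid(x_name: str, y_name: str,
             base: ParameterSet = STABLE_MEDIANS,
             initial: SystemState | None = None,
             resolution: int = 20,
             x_range: tuple[float, float] | None = None,
             y_range: tuple[float, float] | None = None,
             settings: SolverSettings | None = None,
             alpha_on: float = MEDIAN_ALPHA,
             x3_on: float = MEDIAN_X3_INIT,
             log_scale: bool | None = None) -> StabilityGrid:
    """Full-system stability over a 2-D slice of quantity space.

    Sweep ranges default to the Monte Carlo sampling ranges of the two
    quantities (log-spaced for log-uniform quantities, linear for D, Q, mu).
    All other quantities sit at the reference medians, with biofilm and
    cheaters enabled.
    """
    ref_design = default_design("coop_biofilm_cheater")
    for name in (x_name, y_name):
        if name not in ref_design.specs:
            raise ValueError(f"unknown quantity {name!r}")
    settings = settings or SolverSettings()
    initial = initial or SystemState(
        S=REFERENCE_INITIAL.S, E1=REFERENCE_INITIAL.E1, E2=0.0,
        X1=REFERENCE_INITIAL.X1, X2=0.0, X3=x3_on)
    base = base.replace(alpha=alpha_on).validate()

    def axis(name, rng_override):
        spec = ref_design.specs[name]
        lo, hi = rng_override if rng_override else (spec.lo, spec.hi)
        use_log = (spec.family == "loguniform") if log_scale is None else log_scale
        # sampling ranges are half-open [lo, hi): keep the grid inside
        if use_log:
            return np.exp(np.linspace(np.log(lo), np.log(hi), resolution,
                                      endpoint=False))
        return np.linspace(lo, hi, resolution, endpoint=False)

    xs = axis(x_name, x_range)
    ys = axis(y_name, y_range)
    stable = np.zeros((len(ys), len(xs)), dtype=bool)
    cats = np.empty((len(ys), len(xs)), dtype=object)
    t_eval = np.array([0.0, settings.t_end])
    for iy, yv in enumerate(ys):
        for ix, xv in enumerate(xs):
            p_kw = {}
            ic = {"S": initial.S, "E1": initial.E1, "E2": initial.E2,
                  "X1": initial.X1, "X2": initial.X2, "X3": initial.X3}
            for name, v in ((x_name, xv), (y_name, yv)):
                if name in INIT_NAMES:
                    ic[name.replace("_init", "")] = v
                else:
                    p_kw[name] = v
            p = base.replace(**p_kw)
            if p.K_S >= p.S0:   # swept S0 can undercut K_S; keep draw valid
                p = p.replace(K_S=0.5 * p.S0)
            y0 = SystemState(**ic)
            try:
                traj = integrate(p, y0, settings, t_eval=t_eval)
                label = classify_outcome(traj, _variants_present(p, y0))
                cats[iy, ix] = label.category
                stable[iy, ix] = label.category == "full_coexistence"
            except IntegrationError:
                cats[iy, ix] = "failed"
    return StabilityGrid(x_name=x_name, y_name=y_name, x_values=xs,
                         y_values=ys, stable=stable, categories=cats)


def summarize_outcomes(tables: dict[str, OutcomeTable],
                       quantities: list[str] | None = None,
                       stable_only: bool = True) -> pd.DataFrame:
    """Median/mean/IQR per quantity per condition + pairwise rank-sum tests.

    Compares the (by default) fully stable records of each condition.
    Returns a tidy frame with one row per (quantity, condition) carrying the
    summary statistics, and columns ``p_<other>`` with the two-sided
    Mann-Whitney U p-value against every other condition.
    """
    quantities = quantities or _QUANTITY_COLUMNS
    groups = {}
    for cond, table in tables.items():
        df = table.stable_subset() if stable_only else table.records
        if len(df) < 2:
            log.warning("condition %s has fewer than 2 records; excluded", cond)
            continue
        groups[cond] = df
    if len(groups) < 2:
        raise ValueError("need at least two conditions with >= 2 records each")

    rows = []
    for q in quantities:
        for cond, df in groups.items():
            if q not in df.columns:
                continue
            x = df[q].to_numpy(dtype=float)
            row = {"quantity": q, "condition": cond, "n": len(x),
                   "median": float(np.median(x)), "mean": float(np.mean(x)),
                   "q1": float(np.percentile(x, 25)),
                   "q3": float(np.percentile(x, 75))}
            for other, dfo in groups.items():
                if other == cond or q not in dfo.columns:
                    continue
                yv = dfo[q].to_numpy(dtype=float)
                if np.ptp(x) == 0 and np.ptp(yv) == 0 and x[0] == yv[0]:
                    row[f"p_{other}"] = 1.0   # degenerate identical constants
                else:
                    row[f"p_{other}"] = float(
                        mannwhitneyu(x, yv, alternative="two-sided").pvalue)
            rows.append(row)
    return pd.DataFrame(rows)
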