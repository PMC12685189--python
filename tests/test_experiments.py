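"""Experiment orchestration tests (scaled-down problem sizes)."""

import numpy as np
import pandas as pd
import pytest

from biofilmchemostat.experiments import (run_condition_panel, run_monte_carlo,
                                          run_invasion_experiment, run_grid,
                                          summarize_outcomes, OutcomeTable)
from biofilmchemostat.sample import (default_design, cooperator_stable_design,
                                     restrict_design, Spec)
from biofilmchemostat.simulate import SolverSettings


class TestConditionPanel:
    @pytest.fixture(scope="class")
    def panel(self):
        return run_condition_panel()

    def test_cooperators_persist_alone(self, panel):
        traj, label = panel["no_biofilm_no_cheater"]
        assert label.category == "full_coexistence"
        assert label.final_concentrations["X1"] > 0.01

    def test_cheaters_collapse_the_fluid_system(self, panel):
        _, label = panel["no_biofilm_cheater"]
        assert label.category == "tragedy"

    def test_biofilm_without_cheaters_persists(self, panel):
        _, label = panel["biofilm_no_cheater"]
        assert label.category == "full_coexistence"
        assert label.final_concentrations["X2"] > 0.01

    def test_biofilm_rescues_coexistence_with_cheaters(self, panel):
        _, label = panel["biofilm_cheater"]
        assert label.category == "full_coexistence"
        assert all(v > 0.01 for v in label.final_concentrations.values())


class TestMonteCarlo:
    def test_batch_determinism(self):
        d = default_design("coop_biofilm")
        a = run_monte_carlo(d, 20, seed=5, settings=SolverSettings(t_end=2000.0))
        b = run_monte_carlo(d, 20, seed=5, settings=SolverSettings(t_end=2000.0))
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_cooperator_only_yields_some_stable_outcomes(self):
        d = default_design("coop_only")
        t = run_monte_carlo(d, 150, seed=11)
        fr = t.category_fractions()
        assert fr["full_coexistence"] > 0.0

    def test_no_biofilm_with_cheaters_always_tragedy(self):
        d = default_design("coop_cheater_no_biofilm")
        t = run_monte_carlo(d, 100, seed=12)
        assert t.category_fractions()["tragedy"] == 1.0

    def test_n_guard(self):
        with pytest.raises(ValueError):
            run_monte_carlo(default_design("coop_only"), 0, seed=1)


class TestInvasionExperiment:
    def test_single_draw_reproducible(self):
        a = run_invasion_experiment(None, 1, seed=21)
        b = run_invasion_experiment(None, 1, seed=21)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_phase2_keeps_phase1_parameters(self):
        """Only the initial cheater concentration may differ from phase 1."""
        t = run_invasion_experiment(None, 10, seed=22)
        from biofilmchemostat.sample import draw
        import numpy as np
        root = np.random.SeedSequence(22)
        draw_seed, _ = root.spawn(2)
        drawn = draw(cooperator_stable_design(), 10, draw_seed)
        for (_, row), (params, initial) in zip(t.records.iterrows(), drawn):
            for name, value in params.to_dict().items():
                assert row[name] == pytest.approx(value, rel=1e-12)
            assert row["X1_init"] == pytest.approx(initial.X1, rel=1e-12)
            assert row["X3_init"] >= 0.01      # the one overridden quantity

    def test_no_biofilm_control_is_all_tragedy(self):
        """With adhesion off the fluid cooperators still verify stable alone,
        but every invaded run collapses — the biofilm is what rescues them."""
        design = restrict_design(cooperator_stable_design(),
                                 {"alpha": Spec.fixed(0.0)})
        # the design is calibrated for stability *with* the biofilm, so allow
        # a marginal phase-1 failure or two without the rescue pathway
        t = run_invasion_experiment(design, 20, seed=23,
                                    max_unstable_fraction=0.2)
        assert t.category_fractions()["tragedy"] == 1.0


class TestGrid:
    def test_single_cell_reduces_to_reference_scenario(self):
        from biofilmchemostat.model import STABLE_MEDIANS, MEDIAN_ALPHA
        g = run_grid("alpha", "beta_X", resolution=1,
                     x_range=(MEDIAN_ALPHA, MEDIAN_ALPHA * 1.0001),
                     y_range=(STABLE_MEDIANS.beta_X, STABLE_MEDIANS.beta_X * 1.0001))
        assert g.stable.shape == (1, 1)
        assert g.stable[0, 0]

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError):
            run_grid("alpha", "banana", resolution=2)


class TestSummarizeOutcomes:
    def _table(self, cond, values, cat="full_coexistence"):
        df = pd.DataFrame({"mu": values, "category": cat,
                           "condition": cond})
        return OutcomeTable(records=df, condition=cond, n_requested=len(df))

    def test_identical_groups_p_one(self):
        a = self._table("a", [1.0, 2.0, 3.0, 4.0])
        b = self._table("b", [1.0, 2.0, 3.0, 4.0])
        s = summarize_outcomes({"a": a, "b": b}, quantities=["mu"])
        assert np.all(s["p_b"].dropna() > 0.3)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 60)
        a = self._table("a", x)
        b = self._table("b", x + 100.0)
        s = summarize_outcomes({"a": a, "b": b}, quantities=["mu"])
        assert np.all(s["p_b"].dropna() < 1e-6)

    def test_medians_and_iqr_reported(self):
        a = self._table("a", [1.0, 2.0, 3.0, 4.0, 5.0])
        b = self._table("b", [2.0, 3.0, 4.0, 5.0, 6.0])
        s = summarize_outcomes({"a": a, "b": b}, quantities=["mu"])
        row = s[(s.quantity == "mu") & (s.condition == "a")].iloc[0]
        assert row["median"] == 3.0
        assert row["q1"] == 2.0 and row["q3"] == 4.0

    def test_too_few_groups_rejected(self):
        a = self._table("a", [1.0, 2.0])
        with pytest.raises(ValueError):
            summarize_outcomes({"a": a}, quantities=["mu"])
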