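"""Decision-procedure tests: Hommel, composite, CAFS, omnibus wiring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from alstrialsim import (TrialDesign, analyze_trial, cafs_strategy,
                         composite_event_times, composite_strategy,
                         cox_lme_omnibus_strategy, cox_strategy,
                         generate_trial, hommel_omnibus)
from alstrialsim.strategies import cafs_scores


class TestHommel:
    @pytest.mark.parametrize("p1,p2,expect", [
        (0.01, 0.50, True),     # min below alpha/2
        (0.04, 0.045, True),    # both below alpha
        (0.50, 0.60, False),
        (0.03, 0.20, False),    # min between alpha/2 and alpha, max above
    ])
    def test_decisions(self, p1, p2, expect):
        reject, adj = hommel_omnibus(p1, p2)
        assert reject is expect
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= np.array([p1, p2]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            hommel_omnibus(1.2, 0.5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(hst.floats(0.0, 1.0, allow_nan=False),
           hst.floats(0.0, 1.0, allow_nan=False))
    def test_matches_hochberg_closed_form(self, p1, p2):
        """For two hypotheses the Hommel step-up decision equals the
        Hochberg rule: reject iff max(p) <= alpha or min(p) <= alpha/2."""
        reject, _ = hommel_omnibus(p1, p2)
        assert reject == (max(p1, p2) <= 0.05 or min(p1, p2) <= 0.025)


class TestCompositeEndpoint:
    def test_functional_event_at_first_qualifying_visit(self, toy_builder):
        rows = [(0, 0, 0.0, 38.0), (0, 0, 1.0, 36.0), (0, 0, 2.0, 33.0),
                (0, 0, 3.0, 31.0)]
        ds = toy_builder(rows, [(0, 0, 12.0, 0)])
        comp = composite_event_times(ds)
        assert comp.status[0] == 1
        assert comp.time_months[0] == pytest.approx(3.0)   # first drop >= 6

    def test_death_before_functional_event(self, toy_builder):
        rows = [(0, 1, 0.0, 40.0), (0, 1, 1.0, 38.0), (0, 1, 4.0, 36.5)]
        ds = toy_builder(rows, [(0, 1, 5.0, 1)])
        comp = composite_event_times(ds)
        assert comp.status[0] == 1
        assert comp.time_months[0] == pytest.approx(5.0)

    def test_censored_when_drop_below_threshold(self, toy_builder):
        rows = [(0, 0, 0.0, 40.0), (0, 0, 6.0, 35.5), (0, 0, 12.0, 35.1)]
        ds = toy_builder(rows, [(0, 0, 12.0, 0)])
        comp = composite_event_times(ds)
        assert comp.status[0] == 0
        assert comp.time_months[0] == pytest.approx(12.0)


class TestCAFS:
    def test_death_outranked_by_survivor(self, toy_builder):
        rows = [(0, 0, 0.0, 38.0), (1, 1, 0.0, 38.0)]
        ds = toy_builder(rows, [(0, 0, 6.0, 1), (1, 1, 12.0, 0)])
        scores = cafs_scores(ds)
        assert scores[1] == 1 and scores[0] == -1

    def test_functional_comparison_among_survivors(self, toy_builder):
        rows = [(0, 0, 0.0, 40.0), (0, 0, 12.0, 30.0),    # change -10
                (1, 1, 0.0, 40.0), (1, 1, 12.0, 36.0)]    # change -4
        ds = toy_builder(rows, [(0, 0, 12.0, 0), (1, 1, 12.0, 0)])
        scores = cafs_scores(ds)
        assert scores[1] == 1 and scores[0] == -1

    def test_identical_subjects_p_one(self, toy_builder):
        rows, surv = [], []
        for sid in range(8):
            rows += [(sid, sid % 2, 0.0, 38.0), (sid, sid % 2, 12.0, 30.0)]
            surv.append((sid, sid % 2, 12.0, 0))
        ds = toy_builder(rows, surv)
        res = cafs_strategy(ds)
        assert res.p_value == 1.0 and not res.reject

    def test_score_matrix_antisymmetric(self, params):
        from alstrialsim.strategies import _cafs_score_matrix

        ds = generate_trial(params, TrialDesign(n_per_arm=40,
                                                max_followup=12.0, seed=13))
        u = _cafs_score_matrix(ds)
        assert np.array_equal(u, -u.T)
        assert np.all(np.diag(u) == 0)

    def test_label_permutation_exchangeable_under_null(self, params):
        """With no treatment effect the arm labels are exchangeable, so
        the observed joint-rank contrast is unremarkable within its own
        label-permutation distribution."""
        ds = generate_trial(params, TrialDesign(n_per_arm=40,
                                                max_followup=12.0, seed=37))
        res = cafs_strategy(ds, method="permutation", n_perm=500, seed=2)
        assert res.p_value > 0.01

    def test_permutation_agrees_with_ranksum(self, params):
        ds = generate_trial(params.with_scenario(0.66, 0.3),
                            TrialDesign(n_per_arm=60, max_followup=12.0,
                                        seed=19))
        a = cafs_strategy(ds, method="ranksum")
        b = cafs_strategy(ds, method="permutation", n_perm=4000, seed=1)
        assert abs(a.p_value - b.p_value) < 0.05
        assert a.reject == b.reject


class TestStrategyWiring:
    def test_identical_arms_give_null_result(self, params, toy_builder):
        """Mirroring every subject into both arms removes any contrast."""
        base = generate_trial(params, TrialDesign(n_per_arm=40,
                                                  max_followup=12.0, seed=29))
        surv = base.survival.copy()
        mirror = surv.copy()
        mirror["subject_id"] += 1000
        mirror["arm"] = 1 - mirror["arm"]
        both = pd.concat([surv, mirror], ignore_index=True)
        from alstrialsim.fitting import fit_cox

        fit = fit_cox(both)
        assert abs(fit.log_hr) < 1e-6
        assert fit.p_value > 0.999

    def test_analyze_trial_dispatch(self, small_trial):
        res = analyze_trial(small_trial, "cox")
        assert res.strategy == "cox"
        assert 0 <= res.p_value <= 1
        assert res.reject == (res.p_value < 0.05)
        with pytest.raises(ValueError, match="unknown strategy"):
            analyze_trial(small_trial, "bogus")

    def test_omnibus_p_is_min_adjusted(self, small_trial):
        res = cox_lme_omnibus_strategy(small_trial)
        cox = cox_strategy(small_trial)
        assert res.p_value >= min(cox.p_value, 1.0) - 1e-12

    def test_composite_counts_events(self, null_trial):
        res = composite_strategy(null_trial)
        assert 0.5 < res.extra["event_fraction"] <= 1.0
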