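"""Prognostic model, caliper matching and the modified Kraemer pipeline."""

import numpy as np
import pytest

from ptrkit import (
    DegenerateCompositeError,
    DegenerateScoreError,
    NoPairsError,
    build_all_pairs,
    fit_kraemer_ptr,
    fit_modified_kraemer_ptr,
    fit_prognostic_model,
    get_scenario,
    kraemer_weights,
    make_train_test,
    match_on_prognostic_score,
)
from ptrkit.errors import PTRError

from conftest import make_trial, random_trial


class TestPrognosticModel:
    def test_toy_controls_define_a_two_point_line(self, toy):
        model = fit_prognostic_model(toy)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)
        assert model.coefficients["X1"] == pytest.approx(1.0)
        assert model.score(toy) == pytest.approx([2.0, 0.0, 0.0, 2.0], abs=1e-9)

    def test_empty_prognostic_set_gives_control_mean(self):
        data = make_trial([5.0, 1.0, 3.0], [0.5, -0.5, -0.5],
                          {"Z1": [0.0, 1.0, 2.0]}, {"Z1": "moderator"})
        model = fit_prognostic_model(data)
        assert model.coefficients == {}
        assert model.intercept == pytest.approx(2.0)

    def test_outcome_shift_equivariance(self, toy):
        shifted = make_trial(toy.Y + np.where(toy.A < 0, 10.0, 0.0), toy.A,
                             {c: toy.biomarkers[c] for c in toy.biomarkers},
                             dict(toy.roles))
        s0 = fit_prognostic_model(toy).score(toy)
        s1 = fit_prognostic_model(shifted).score(shifted)
        assert s1 == pytest.approx(s0 + 10.0)

    def test_no_controls_raises(self):
        data = make_trial([1.0, 2.0], [0.5, 0.5], {"X1": [0.0, 1.0]},
                          {"X1": "prognostic"})
        with pytest.raises(PTRError):
            fit_prognostic_model(data)


class TestMatching:
    def test_toy_matches_by_score_distance_zero(self, toy):
        model = fit_prognostic_model(toy)
        pairs = match_on_prognostic_score(toy, model, caliper_sd=0.1)
        matched = set(zip(pairs.treated_id, pairs.control_id))
        assert matched == {("T1", "C2"), ("T2", "C1")}
        assert pairs.n_excluded == 0
        assert pairs.provenance == "matched"

    def test_every_matched_pair_is_within_caliper(self):
        spec = get_scenario("1a")
        train, _ = make_train_test(spec, 200, 21)
        data = train.data
        model = fit_prognostic_model(data)
        pairs = match_on_prognostic_score(data, model, caliper_sd=0.1)
        scores = dict(zip(data.subject_id, model.score(data)))
        caliper = 0.1 * np.std(model.score(data), ddof=1)
        for t, c in zip(pairs.treated_id, pairs.control_id):
            assert abs(scores[t] - scores[c]) <= caliper

    def test_single_control_infinite_caliper_reproduces_all_pairs(self):
        rng = np.random.default_rng(8)
        data = random_trial(rng, n=8, n_mod=1, n_prog=1)
        from ptrkit import PrognosticModel

        one_ctrl = data.subset(np.flatnonzero(data.A > 0).tolist()
                               + [int(np.flatnonzero(data.A < 0)[0])])
        model = PrognosticModel(intercept=0.0, coefficients={"X1": 1.0})
        matched = match_on_prognostic_score(one_ctrl, model, caliper_sd=np.inf)
        allp = build_all_pairs(one_ctrl)
        assert matched.n_pairs == allp.n_pairs
        assert np.allclose(np.sort(matched.dY), np.sort(allp.dY))

    def test_matched_rows_are_submultiset_of_all_pairs(self):
        spec = get_scenario("1a")
        train, _ = make_train_test(spec, 120, 13)
        data = train.data
        model = fit_prognostic_model(data)
        matched = match_on_prognostic_score(data, model)
        allp = build_all_pairs(data)
        # every matched (treated, control) key exists among all pairs and the
        # row values (dY, muZ, dX) agree exactly
        lookup = {(t, c): k for k, (t, c) in
                  enumerate(zip(allp.treated_id, allp.control_id))}
        for i, key in enumerate(zip(matched.treated_id, matched.control_id)):
            k = lookup[key]
            assert matched.dY[i] == allp.dY[k]
            assert np.array_equal(matched.muZ.iloc[i].to_numpy(),
                                  allp.muZ.iloc[k].to_numpy())
            assert np.array_equal(matched.dX.iloc[i].to_numpy(),
                                  allp.dX.iloc[k].to_numpy())

    def test_each_treated_appears_at_most_once_controls_may_repeat(self):
        spec = get_scenario("1a")
        train, _ = make_train_test(spec, 150, 5)
        model = fit_prognostic_model(train.data)
        pairs = match_on_prognostic_score(train.data, model)
        assert len(set(pairs.treated_id)) == pairs.n_pairs
        assert pairs.n_pairs + pairs.n_excluded == train.data.n_treated

    def test_constant_score_raises_degenerate(self):
        # no prognostic variables -> control-mean model -> constant score
        data = make_trial([1.0, 2.0, 0.0, 3.0], [0.5, 0.5, -0.5, -0.5],
                          {"Z1": [0.0, 1.0, 0.0, 1.0]}, {"Z1": "moderator"})
        model = fit_prognostic_model(data)
        with pytest.raises(DegenerateScoreError):
            match_on_prognostic_score(data, model)

    def test_unmatchable_treated_raises_no_pairs(self):
        data = make_trial([0.0, 0.1, 10.0, 10.1], [0.5, 0.5, -0.5, -0.5],
                          {"X1": [0.0, 0.1, 10.0, 10.1],
                           "Z1": [0.0, 1.0, 0.0, 1.0]},
                          {"X1": "prognostic", "Z1": "moderator"})
        model = fit_prognostic_model(data)
        with pytest.raises(NoPairsError):
            match_on_prognostic_score(data, model, caliper_sd=0.01)

    def test_equidistant_controls_break_tie_to_lowest_index(self):
        data = make_trial([1.0, 4.0, 2.0, 1.0], [0.5, -0.5, -0.5, -0.5],
                          {"X1": [1.0, 2.0, 0.0, 2.0],
                           "Z1": [0.0, 1.0, 0.0, 1.0]},
                          {"X1": "prognostic", "Z1": "moderator"})
        model = fit_prognostic_model(data)
        # scores are linear in X1; controls at X1=2 and X1=0 are equidistant
        # from the treated subject at X1=1
        pairs = match_on_prognostic_score(data, model, caliper_sd=np.inf)
        assert pairs.control_id == ("S2",)


class TestModifiedKraemer:
    def test_toy_pipeline_surfaces_degenerate_composite_with_diagnostics(self, toy):
        with pytest.raises(DegenerateCompositeError) as err:
            fit_modified_kraemer_ptr(toy)
        diag = err.value.diagnostics
        assert diag["n_matched"] == 2
        assert diag["weights"]["Z1"] == pytest.approx(0.0, abs=1e-12)

    def test_produces_valid_rules_on_nearly_all_replicates(self):
        spec = get_scenario("1a")
        ok = 0
        for seed in range(100):
            train, _ = make_train_test(spec, 300, 1000 + seed)
            try:
                fit_modified_kraemer_ptr(train.data)
                ok += 1
            except PTRError:
                pass
        assert ok >= 99

    def test_single_control_huge_caliper_equals_plain_kraemer(self):
        """With one control and an unbounded caliper the matched pair set is
        the all-pairs set, so the moderator weights coincide."""
        from ptrkit import PrognosticModel

        rng = np.random.default_rng(30)
        data = random_trial(rng, n=10, n_mod=2, n_prog=1)
        keep = np.flatnonzero(data.A > 0).tolist() + \
            [int(np.flatnonzero(data.A < 0)[0])]
        one_ctrl = data.subset(keep)
        model = PrognosticModel(intercept=0.0, coefficients={"X1": 1.0})
        matched = match_on_prognostic_score(one_ctrl, model, caliper_sd=np.inf)
        w_matched = kraemer_weights(matched)
        w_plain = kraemer_weights(build_all_pairs(one_ctrl))
        for k in w_plain.weights:
            assert w_matched.weights[k] == pytest.approx(w_plain.weights[k])
        assert w_matched.intercept == pytest.approx(w_plain.intercept)

    def test_diagnostics_report_matching_counts_and_weights(self):
        spec = get_scenario("1a")
        train, _ = make_train_test(spec, 300, 17)
        rule = fit_modified_kraemer_ptr(train.data)
        diag = rule.diagnostics
        assert diag["n_matched"] + diag["n_excluded"] == train.data.n_treated
        assert set(diag["weights"]) == set(train.data.moderator_names)
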