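import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perimark import (
    AbundanceTable,
    CohortLabels,
    ComboScoreModel,
    PlantedCombo,
    SyntheticSpec,
    ValidationError,
    combo_score,
    fit_combo_model,
    generate_cohort,
    predict_combo,
    score_samples,
)
from perimark.combo import score_terms, tune_threshold
from perimark.metrics import confusion, sensitivity, specificity


def unit_model(median_pi, median_hi, weights=None, threshold=0.0):
    n = len(median_pi)
    return ComboScoreModel(
        taxa=tuple(f"t{i}" for i in range(n)),
        median_pi=median_pi,
        median_hi=median_hi,
        weights=np.ones(n) if weights is None else weights,
        threshold=threshold,
    )


class TestScore:
    def test_sample_at_pi_medians_scores_plus_100n(self):
        model = unit_model([10.0, 5.0, 2.0], [1.0, 1.0, 1.0])
        assert combo_score(model, [10.0, 5.0, 2.0]) == pytest.approx(300.0)

    def test_sample_at_hi_medians_scores_minus_100n(self):
        model = unit_model([10.0, 5.0, 2.0], [1.0, 1.0, 1.0])
        assert combo_score(model, [1.0, 1.0, 1.0]) == pytest.approx(-300.0)

    def test_equidistant_sample_scores_zero(self):
        model = unit_model([10.0], [2.0], weights=[0.5])
        assert combo_score(model, [6.0]) == pytest.approx(0.0)

    def test_hand_computed_term(self):
        """median_PI=10, median_HI=2, x=8, W=0.5: P=2, N=6, S=100*0.5*4/8=25."""
        model = unit_model([10.0], [2.0], weights=[0.5])
        assert combo_score(model, [8.0]) == pytest.approx(25.0)

    def test_coinciding_medians_contribute_zero(self):
        model = unit_model([3.0, 10.0], [3.0, 2.0])
        # first taxon: P=N=0 at x=3 -> term 0; second taxon at PI median -> +100
        assert combo_score(model, [3.0, 10.0]) == pytest.approx(100.0)

    def test_missing_taxon_rejected(self):
        model = unit_model([10.0], [2.0])
        with pytest.raises(ValidationError, match="missing"):
            combo_score(model, {"other": 1.0})

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_score_bounded_additive_and_order_invariant(self, data):
        n = data.draw(st.integers(2, 4))
        floats = st.floats(0.0, 1e5, allow_nan=False)
        med_pi = data.draw(st.lists(floats, min_size=n, max_size=n))
        med_hi = data.draw(st.lists(floats, min_size=n, max_size=n))
        weights = data.draw(
            st.lists(st.floats(0.0, 1.0), min_size=n, max_size=n)
        )
        x = np.array(data.draw(st.lists(floats, min_size=n, max_size=n)))
        model = unit_model(med_pi, med_hi, weights)
        s = combo_score(model, x)
        # bounded by the weight budget
        assert abs(s) <= 100.0 * np.sum(weights) + 1e-9
        # additive: dropping the last taxon subtracts exactly its term
        term_last = float(score_terms(model, x[None, :])[0, -1])
        if n > 2:
            sub = unit_model(med_pi[:-1], med_hi[:-1], weights[:-1])
            assert combo_score(sub, x[:-1]) == pytest.approx(
                s - term_last, abs=1e-9
            )
        # invariant under taxon reordering
        perm = data.draw(st.permutations(range(n)))
        perm = list(perm)
        reordered = ComboScoreModel(
            taxa=tuple(f"t{i}" for i in perm),
            median_pi=np.asarray(med_pi)[perm],
            median_hi=np.asarray(med_hi)[perm],
            weights=np.asarray(weights)[perm],
        )
        assert combo_score(reordered, x[perm]) == pytest.approx(s, abs=1e-9)

    def test_moving_toward_pi_median_never_decreases_term(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            mpi, mhi, x = rng.uniform(0, 100, size=3)
            model = unit_model([mpi], [mhi])
            before = combo_score(model, [x])
            after = combo_score(model, [mpi])  # jump to the PI median
            assert after >= before - 1e-9


class TestFit:
    def test_presence_weight_for_pi_exclusive_taxon(self):
        """Taxon detected in all 20 PI and no HI training samples:
        W = (1 + 0.025) / (1 + 0 + 0.05)."""
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(40)]
        values = np.zeros((40, 2))
        values[:20, 0] = rng.lognormal(size=20) + 0.1  # PI-only taxon
        values[:, 1] = rng.lognormal(size=40) + 0.1
        table = AbundanceTable(pd.DataFrame(values, index=ids, columns=["a", "b"]))
        labels = CohortLabels(pd.Series(["PI"] * 20 + ["HI"] * 20, index=ids))
        model = fit_combo_model(table, labels, ["a", "b"], tune=False)
        assert model.weights[0] == pytest.approx(1.025 / 1.05)

    def test_equal_prevalence_gives_half(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(40)]
        values = rng.lognormal(size=(40, 2)) + 0.1  # present everywhere
        table = AbundanceTable(pd.DataFrame(values, index=ids, columns=["a", "b"]))
        labels = CohortLabels(pd.Series(["PI"] * 20 + ["HI"] * 20, index=ids))
        model = fit_combo_model(table, labels, ["a", "b"], tune=False)
        assert np.allclose(model.weights, 0.5)

    def test_all_zero_taxon_warns_and_gets_half_weight(self):
        ids = [f"s{i}" for i in range(8)]
        values = np.ones((8, 2))
        values[:, 0] = 0.0
        table = AbundanceTable(pd.DataFrame(values, index=ids, columns=["z", "b"]))
        labels = CohortLabels(pd.Series(["PI"] * 4 + ["HI"] * 4, index=ids))
        with pytest.warns(UserWarning, match="all-zero"):
            model = fit_combo_model(table, labels, ["z", "b"], tune=False)
        assert model.weights[0] == pytest.approx(0.5)

    def test_panel_size_bounds(self, tiny_table, tiny_labels):
        with pytest.raises(ValidationError, match="panel size"):
            fit_combo_model(tiny_table, tiny_labels, ["taxA"])

    def test_training_medians_use_train_samples_only(self, tiny_table, tiny_labels):
        model = fit_combo_model(
            tiny_table, tiny_labels, ["taxA", "taxB"],
            train_samples=["s0", "s1", "s3", "s4"],
        )
        assert model.median_pi[0] == pytest.approx(110.0)  # median(100, 120)
        assert model.median_hi[0] == pytest.approx(11.0)  # median(10, 12)

    def test_perfectly_separating_planted_combo(self):
        """A fully penetrant planted panel separates its training samples."""
        spec = SyntheticSpec.saliva_like(
            n_bacteria=150, n_fungi=20, n_virus=80,
            planted_combo=PlantedCombo((10, 60, 200), multiplier=20, penetrance=1.0),
            seed=8,
        )
        table, labels = generate_cohort(spec)
        ids = spec.planted_truth()["combo"]["taxon_ids"]
        model = fit_combo_model(table, labels, ids)
        pred = predict_combo(model, table)
        c = confusion(pred, labels)
        assert min(sensitivity(c), specificity(c)) == 1.0

    def test_heldout_recovery_performance(self, planted_cohort):
        """Fitted on <50% of the cohort, the true planted panel classifies
        held-out samples with sensitivity and specificity >= 0.9."""
        spec, table, labels = planted_cohort
        ids = spec.planted_truth()["combo"]["taxon_ids"]
        rng = np.random.default_rng(17)
        train = (
            list(rng.choice(labels.group_samples("PI"), 8, replace=False))
            + list(rng.choice(labels.group_samples("HI"), 8, replace=False))
        )
        test = [s for s in table.sample_ids if s not in train]
        model = fit_combo_model(table, labels, ids, train_samples=train)
        pred = predict_combo(model, table.subset_samples(test))
        c = confusion(pred, labels)
        assert sensitivity(c) >= 0.9
        assert specificity(c) >= 0.9


class TestPredict:
    def test_threshold_rule(self):
        model = unit_model([10.0, 10.0, 10.0], [1.0, 1.0, 1.0])
        ids = ["pi_like", "hi_like"]
        table = AbundanceTable(
            pd.DataFrame(
                [[10.0, 10.0, 10.0], [1.0, 1.0, 1.0]],
                index=ids,
                columns=["t0", "t1", "t2"],
            )
        )
        assert list(predict_combo(model, table)) == ["PI", "HI"]

    def test_score_equal_to_threshold_predicts_hi(self):
        model = unit_model([10.0], [2.0], threshold=25.0)
        table = AbundanceTable(pd.DataFrame({"t0": [8.0]}, index=["s"]))
        # S = 50 * (6-2)/8 * ... with W=1: 100*(4/8)=50 > 25 -> PI
        assert list(predict_combo(model, table)) == ["PI"]
        model.threshold = 50.0  # S == tau exactly
        assert list(predict_combo(model, table)) == ["HI"]

    def test_score_samples_matches_combo_score(self, tiny_table):
        model = unit_model([100.0, 5.0], [10.0, 6.0])
        model = ComboScoreModel(
            taxa=("taxA", "taxB"),
            median_pi=model.median_pi,
            median_hi=model.median_hi,
            weights=model.weights,
        )
        scores = score_samples(model, tiny_table)
        for sid in tiny_table.sample_ids:
            row = tiny_table.data.loc[sid, ["taxA", "taxB"]]
            assert scores[sid] == pytest.approx(combo_score(model, row))


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        model = unit_model([10.0, 2.0], [1.0, 5.0], weights=[0.7, 0.3], threshold=12.5)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ComboScoreModel.from_json(path)
        assert back.taxa == model.taxa
        assert np.allclose(back.median_pi, model.median_pi)
        assert np.allclose(back.weights, model.weights)
        assert back.threshold == model.threshold


class TestTuneThreshold:
    def test_prefers_zero_when_tied(self):
        scores = np.array([-50.0, -40.0, 40.0, 50.0])
        is_pi = np.array([False, False, True, True])
        assert tune_threshold(scores, is_pi) == 0.0

    def test_moves_when_zero_is_suboptimal(self):
        scores = np.array([10.0, 20.0, 60.0, 70.0])
        is_pi = np.array([False, False, True, True])
        tau = tune_threshold(scores, is_pi)
        assert tau == pytest.approx(40.0)
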