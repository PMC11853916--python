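import numpy as np
import pandas as pd
import pytest

from perimark import (
    AbundanceTable,
    CohortLabels,
    EvoConfig,
    ValidationError,
    evolve_combinations,
    fit_combo_model,
    score_samples,
)
from perimark.evolve import stratified_split


def toy_cohort():
    """Six taxa, 20 samples; taxa t0+t1 jointly separate the groups."""
    rng = np.random.default_rng(42)
    n = 20
    is_pi = np.array([True] * 10 + [False] * 10)
    values = rng.lognormal(2.0, 0.4, size=(n, 6))
    # t0 up-shifted in the first 7 PI samples, t1 in the last 7 -> overlap
    values[0:7, 0] *= 15.0
    values[3:10, 1] *= 15.0
    ids = [f"s{i}" for i in range(n)]
    table = AbundanceTable(
        pd.DataFrame(values, index=ids, columns=[f"t{j}" for j in range(6)])
    )
    labels = CohortLabels(
        pd.Series(np.where(is_pi, "PI", "HI"), index=ids)
    )
    return table, labels


def resubstitution_fitness(table, labels, panel, train):
    """Independent route to the training fitness tuple via the public API."""
    model = fit_combo_model(table, labels, list(panel), train_samples=train)
    scores = score_samples(model, table).loc[train]
    is_pi = (labels.labels.loc[train] == "PI").to_numpy()
    pred = (scores > model.threshold).to_numpy()
    sens = (pred & is_pi).sum() / is_pi.sum()
    spec = (~pred & ~is_pi).sum() / (~is_pi).sum()
    lo, hi = scores[is_pi], scores[~is_pi]
    margin = (np.median(lo) - np.median(hi)) + (lo.min() - hi.max())
    return (float(min(sens, spec)), float(sens + spec), float(margin))


class TestConfigValidation:
    def test_half_training_fraction_rejected(self):
        with pytest.raises(ValidationError, match="below 0.5"):
            EvoConfig(train_fraction=0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 1},
            {"generations": 0},
            {"mutation_rate": 1.5},
            {"elitism": 50},
            {"fitness_mode": "magic"},
            {"cv_fit_fraction": 0.2},
            {"candidate_bias": 2.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            EvoConfig(**kwargs)

    def test_too_few_taxa_rejected(self):
        ids = ["a", "b", "c", "d", "e", "f", "g", "h"]
        table = AbundanceTable(
            pd.DataFrame(
                np.random.default_rng(0).lognormal(size=(8, 3)),
                index=ids,
                columns=["x", "y", "z"],
            )
        )
        labels = CohortLabels(pd.Series(["PI"] * 4 + ["HI"] * 4, index=ids))
        with pytest.raises(ValidationError, match="nonzero variance"):
            evolve_combinations(table, labels, EvoConfig(n_models=1))


class TestSearch:
    def test_exhaustive_pairs_match_brute_force(self):
        """Seeded with every size-2 panel of a 6-taxon table and a single
        generation, the search returns the brute-force optimum of its own
        fitness (computed here through the public fitting API)."""
        table, labels = toy_cohort()
        panels = [
            (f"t{i}", f"t{j}") for i in range(6) for j in range(i + 1, 6)
        ]
        config = EvoConfig(
            n_models=1,
            generations=1,
            population_size=15,
            mutation_rate=0.0,
            crossover_rate=0.0,
            elitism=1,
            seed=5,
            fitness_mode="resubstitution",
        )
        result = evolve_combinations(
            table, labels, config, initial_population=panels
        )
        best = result.models[0]

        rng = np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0])
        train, _ = stratified_split(labels, config.train_fraction, rng)
        best_bf, best_fit = None, None
        for panel in panels:
            f = resubstitution_fitness(table, labels, panel, train)
            if best_fit is None or f > best_fit:
                best_bf, best_fit = panel, f
        assert tuple(sorted(best.model.taxa)) == tuple(sorted(best_bf))

    def test_seeded_optimum_never_beaten_silently(self):
        """The returned fitness is at least that of any seeded panel."""
        table, labels = toy_cohort()
        config = EvoConfig(
            n_models=1, generations=3, population_size=10, seed=2,
            fitness_mode="resubstitution",
        )
        result = evolve_combinations(
            table, labels, config,
            initial_population=[("t0", "t1"), ("t2", "t3")],
        )
        rng = np.random.default_rng(np.random.SeedSequence(2).spawn(1)[0])
        train, _ = stratified_split(labels, config.train_fraction, rng)
        seeded = resubstitution_fitness(table, labels, ("t0", "t1"), train)
        assert result.models[0].fitness >= seeded

    def test_identical_seeds_identical_results(self, null_cohort_small):
        table, labels = null_cohort_small
        config = EvoConfig(
            n_models=3, generations=10, population_size=12, seed=7
        )
        r1 = evolve_combinations(table, labels, config)
        r2 = evolve_combinations(table, labels, config)
        for a, b in zip(r1.models, r2.models):
            assert a.model.taxa == b.model.taxa
            assert a.model.threshold == b.model.threshold
            assert a.test_report.sensitivity == b.test_report.sensitivity
            assert a.train_samples == b.train_samples
        assert r1.biomarker_counts == r2.biomarker_counts

    def test_biomarker_counts_sum_to_panel_sizes(self, null_cohort_small):
        table, labels = null_cohort_small
        config = EvoConfig(
            n_models=4, generations=5, population_size=10, seed=1
        )
        result = evolve_combinations(table, labels, config)
        assert sum(result.biomarker_counts.values()) == sum(
            r.model.n_taxa for r in result.models
        )
        for r in result.models:
            assert 2 <= r.model.n_taxa <= 4

    def test_null_data_heldout_band(self, null_cohort_small):
        """Without planted signal the best panels do not generalize: mean
        held-out min(sens, spec) stays at or below the overfit chance band."""
        table, labels = null_cohort_small
        config = EvoConfig(
            n_models=10, generations=20, population_size=20, seed=3
        )
        result = evolve_combinations(table, labels, config)
        heldout = np.mean(
            [
                min(r.test_report.sensitivity, r.test_report.specificity)
                for r in result.models
            ]
        )
        assert heldout <= 0.75

    def test_fast_path_matches_public_fit(self, planted_cohort):
        """The model returned for the best panel equals refitting that
        panel with fit_combo_model on the same training samples."""
        _, table, labels = planted_cohort
        config = EvoConfig(n_models=1, generations=5, population_size=10, seed=4)
        result = evolve_combinations(table, labels, config)
        run = result.models[0]
        refit = fit_combo_model(
            table, labels, run.model.taxa, train_samples=run.train_samples
        )
        assert np.allclose(refit.median_pi, run.model.median_pi)
        assert np.allclose(refit.weights, run.model.weights)
        assert refit.threshold == run.model.threshold
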