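"""Evolution-inspired search for high-performing biomarker panels.

Each independent run draws a stratified train/test split (training
fraction strictly below 50% of the cohort), then evolves a population of
distinct-taxon panels (size 2-4 by default) under a multi-objective
fitness built from the training samples only: ``min(sensitivity,
specificity)`` with ``sensitivity + specificity`` and a score-separation
margin breaking ties. With only a handful of training samples a panel
can trivially memorize them, so by default the fitness is estimated by
repeated stratified splits *inside* the training set (fit statistics on
one part, score the rest, pool), which keeps memorizing panels near
chance; panel draws are biased toward a shortlist of taxa whose score
terms best order the groups on the training samples. Selection is by
tournament (k = 3), variation by taxon-exchange crossover, single-taxon
replacement and panel resizing, and elitism carries the top panels over
unchanged, so the best-so-far fitness never decreases. After the last
generation the best panel is refitted through
:func:`perimark.combo.fit_combo_model` and re-evaluated on the held-out
test samples and on the full cohort.

Running ``n_models`` independent seeded runs yields the population of
candidate classifiers that downstream ranking and biomarker frequency
counting summarize.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .combo import (
    ComboScoreModel,
    fit_combo_model,
    predict_combo,
    presence_weights,
    abundance_ratio_weights,
    score_samples,
    tune_threshold,
)
from .errors import SplitError, ValidationError
from .io import AbundanceTable, CohortLabels
from .metrics import PerformanceReport, evaluate_scores

_TOURNAMENT_K = 3


@dataclass
class EvoConfig:
    """Search hyperparameters. Defaults: 50 panels evolved for 100
    generations per run, 100 independent runs, 40% of samples for training."""

    population_size: int = 50
    generations: int = 100
    combo_size_range: tuple = (2, 4)
    train_fraction: float = 0.4
    mutation_rate: float = 0.3
    crossover_rate: float = 0.5
    elitism: int = 2
    n_models: int = 100
    seed: int = 0
    weight_scheme: str = "presence"
    tune_threshold: bool = True
    fitness_mode: str = "split"  # "split" (CV inside train) or "resubstitution"
    cv_repeats: int = 12  # random-split repeats pooled by the "split" fitness
    cv_fit_fraction: float = 0.6  # training-split share fitted per repeat
    candidate_pool_size: int = 15  # shortlist of taxa with the largest
    # training-score separation, used to bias panel draws
    candidate_bias: float = 0.9  # probability a new taxon is drawn from the
    # shortlist instead of uniformly from all taxa

    def __post_init__(self) -> None:
        if self.fitness_mode not in ("split", "resubstitution"):
            raise ValidationError(
                "fitness_mode must be 'split' or 'resubstitution'"
            )
        if self.cv_repeats < 1:
            raise ValidationError("cv_repeats must be >= 1")
        if not 0.5 <= self.cv_fit_fraction < 1.0:
            raise ValidationError("cv_fit_fraction must be in [0.5, 1)")
        if self.candidate_pool_size < 0:
            raise ValidationError("candidate_pool_size must be >= 0")
        if not 0.0 <= self.candidate_bias <= 1.0:
            raise ValidationError("candidate_bias must be in [0, 1]")
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        lo, hi = self.combo_size_range
        if not (1 <= lo <= hi):
            raise ValidationError("combo_size_range must satisfy 1 <= lo <= hi")
        if not 0.0 < self.train_fraction < 0.5:
            raise ValidationError(
                "train_fraction must be strictly below 0.5 "
                "(training uses less than half of the cohort)"
            )
        for name in ("mutation_rate", "crossover_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0 <= self.elitism < self.population_size:
            raise ValidationError("elitism must be in [0, population_size)")
        if self.n_models < 1:
            raise ValidationError("n_models must be >= 1")


@dataclass
class EvoRunResult:
    """Best panel of one independent run with its three evaluations."""

    model: ComboScoreModel
    train_report: PerformanceReport
    test_report: PerformanceReport
    full_report: PerformanceReport
    run_index: int
    train_samples: list
    test_samples: list
    fitness: tuple  # (min(sens, spec), sens + spec) on training samples


@dataclass
class SearchResult:
    """All run results plus how often each taxon appears across best panels."""

    models: list = field(default_factory=list)
    biomarker_counts: dict = field(default_factory=dict)


def stratified_split(labels: CohortLabels, train_fraction: float, rng):
    """Per-group random split; every group keeps >= 1 sample on each side."""
    train, test = [], []
    for group in ("HI", "PI"):
        samples = labels.group_samples(group)
        n = len(samples)
        if n < 2:
            raise SplitError(f"group {group} has {n} sample(s); cannot split")
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        train += [samples[i] for i in perm[:n_train]]
        test += [samples[i] for i in perm[n_train:]]
    return train, test


def _term_rows(median_pi, median_hi, weights, block):
    """Per-taxon score-term rows: (n_taxa, n_samples) for an abundance block."""
    x = block.T
    p = np.abs(median_pi[:, None] - x)
    n = np.abs(median_hi[:, None] - x)
    denom = p + n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = 100.0 * weights[:, None] * (n - p) / denom
    terms[denom == 0] = 0.0
    return terms


def _group_stats(block, is_pi, eligible, weight_scheme):
    pi_block, hi_block = block[is_pi], block[~is_pi]
    median_pi = np.median(pi_block, axis=0)
    median_hi = np.median(hi_block, axis=0)
    if weight_scheme == "presence":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            weights = presence_weights(pi_block, hi_block, eligible)
    else:
        weights = abundance_ratio_weights(pi_block, hi_block)
    return median_pi, median_hi, weights


class _RunContext:
    """Per-run precomputation: train statistics for every eligible taxon.

    Scoring a panel reduces to summing precomputed per-taxon score-term
    rows, which keeps each fitness evaluation O(panel * n_train). The
    full-train rows reproduce :func:`fit_combo_model` on the same
    training samples exactly; for the cross-validated fitness the training
    split is itself halved (stratified), and each half's statistics are
    used to score the opposite half.
    """

    def __init__(
        self, table, labels, train_samples, eligible, weight_scheme, rng,
        cv_repeats: int = 12, cv_fit_fraction: float = 0.6,
    ):
        self.taxon_ids = eligible
        data = table.data[eligible]
        groups = labels.labels.loc[train_samples]
        block = data.loc[train_samples].to_numpy()
        is_pi = (groups == "PI").to_numpy()
        self.is_pi_train = is_pi

        self.median_pi, self.median_hi, self.weights = _group_stats(
            block, is_pi, eligible, weight_scheme
        )
        self.train_terms = _term_rows(
            self.median_pi, self.median_hi, self.weights, block
        )
        # taxa ranked by how well their training score terms order the two
        # groups (per-taxon rank statistic |AUC - 1/2|, robust to the heavy
        # tails of abundance data); the head seeds the candidate shortlist
        from scipy.stats import rankdata

        ranks = rankdata(self.train_terms, axis=1)
        n_pi, n_hi = int(is_pi.sum()), int((~is_pi).sum())
        u = ranks[:, is_pi].sum(axis=1) - n_pi * (n_pi + 1) / 2.0
        auc = u / (n_pi * n_hi)
        self.separation_rank = np.argsort(-np.abs(auc - 0.5), kind="stable")

        # repeated stratified splits of the training samples for the
        # cross-validated fitness; each repeat fits per-taxon statistics on
        # cv_fit_fraction of the training split and scores the rest
        idx = np.arange(len(train_samples))
        self.half_terms = []  # terms of the held-out part under the fit stats
        self.half_is_pi = []
        self.half_fit_terms = []  # terms of the fitting part itself (for tau)
        self.half_fit_is_pi = []
        for _repeat in range(cv_repeats):
            fit_mask = np.zeros(len(idx), dtype=bool)
            for mask in (is_pi, ~is_pi):
                members = idx[mask]
                n_fit = max(2, int(round(cv_fit_fraction * len(members))))
                n_fit = min(n_fit, len(members) - 1)
                picked = rng.permutation(members)[:n_fit]
                fit_mask[picked] = True
            m_pi, m_hi, w = _group_stats(
                block[fit_mask], is_pi[fit_mask], eligible, weight_scheme
            )
            self.half_fit_terms.append(_term_rows(m_pi, m_hi, w, block[fit_mask]))
            self.half_fit_is_pi.append(is_pi[fit_mask])
            self.half_terms.append(_term_rows(m_pi, m_hi, w, block[~fit_mask]))
            self.half_is_pi.append(is_pi[~fit_mask])


def _sens_spec(pred_pi, is_pi):
    sens = (pred_pi & is_pi).sum() / is_pi.sum()
    spec = (~pred_pi & ~is_pi).sum() / (~is_pi).sum()
    return sens, spec


def _evaluate_panel(ctx: _RunContext, panel: tuple, tune: bool, mode: str):
    """(fitness, tau) of a panel, using training samples only.

    Fitness is the tuple (min(sens, spec), sens + spec, margin), where
    margin combines the central and the worst-case score gap between the
    groups — (median S over PI − median S over HI) plus (min S over PI −
    max S over HI), in raw score units. A panel that classifies the
    evaluation samples correctly only by a hair has a margin near zero,
    while a panel whose score distributions genuinely separate keeps a
    wide one, so ties at the top resolve toward robust separation rather
    than lucky threshold placement; the central term rewards partners
    that shift the bulk of the score distribution, not just its extremes.

    In ``"split"`` mode (the default) the metrics are cross-validated
    inside the training split: medians, weights and the threshold are
    fitted on one stratified half and evaluated on the other, both ways,
    and the held-within-train predictions are pooled. This keeps panels
    that only memorize the training samples near chance while genuinely
    discriminating panels stay near 1, so the search can tell them apart.
    ``"resubstitution"`` scores the training samples with statistics
    fitted on all of them (optimistically biased).
    """
    panel = list(panel)
    if mode == "resubstitution":
        scores = ctx.train_terms[panel].sum(axis=0)
        is_pi = ctx.is_pi_train
        tau = tune_threshold(scores, is_pi) if tune else 0.0
        sens, spec = _sens_spec(scores > tau, is_pi)
        margin = float(
            (np.median(scores[is_pi]) - np.median(scores[~is_pi]))
            + (scores[is_pi].min() - scores[~is_pi].max())
        )
        return (float(min(sens, spec)), float(sens + spec), margin), tau

    preds, truths, margins = [], [], []
    for fold in range(len(ctx.half_terms)):
        fit_scores = ctx.half_fit_terms[fold][panel].sum(axis=0)
        tau = tune_threshold(fit_scores, ctx.half_fit_is_pi[fold]) if tune else 0.0
        out_scores = ctx.half_terms[fold][panel].sum(axis=0)
        out_is_pi = ctx.half_is_pi[fold]
        preds.append(out_scores > tau)
        truths.append(out_is_pi)
        lo, hi = out_scores[out_is_pi], out_scores[~out_is_pi]
        margins.append(
            (np.median(lo) - np.median(hi)) + (lo.min() - hi.max())
        )
    pred_pi = np.concatenate(preds)
    is_pi = np.concatenate(truths)
    sens, spec = _sens_spec(pred_pi, is_pi)
    margin = float(np.mean(margins))
    # tau for reporting: tuned on the full training split
    scores = ctx.train_terms[panel].sum(axis=0)
    full_tau = tune_threshold(scores, ctx.is_pi_train) if tune else 0.0
    return (float(min(sens, spec)), float(sens + spec), margin), full_tau


class _TaxonSampler:
    """Draws new panel taxa during initialization, crossover and mutation.

    With probability ``bias`` the taxon comes from a shortlist of taxa
    whose training score terms best separate the groups (an informed
    candidate prior computed from the training samples only); otherwise it
    is drawn uniformly from all eligible taxa. Already-used taxa are never
    returned.
    """

    def __init__(self, n_taxa: int, shortlist, bias: float):
        self.n_taxa = n_taxa
        self.shortlist = np.asarray(shortlist, dtype=int)
        self.bias = bias

    def draw(self, rng, used) -> int:
        used_arr = np.asarray(sorted(used), dtype=int)
        if self.shortlist.size and rng.random() < self.bias:
            cands = self.shortlist[~np.isin(self.shortlist, used_arr)]
            if cands.size:
                return int(rng.choice(cands))
        choices = np.setdiff1d(np.arange(self.n_taxa), used_arr)
        return int(rng.choice(choices))


def _random_panel(rng, sampler: _TaxonSampler, size_range: tuple) -> tuple:
    size = int(rng.integers(size_range[0], size_range[1] + 1))
    panel: list = []
    while len(panel) < size:
        panel.append(sampler.draw(rng, panel))
    return tuple(sorted(panel))


def _crossover(rng, a: tuple, b: tuple, sampler: _TaxonSampler, size_range) -> tuple:
    """Child drawn from the parents' pooled taxa, duplicates resampled."""
    size = len(a) if rng.random() < 0.5 else len(b)
    pool = np.array(sorted(set(a) | set(b)))
    if pool.size >= size:
        child = rng.choice(pool, size=size, replace=False).tolist()
    else:
        child = pool.tolist()
        while len(child) < size:
            child.append(sampler.draw(rng, child))
    return tuple(sorted(child))


def _mutate(rng, panel: tuple, sampler: _TaxonSampler, size_range: tuple) -> tuple:
    """Replace one taxon with an unused one, or resize within range."""
    panel = list(panel)
    lo, hi = size_range
    grow_ok = len(panel) < hi
    shrink_ok = len(panel) > lo
    op = rng.random()
    if op < 0.5 or not (grow_ok or shrink_ok):
        drop = int(rng.integers(len(panel)))
        panel[drop] = sampler.draw(rng, panel)
    elif grow_ok and (not shrink_ok or rng.random() < 0.5):
        panel.append(sampler.draw(rng, panel))
    else:
        panel.pop(int(rng.integers(len(panel))))
    return tuple(sorted(panel))


def _tournament(rng, population, fitnesses, k: int = _TOURNAMENT_K):
    # ties resolve to the earliest slot, so equal-fitness panels found
    # earlier are preferred (no drift pressure from taxon indices)
    idx = sorted(rng.integers(len(population), size=k).tolist())
    best = max(idx, key=lambda i: (fitnesses[i], -i))
    return population[best]


def evolve_combinations(
    table: AbundanceTable,
    labels: CohortLabels,
    config: EvoConfig,
    initial_population: Optional[Sequence] = None,
) -> SearchResult:
    """Run ``config.n_models`` independent evolutionary searches.

    ``initial_population`` (a list of taxon-id tuples) can seed every
    run's starting population — e.g. an exhaustive enumeration of small
    panels to compare the search against brute force. Results are fully
    reproducible for a fixed ``config.seed``.
    """
    labels.require_both_groups()
    aligned = labels.align_with(table)
    for group in ("HI", "PI"):
        if int((aligned == group).sum()) < 4:
            raise ValidationError(f"group {group} needs at least 4 samples")

    variances = table.data.to_numpy().var(axis=0)
    eligible = [t for t, v in zip(table.taxon_ids, variances) if v > 0]
    max_size = config.combo_size_range[1]
    if len(eligible) < max_size:
        raise ValidationError(
            f"need at least {max_size} taxa with nonzero variance, "
            f"found {len(eligible)}"
        )
    taxon_index = {t: i for i, t in enumerate(eligible)}
    n_taxa = len(eligible)

    seed_pop = None
    if initial_population is not None:
        seed_pop = []
        for panel in initial_population:
            idx = tuple(sorted(taxon_index[t] for t in panel))
            seed_pop.append(idx)

    sub_labels = CohortLabels(aligned)
    run_seeds = np.random.SeedSequence(config.seed).spawn(config.n_models)
    results = SearchResult()
    counts: Counter = Counter()

    for run_index, seed in enumerate(run_seeds):
        rng = np.random.default_rng(seed)
        train_ids, test_ids = stratified_split(sub_labels, config.train_fraction, rng)
        ctx = _RunContext(
            table, labels, train_ids, eligible, config.weight_scheme, rng,
            cv_repeats=config.cv_repeats,
            cv_fit_fraction=config.cv_fit_fraction,
        )

        sampler = _TaxonSampler(
            n_taxa,
            ctx.separation_rank[: config.candidate_pool_size],
            config.candidate_bias,
        )
        if seed_pop is not None:
            population = list(seed_pop)
        else:
            population = [
                _random_panel(rng, sampler, config.combo_size_range)
                for _ in range(config.population_size)
            ]

        cache: dict = {}

        def fitness_of(panel):
            hit = cache.get(panel)
            if hit is None:
                hit = _evaluate_panel(
                    ctx, panel, config.tune_threshold, config.fitness_mode
                )
                cache[panel] = hit
            return hit

        best_panel, best_fit = None, None
        for _generation in range(config.generations):
            fitnesses = [fitness_of(p)[0] for p in population]
            for p, f in zip(population, fitnesses):
                # strict improvement only: the first panel reaching the best
                # fitness is kept, so saturated fitness does not drift
                if best_fit is None or f > best_fit:
                    best_panel, best_fit = p, f
            ranked = sorted(
                range(len(population)), key=lambda i: fitnesses[i], reverse=True
            )
            next_pop = [population[i] for i in ranked[: config.elitism]]
            while len(next_pop) < config.population_size:
                parent_a = _tournament(rng, population, fitnesses)
                if rng.random() < config.crossover_rate:
                    parent_b = _tournament(rng, population, fitnesses)
                    child = _crossover(
                        rng, parent_a, parent_b, sampler, config.combo_size_range
                    )
                else:
                    child = parent_a
                if rng.random() < config.mutation_rate:
                    child = _mutate(rng, child, sampler, config.combo_size_range)
                next_pop.append(child)
            population = next_pop
        for p in population:  # final generation's offspring
            f = fitness_of(p)[0]
            if f > best_fit:
                best_panel, best_fit = p, f

        best_taxa = tuple(eligible[i] for i in best_panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_combo_model(
                table,
                labels,
                best_taxa,
                train_samples=train_ids,
                weight_scheme=config.weight_scheme,
                tune=config.tune_threshold,
                panel_size_range=config.combo_size_range,
            )
        model.metadata["run_index"] = run_index
        model.metadata["test_samples"] = list(test_ids)

        scores = score_samples(model, table)
        predictions = predict_combo(model, table)
        reports = {}
        for name, subset in (
            ("train", train_ids),
            ("test", test_ids),
            ("full", list(table.sample_ids)),
        ):
            reports[name] = evaluate_scores(
                scores.loc[subset],
                predictions.loc[subset],
                labels,
                model_id=f"run{run_index:03d}",
            )
        results.models.append(
            EvoRunResult(
                model=model,
                train_report=reports["train"],
                test_report=reports["test"],
                full_report=reports["full"],
                run_index=run_index,
                train_samples=list(train_ids),
                test_samples=list(test_ids),
                fitness=best_fit,
            )
        )
        counts.update(best_taxa)

    results.biomarker_counts = dict(counts)
    return results
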