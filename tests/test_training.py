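"""Splits, AUPRC, training loop, ablations and determinism."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from cliqueflux import (
    CohortSpec,
    FluxConfig,
    TrainConfig,
    auprc,
    build_graph,
    generate_cohort,
    impute,
    make_splits,
    run_experiment,
    train,
)
from cliqueflux.cliques import assign_clique_weights, enumerate_maximal_cliques

from conftest import brute_force_average_precision


def quick_cfg(**kw) -> TrainConfig:
    base = dict(epochs=20, n_repeats=2, flux=FluxConfig(p_add=0.01, p_delete=0.05, seed=0), seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestSplits:
    @pytest.mark.parametrize("fractions", list({(0.70, 0.15, 0.15), (0.40, 0.30, 0.30),
                                                (0.30, 0.35, 0.35), (0.20, 0.40, 0.40)}))
    @pytest.mark.parametrize("n", [10, 100, 1234])
    def test_disjoint_exhaustive_correct_sizes(self, fractions, n):
        tr, va, te = make_splits(n, fractions, seed=1)
        assert len(set(tr) | set(va) | set(te)) == n
        assert len(tr) + len(va) + len(te) == n
        # largest-remainder rounding: each size within 1 of n*f
        for part, f in zip((tr, va, te), fractions):
            assert abs(len(part) - n * f) < 1

    def test_largest_remainder_example(self):
        tr, va, te = make_splits(10, (0.7, 0.15, 0.15), seed=0)
        assert (len(tr), len(va) + len(te)) == (7, 3)
        assert {len(va), len(te)} == {1, 2}

    def test_exact_fractions(self):
        sizes = tuple(len(s) for s in make_splits(100, (0.2, 0.4, 0.4), seed=5))
        assert sizes == (20, 40, 40)

    def test_deterministic(self):
        a = make_splits(50, (0.7, 0.15, 0.15), seed=9)
        b = make_splits(50, (0.7, 0.15, 0.15), seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_splits(3, (0.98, 0.01, 0.01), seed=0)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_reversed_ranking_matches_oracle(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([1, 1, 0, 0])
        assert auprc(s, y) == pytest.approx(brute_force_average_precision(s, y), abs=1e-12)

    def test_constant_scores_give_prevalence(self):
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        assert auprc(np.full(10, 0.3), y) == pytest.approx(0.2)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.9], size=n) + rng.normal(0, 0.01, n) * rng.integers(0, 2)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auprc(scores, labels) == pytest.approx(
                brute_force_average_precision(scores, labels), abs=1e-10
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            auprc(np.array([0.1, 0.9]), np.array([1, 1]))


@pytest.fixture(scope="module")
def noisy_setup():
    spec = CohortSpec(n_encounters=300, cluster_outcome_strength=0.8, seed=21)
    cohort = impute(generate_cohort(spec))
    g = build_graph(cohort)
    gw = assign_clique_weights(g, enumerate_maximal_cliques(g))
    return cohort, gw


class TestTrain:
    def test_single_class_labels_rejected(self, noisy_setup):
        cohort, gw = noisy_setup
        with pytest.raises(ValueError, match="single-class"):
            train(cohort.features, gw, np.zeros(cohort.n_encounters, dtype=int), quick_cfg())

    def test_learns_separable_cohort(self, separable_cohort):
        g = build_graph(separable_cohort)
        gw = assign_clique_weights(g, enumerate_maximal_cliques(g))
        out = train(separable_cohort.features, gw, separable_cohort.labels,
                    quick_cfg(epochs=60, n_repeats=1))
        assert out.test_auprc is not None and out.test_auprc >= 0.9
        assert min(h["train_loss"] for h in out.loss_history) < 0.1

    def test_nan_guard_message(self, noisy_setup):
        cohort, gw = noisy_setup
        x = cohort.features.copy()
        x[0, :] = np.inf  # inf - inf in the aggregation turns the loss NaN
        with pytest.raises(FloatingPointError, match="epoch"):
            with np.errstate(all="ignore"):
                train(x, gw, cohort.labels, quick_cfg())


class TestRunExperiment:
    def test_repeat_count_and_stat_consistency(self, noisy_setup):
        cohort, gw = noisy_setup
        res = run_experiment(cohort, quick_cfg(n_repeats=3), graph=gw)
        assert len(res.per_repeat_auprc) == 3
        arr = np.array(res.per_repeat_auprc)
        assert res.mean_auprc == pytest.approx(arr.mean(), abs=1e-12)
        assert res.std_auprc == pytest.approx(arr.std(), abs=1e-12)

    def test_single_repeat_zero_std(self, noisy_setup):
        cohort, gw = noisy_setup
        res = run_experiment(cohort, quick_cfg(n_repeats=1), graph=gw)
        assert res.std_auprc == 0.0

    def test_deterministic_under_master_seed(self, noisy_setup):
        cohort, gw = noisy_setup
        a = run_experiment(cohort, quick_cfg(), graph=gw)
        b = run_experiment(cohort, quick_cfg(), graph=gw)
        assert a.per_repeat_auprc == b.per_repeat_auprc

    def test_flux_ablation_identity_when_probs_zero(self, noisy_setup):
        """With p_add = p_delete = 0 the edge-flux arm is a no-op, so 'full'
        and 'no_edge_flux' must be bit-identical under one seed."""
        cohort, gw = noisy_setup
        zero = FluxConfig(p_add=0.0, p_delete=0.0, seed=0)
        full = run_experiment(cohort, quick_cfg(flux=zero, ablation="full"), graph=gw)
        wo = run_experiment(cohort, quick_cfg(flux=zero, ablation="no_edge_flux"), graph=gw)
        assert full.per_repeat_auprc == wo.per_repeat_auprc

    def test_no_clique_ablation_unit_weights(self, noisy_setup):
        """The no-clique arm must equal a run on the binarised graph."""
        cohort, gw = noisy_setup
        binary = gw.adjacency.copy()
        binary.data[:] = 1
        g1 = gw.with_adjacency(binary)
        a = run_experiment(cohort, quick_cfg(ablation="no_clique"), graph=gw)
        b = run_experiment(cohort, quick_cfg(ablation="full"), graph=g1)
        assert a.per_repeat_auprc == b.per_repeat_auprc

    def test_three_ablation_arms_emit_results(self, noisy_setup):
        cohort, gw = noisy_setup
        for arm in ("full", "no_edge_flux", "no_clique"):
            res = run_experiment(cohort, quick_cfg(n_repeats=1, ablation=arm), graph=gw)
            assert 0.0 <= res.mean_auprc <= 1.0
            assert res.ablation == arm

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="split_fractions"):
            TrainConfig(split_fractions=(0.5, 0.3, 0.3)).validate()
        with pytest.raises(ValueError, match="ablation"):
            TrainConfig(ablation="none").validate()
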