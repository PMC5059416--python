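"""Semi-supervised SVM rescoring: subset sampling, initialization, training."""

import numpy as np
import pytest

from percolite.pin import PsmTable
from percolite.rescore import (
    TrainConfig,
    choose_initial_direction,
    rescore,
    score_all,
    subset_sample,
    train_cross_validation,
)
from percolite.simulate import SimConfig, simulate_proteome, simulate_psms
from percolite.stats import target_decoy_qvalues


def paired_table(n_spectra=10, n_features=3, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_spectra
    return PsmTable(
        spec_ids=np.repeat([f"s{i}" for i in range(n_spectra)], 2).astype(object),
        scans=np.repeat(np.arange(1, n_spectra + 1), 2),
        is_target=np.tile([True, False], n_spectra),
        features=rng.normal(size=(n, n_features)),
        feature_names=tuple(f"f{j}" for j in range(n_features)),
        peptides=np.array([f"-.PEP{i}K.-" for i in range(n)], dtype=object),
        proteins=[("P1",)] * n,
    )


class TestSubsetSample:
    def test_whole_spectra_sampled(self):
        table = paired_table(n_spectra=10)
        sub = subset_sample(table, 6, seed=1)
        assert len(sub) == 6
        sids, counts = np.unique(sub.spec_ids.astype(str), return_counts=True)
        assert len(sids) == 3 and (counts == 2).all()

    def test_identity_when_size_equals_total(self):
        table = paired_table(5)
        sub = subset_sample(table, len(table), seed=0)
        assert len(sub) == len(table)

    def test_oversized_request_warns_and_returns_all(self):
        table = paired_table(5)
        with pytest.warns(UserWarning):
            sub = subset_sample(table, len(table) + 1, seed=0)
        assert len(sub) == len(table)

    def test_deterministic_per_seed(self):
        table = paired_table(50)
        a = subset_sample(table, 30, seed=4)
        b = subset_sample(table, 30, seed=4)
        assert (a.spec_ids == b.spec_ids).all()
        c = subset_sample(table, 30, seed=5)
        assert set(a.spec_ids) != set(c.spec_ids)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_splits_a_spectrum(self, seed):
        rng = np.random.default_rng(seed)
        table = paired_table(n_spectra=40, seed=seed)
        size = int(rng.integers(1, len(table)))
        sub = subset_sample(table, size, seed=seed)
        full_counts = {s: 2 for s in np.unique(table.spec_ids.astype(str))}
        _, counts = np.unique(sub.spec_ids.astype(str), return_counts=True)
        assert all(c == 2 for c in counts)
        assert len(sub) >= size


class TestInitialDirection:
    def make_features(self, seed=0, flip=False):
        rng = np.random.default_rng(seed)
        n = 1200
        is_target = np.tile([True, False], n // 2)
        correct = is_target & (rng.random(n) < 0.6)
        X = rng.normal(size=(n, 5))
        X[correct, 2] += 4.0  # informative feature at index 2
        if flip:
            X[:, 2] = -X[:, 2]
        return X, is_target

    def test_informative_feature_chosen(self):
        X, y = self.make_features()
        assert choose_initial_direction(X, y) == (2, 1)

    def test_negated_feature_flips_sign(self):
        X, y = self.make_features(flip=True)
        assert choose_initial_direction(X, y) == (2, -1)

    def test_pure_noise_tie_break(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        y = np.tile([True, False], 50)
        assert choose_initial_direction(X, y, q_train=0.0001) == (0, 1)


class TestTraining:
    def separable_table(self, n_spectra=300, seed=0):
        rng = np.random.default_rng(seed)
        table = paired_table(n_spectra=n_spectra, n_features=3, seed=seed)
        X = rng.normal(size=(len(table), 3))
        X[table.is_target, 0] += 8.0  # linearly separable by feature 0
        return PsmTable(
            spec_ids=table.spec_ids,
            scans=table.scans,
            is_target=table.is_target,
            features=X,
            feature_names=table.feature_names,
            peptides=table.peptides,
            proteins=table.proteins,
        )

    def test_separable_data_zero_violations(self):
        table = self.separable_table()
        model = train_cross_validation(table, TrainConfig(seed=0))
        scores = score_all(table, model.vectors, "cross_validation", model.fold_assignment)
        assert scores[table.is_target].min() > scores[~table.is_target].max()

    def test_zero_iterations_returns_initial_direction(self):
        table = self.separable_table()
        model = train_cross_validation(table, TrainConfig(iterations=0, seed=0))
        for v in model.vectors:
            # unit vector on the informative feature, up to feature scaling
            nz = np.nonzero(v.weights)[0]
            assert nz.tolist() == [0]
            assert v.weights[0] > 0

    def test_dimensionality_mismatch_error(self):
        table = self.separable_table()
        model = train_cross_validation(table, TrainConfig(seed=0))
        bad = paired_table(n_spectra=10, n_features=5)
        with pytest.raises(ValueError):
            score_all(bad, model.vectors, "cross_validation", np.zeros(20, int))

    def test_positives_grow_during_training(self):
        """The confident-target count is non-decreasing over iterations in
        at least 90% of seeded synthetic runs."""
        monotone = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = SimConfig(n_proteins=60, n_spectra=800, seed=seed)
            table, _ = simulate_psms(simulate_proteome(cfg), cfg)
            model = train_cross_validation(table, TrainConfig(iterations=5, seed=seed))
            totals = [
                sum(fold[i] for fold in model.positive_history)
                for i in range(len(model.positive_history[0]))
            ]
            monotone += int(all(b >= a for a, b in zip(totals, totals[1:])))
        assert monotone / n_runs >= 0.9

    def test_pipeline_deterministic(self):
        cfg = SimConfig(n_proteins=50, n_spectra=500, seed=11)
        table, _ = simulate_psms(simulate_proteome(cfg), cfg)
        s1, _ = rescore(table, TrainConfig(seed=3))
        s2, _ = rescore(table, TrainConfig(seed=3))
        assert np.array_equal(s1, s2)

    def test_identical_vectors_subset_average_preserves_ranking(self):
        table = self.separable_table()
        model = train_cross_validation(table, TrainConfig(seed=0))
        v = model.vectors[0]
        avg = score_all(table, [v, v, v], "subset_average")
        single = v.normalized_scores(table.features)
        assert np.argsort(avg).tolist() == np.argsort(single).tolist()

    def test_rescoring_never_loses_identifications(self):
        """Averaged over 10 seeds, SVM rescoring keeps at least 98% of the
        identifications the initial single-feature direction achieves at
        q <= 0.01 (and typically gains)."""
        ratios = []
        for seed in range(10):
            cfg = SimConfig(n_proteins=80, n_spectra=2000, seed=seed)
            table, _ = simulate_psms(simulate_proteome(cfg), cfg)
            j, sign = choose_initial_direction(table.features, table.is_target)
            q0 = target_decoy_qvalues(sign * table.features[:, j], table.is_target)
            n0 = int(((q0 <= 0.01) & table.is_target).sum())
            scores, _ = rescore(table, TrainConfig(seed=seed))
            q1 = target_decoy_qvalues(scores, table.is_target)
            n1 = int(((q1 <= 0.01) & table.is_target).sum())
            ratios.append(n1 / n0)
        assert np.mean(ratios) >= 0.98

    def test_subset_variability_grows_as_subset_shrinks(self):
        """Across sampling seeds, the spread of identification counts is
        larger for smaller training subsets."""
        cfg = SimConfig(
            n_proteins=100, n_spectra=4000, effect_size=(1.5, 0.5, 0.25, 0.0, 0.0), seed=21
        )
        table, _ = simulate_psms(simulate_proteome(cfg), cfg)
        stds = []
        for size in (400, 4000):
            counts = []
            for seed in range(8):
                scores, _ = rescore(
                    table, TrainConfig(subset_size=size, iterations=5, seed=seed)
                )
                q = target_decoy_qvalues(scores, table.is_target)
                counts.append(int(((q <= 0.01) & table.is_target).sum()))
            stds.append(np.std(counts))
        assert stds[0] >= stds[1]


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(n_folds=1)
    with pytest.raises(ValueError):
        TrainConfig(q_train=0.0)
    with pytest.raises(ValueError):
        TrainConfig(c_pos=0.0)
    with pytest.raises(ValueError):
        TrainConfig(subset_size=0)
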