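"""Target-decoy q-values, PEPs, empirical p-values and Fisher's method."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from percolite.stats import (
    ScoredEntity,
    confidence_table,
    empirical_pvalue,
    empirical_pvalues,
    estimate_peps,
    fisher_combine,
    pep_estimates,
    qvalues_from_target_decoy,
    target_decoy_qvalues,
)


def oracle_qvalues(scores, is_target):
    """Evaluate the FDR at every target threshold, take the running minimum."""
    scores = np.asarray(scores, float)
    is_target = np.asarray(is_target, bool)
    t = scores[is_target]
    d = scores[~is_target]
    thresholds = np.unique(t)
    fdr = np.array([(1 + (d >= v).sum()) / (t >= v).sum() for v in thresholds])
    out = []
    for s in scores:
        eligible = fdr[thresholds <= s]
        if eligible.size == 0:  # below every target: loosest threshold
            eligible = fdr[:1]
        out.append(min(1.0, eligible.min()))
    return np.array(out)


class TestQValues:
    def test_interleaved_decoys(self):
        scores = np.array([10, 9, 8, 7, 8.5, 6.0])
        is_t = np.array([1, 1, 1, 1, 0, 0], bool)
        assert target_decoy_qvalues(scores, is_t)[:4] == pytest.approx([0.5] * 4)

    def test_no_decoys_pseudocount(self):
        q = target_decoy_qvalues(np.array([3.0, 2, 1]), np.ones(3, bool))
        assert q == pytest.approx([1 / 3] * 3)

    def test_capped_at_one(self):
        scores = np.concatenate([np.arange(10, 20), np.arange(10)])  # decoys on top
        is_t = np.concatenate([np.zeros(10, bool), np.ones(10, bool)])
        assert np.all(target_decoy_qvalues(scores, is_t) == 1.0)

    def test_zero_targets_error(self):
        with pytest.raises(ValueError):
            target_decoy_qvalues(np.array([1.0]), np.array([False]))

    def test_tied_scores_share_q(self):
        scores = np.array([5.0, 5.0, 5.0, 4.0, 3.0])
        is_t = np.array([1, 1, 0, 1, 0], bool)
        q = target_decoy_qvalues(scores, is_t)
        assert q[0] == q[1]

    @given(
        n_t=st.integers(min_value=1, max_value=60),
        n_d=st.integers(min_value=0, max_value=60),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_bruteforce_oracle(self, n_t, n_d, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n_t + n_d), 1)  # rounding forces ties
        is_t = np.zeros(n_t + n_d, bool)
        is_t[:n_t] = True
        assert target_decoy_qvalues(scores, is_t) == pytest.approx(
            oracle_qvalues(scores, is_t)
        )

    def test_confidence_table_sorted_and_monotone(self):
        rng = np.random.default_rng(0)
        ents = [
            ScoredEntity(str(i), float(s), "target" if i % 3 else "decoy")
            for i, s in enumerate(rng.normal(size=200))
        ]
        df = qvalues_from_target_decoy(ents)
        assert (df["score"].diff().dropna() <= 0).all()
        assert (df["q_value"].diff().dropna() >= -1e-12).all()

    def test_null_qvalues_track_true_false_positive_fraction(self):
        """When incorrect targets and decoys share a distribution, the q-value
        approximates the realized false-positive fraction of the accepted set."""
        rng = np.random.default_rng(3)
        n = 4000
        correct = rng.random(n) < 0.4
        t_scores = np.where(correct, rng.normal(3.0, 1.0, n), rng.normal(0, 1.0, n))
        d_scores = rng.normal(0, 1.0, n)
        scores = np.concatenate([t_scores, d_scores])
        is_t = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        q = target_decoy_qvalues(scores, is_t)
        for thr in (0.02, 0.05, 0.1):
            accepted = is_t & (q <= thr)
            fp = (~correct[accepted[:n]]).sum()
            n_acc = accepted.sum()
            se = math.sqrt(thr * (1 - thr) / n_acc)
            assert fp / n_acc == pytest.approx(thr, abs=4 * se + 2 / n_acc)


class TestPeps:
    def test_label_pure_bins(self):
        ents = (
            [ScoredEntity(f"t{i}", 10 - (i % 3), "target") for i in range(60)]
            + [ScoredEntity(f"d{i}", 2 - (i % 3), "decoy") for i in range(60)]
        )
        df = estimate_peps(ents, n_bins=2)
        assert df.loc[df["label"] == "target", "pep"].max() == 0.0
        assert df.loc[df["label"] == "decoy", "pep"].min() == 1.0

    def test_identical_distributions_pep_near_one(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(size=2000)
        ents = [ScoredEntity(f"t{i}", float(s), "target") for i, s in enumerate(shared)]
        ents += [ScoredEntity(f"d{i}", float(s), "decoy") for i, s in enumerate(shared)]
        df = estimate_peps(ents, n_bins=20)
        assert df["pep"].mean() > 0.9

    def test_monotone_non_increasing_with_score(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(2, 1, 500), rng.normal(0, 1, 500)])
        is_t = np.concatenate([np.ones(500, bool), np.zeros(500, bool)])
        pep = pep_estimates(scores, is_t, n_bins=25)
        order = np.argsort(scores)
        assert (np.diff(pep[order]) <= 1e-12).all()

    def test_small_sample_single_bin_fallback(self):
        scores = np.arange(10.0)
        is_t = np.array([1, 1, 1, 1, 1, 0, 0, 0, 1, 1], bool)
        pep = pep_estimates(scores, is_t)
        assert np.all(pep == pytest.approx(3 / 7))

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            pep_estimates(np.arange(50.0), np.ones(50, bool), n_bins=0)

    def test_pep_fdr_consistency(self):
        """Mean PEP among confident targets stays below the cutoff."""
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(2.5, 1, 2000), rng.normal(0, 1, 2000)])
        is_t = np.concatenate([np.ones(2000, bool), np.zeros(2000, bool)])
        pep = pep_estimates(scores, is_t)
        for c in (0.1, 0.5):
            mask = is_t & (pep <= c)
            if mask.any():
                assert pep[mask].mean() <= c + 1e-9


class TestEmpiricalPValues:
    def test_basic_counts(self):
        assert empirical_pvalue(5.0, [1, 2, 3]) == 0.25
        assert empirical_pvalue(0.0, [1, 2, 3]) == 1.0

    def test_large_decoy_set(self):
        decoys = np.arange(999.0)
        assert empirical_pvalue(1000.0, decoys) == pytest.approx(1 / 1000)

    def test_empty_decoys_error(self):
        with pytest.raises(ValueError):
            empirical_pvalues(np.array([1.0]), np.array([]))

    def test_vectorized_in_unit_interval(self):
        rng = np.random.default_rng(0)
        p = empirical_pvalues(rng.normal(size=100), rng.normal(size=50))
        assert np.all((p > 0) & (p <= 1))


class TestFisher:
    def test_two_half_pvalues(self):
        # closed form for 4 df: (1 + X/2) exp(-X/2), X = -2 ln(0.25)
        x = -2 * math.log(0.25)
        assert fisher_combine([0.5, 0.5]) == pytest.approx((1 + x / 2) * math.exp(-x / 2), abs=1e-12)
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)

    @pytest.mark.parametrize("p", [0.01, 0.3, 0.77, 1.0])
    def test_single_p_identity(self, p):
        assert fisher_combine([p]) == pytest.approx(p, abs=1e-12)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 0.0])
        with pytest.raises(ValueError):
            fisher_combine([])

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_matches_numerical_integration(self, k):
        """Survival probability agrees with direct integration of the
        chi-square density with 2k degrees of freedom to 1e-9."""
        ps = [0.3, 0.8, 0.11, 0.6, 0.42][:k]
        x = -2 * sum(math.log(p) for p in ps)

        def chi2_pdf(t, df=2 * k):
            return t ** (df / 2 - 1) * math.exp(-t / 2) / (2 ** (df / 2) * math.gamma(df / 2))

        # truncate the tail: the integrand beyond x + 400 is < exp(-200)
        expected, err = integrate.quad(chi2_pdf, x, x + 400, epsabs=1e-12, limit=200)
        assert err < 1e-10
        assert fisher_combine(ps) == pytest.approx(expected, abs=1e-9)


def test_confidence_table_full(tmp_path):
    rng = np.random.default_rng(9)
    ents = [
        ScoredEntity(str(i), float(s), "target" if i % 2 else "decoy")
        for i, s in enumerate(rng.normal(size=100))
    ]
    df = confidence_table(ents, with_pvalues=True)
    assert set(df.columns) == {"id", "label", "score", "q_value", "pep", "p_value"}
    assert df.notna().all().all()
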