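import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import sexmeta as sm
from sexmeta.meta import (
    adjust_fdr_pooled,
    combine_pvalues,
    compute_weights,
    consensus_direction,
    consistency_score,
    cross_study_lfc,
    meta_analyze,
    reliability_score,
    subsample_robustness,
)
from .conftest import make_dataset


def bh_stepup(p):
    """Reference Benjamini-Hochberg step-up, written independently."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def combine_oracle(p, lfc, w, direction, sidedness="two_sided"):
    """Brute-force weighted inverse-normal combination via norm.ppf/sf."""
    sel = [(pi, wi) for pi, li, wi in zip(p, lfc, w) if np.sign(li) == direction]
    ps = [pi / 2 if sidedness == "one_sided" else pi for pi, _ in sel]
    zs = [norm.ppf(1 - pi) for pi in ps]
    ws = [wi for _, wi in sel]
    s = sum(wi * zi for wi, zi in zip(ws, zs)) / np.sqrt(sum(wi * wi for wi in ws))
    return float(norm.sf(s))


class TestWeights:
    def test_single_dataset_weight_is_one(self):
        ds = make_dataset(n_f_case=5, n_f_control=7)
        (w,) = compute_weights([ds], "F")
        assert w.weight == pytest.approx(1.0)
        assert w.effective_n == 5

    def test_hand_arithmetic_4_and_16(self):
        d1 = make_dataset("d1", n_f_case=4, n_f_control=6)
        d2 = make_dataset("d2", n_f_case=16, n_f_control=20)
        w = compute_weights([d1, d2], "F")
        assert w[0].weight == pytest.approx(np.sqrt(4 / 20), abs=5e-5)
        assert w[1].weight == pytest.approx(np.sqrt(16 / 20), abs=5e-5)
        assert w[0].weight == pytest.approx(0.4472, abs=1e-4)
        assert w[1].weight == pytest.approx(0.8944, abs=1e-4)

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            datasets = [
                make_dataset(f"d{i}", n_f_case=int(rng.integers(2, 30)),
                             n_f_control=int(rng.integers(2, 30)))
                for i in range(int(rng.integers(1, 8)))
            ]
            w = compute_weights(datasets, "F")
            assert sum(x.weight**2 for x in w) == pytest.approx(1.0)

    def test_zero_n_dataset_gets_zero_weight_and_all_zero_errors(self):
        d1 = make_dataset("d1", n_f_case=4, n_f_control=4)
        d2 = make_dataset("d2", n_f_case=0, n_f_control=4)
        w = compute_weights([d1, d2], "F")
        assert w[1].weight == 0.0
        with pytest.raises(ValueError):
            compute_weights([make_dataset(n_f_case=0)], "F")


class TestConsensusDirection:
    def test_weighted_vote(self):
        d, tie = consensus_direction([1.0, 0.5, -2.0], [0.3, 0.3, 0.5])
        assert d == 1 and not tie  # 0.6 > 0.5

    def test_unanimous_and_single(self):
        assert consensus_direction([0.2, 0.4], [0.5, 0.5])[0] == 1
        assert consensus_direction([-0.7], [1.0])[0] == -1

    def test_zero_lfcs_vote_for_neither_side(self):
        d, tie = consensus_direction([0.0, 0.0, -0.1], [0.9, 0.9, 0.1])
        assert d == -1 and not tie

    def test_exact_tie_flagged(self):
        d, tie = consensus_direction([1.0, -3.0], [0.5, 0.5])
        assert tie and d == 1


class TestCombinePvalues:
    def test_single_study_identities(self):
        # one-sided convention: p/2; calibrated default: p itself
        assert combine_pvalues([0.1], [1.0], [1.0], 1, "one_sided") == pytest.approx(0.05)
        assert combine_pvalues([0.1], [1.0], [1.0], 1, "two_sided") == pytest.approx(0.1)

    def test_two_equal_weight_studies_closed_form(self):
        # one-sided p = 0.05 each: S = sqrt(2) * z_{0.95}, p ~= 0.0100
        p = combine_pvalues([0.1, 0.1], [1.0, 1.0], [0.5, 0.5], 1, "one_sided")
        expected = norm.sf(np.sqrt(2) * norm.ppf(0.95))
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.0100, abs=5e-4)

    def test_monotone_in_member_pvalues(self):
        base = combine_pvalues([0.2, 0.3], [1, 1], [0.6, 0.8], 1)
        lower = combine_pvalues([0.1, 0.3], [1, 1], [0.6, 0.8], 1)
        assert lower <= base

    def test_inconsistent_datasets_excluded(self):
        only = combine_pvalues([0.01, 0.5], [1.0, -1.0], [0.7, 0.7], 1)
        alone = combine_pvalues([0.01], [1.0], [0.7], 1)
        assert only == pytest.approx(alone)
        with pytest.raises(ValueError, match="consistent"):
            combine_pvalues([0.01], [-1.0], [1.0], 1)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            d = int(rng.integers(1, 7))
            p = rng.uniform(1e-6, 1, d)
            lfc = rng.normal(0, 1, d)
            w = np.sqrt(rng.dirichlet(np.ones(d)))
            direction, _ = consensus_direction(lfc, w)
            for mode in ("two_sided", "one_sided"):
                assert combine_pvalues(p, lfc, w, direction, mode) == pytest.approx(
                    combine_oracle(p, lfc, w, direction, mode), abs=1e-12
                )


class TestLfcConsistencyReliability:
    def test_cross_study_lfc_weighted_mean(self):
        assert cross_study_lfc([1.0, 0.5], [0.6, 0.8], 1) == pytest.approx(
            (0.6 * 1.0 + 0.8 * 0.5) / 1.4
        )
        assert cross_study_lfc([0.42], [1.0], 1) == pytest.approx(0.42)
        assert cross_study_lfc([1.0, -0.2], [0.5, 0.5], 1) == pytest.approx(1.0)

    def test_consistency_examples(self):
        assert consistency_score([0.3, 0.1], [0.5, 0.5], 1) == 1.0
        cst = consistency_score([0.4, -0.5], [0.6, 0.8], -1)
        assert cst == pytest.approx(0.8 / 1.4)
        assert cst < 0.6  # excluded downstream
        # a profile at 0.86 passes the 60% retention threshold
        assert 0.86 >= 0.6

    def test_reliability_examples(self):
        assert reliability_score([True, True], [0.5, 0.5]) == 1.0
        assert reliability_score([False, False], [0.5, 0.5]) == 0.0
        r = reliability_score([False, True, True], [0.5, 0.5, 0.707])
        assert r == pytest.approx((0.5 + 0.707) / 1.707)
        assert r >= 2 / 3  # retained ("below" is strict)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        lfc = rng.normal(0, 1, 6)
        w = rng.uniform(0.1, 1, 6)
        present = rng.random(6) > 0.3
        perm = rng.permutation(6)
        d0, _ = consensus_direction(lfc, w)
        d1, _ = consensus_direction(lfc[perm], w[perm])
        assert d0 == d1
        assert consistency_score(lfc, w, d0) == pytest.approx(
            consistency_score(lfc[perm], w[perm], d0)
        )
        assert reliability_score(present, w) == pytest.approx(
            reliability_score(present[perm], w[perm])
        )


class TestPooledFdr:
    def test_stepup_by_hand(self):
        f = pd.Series([0.01, 0.02], index=["a", "b"])
        m = pd.Series([0.03, 0.04], index=["a", "b"])
        fdr_f, fdr_m = adjust_fdr_pooled(f, m)
        assert np.allclose(fdr_f, [0.04, 0.04]) and np.allclose(fdr_m, [0.04, 0.04])

    def test_all_ones_and_elementwise_bound(self):
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        m = pd.Series([1.0], index=["a"])
        fdr_f, fdr_m = adjust_fdr_pooled(f, m)
        assert (fdr_f == 1).all() and (fdr_m == 1).all()
        rng = np.random.default_rng(2)
        f = pd.Series(rng.uniform(size=50))
        m = pd.Series(rng.uniform(size=30))
        fdr_f, fdr_m = adjust_fdr_pooled(f, m)
        assert (fdr_f >= f).all() and (fdr_m >= m).all()

    def test_matches_reference_stepup(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            f = pd.Series(rng.uniform(size=int(rng.integers(1, 100))))
            m = pd.Series(rng.uniform(size=int(rng.integers(1, 100))))
            fdr_f, fdr_m = adjust_fdr_pooled(f, m)
            ref = bh_stepup(np.concatenate([f, m]))
            # agreement to floating-point rounding of the step-up arithmetic
            np.testing.assert_allclose(
                np.concatenate([fdr_f, fdr_m]), ref, rtol=1e-13, atol=0
            )

    def test_nan_entries_stay_nan(self):
        f = pd.Series([0.01, np.nan], index=["a", "b"])
        m = pd.Series([0.02], index=["a"])
        fdr_f, _ = adjust_fdr_pooled(f, m)
        assert np.isnan(fdr_f["b"]) and not np.isnan(fdr_f["a"])


class TestMetaAnalyze:
    def test_dataset_order_invariance(self, null_run):
        de = null_run["de"]["F"][:3]
        w = compute_weights(de, "F")
        a = meta_analyze(de, w)
        b = meta_analyze(de[::-1], w[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_direction_matches_lfc_sign(self, null_run):
        t = null_run["tables"]["F"]
        assert (np.sign(t["lfc"]) == t["direction"]).all()

    def test_reliability_one_when_fully_measured(self, null_run):
        assert (null_run["tables"]["M"]["reliability"] == 1.0).all()


class TestSubsampling:
    def test_equal_counts_reproduce_full_analysis(self):
        cfg = sm.SimulationConfig(
            n_datasets=2, n_genes=150, seed=8,
            counts={(s, c): 10 for s in ("F", "M") for c in ("PD", "control")},
            effect_classes={"male_specific": sm.EffectClass(0.2, 0.0, 1.0)},
        )
        datasets, _ = sm.generate_cohorts(cfg)
        runs, summary = subsample_robustness(datasets, n_subsets=2, seed=5)
        assert np.allclose(summary["sign_agreement_all"], 1.0)
        assert np.allclose(summary["rank_correlation"], 1.0)

    def test_seed_determinism_and_male_effect_concordance(self):
        cfg = sm.SimulationConfig(
            n_datasets=3, n_genes=200, seed=8,
            counts={("F", "PD"): 6, ("F", "control"): 6,
                    ("M", "PD"): 14, ("M", "control"): 14},
            effect_classes={"male_specific": sm.EffectClass(0.25, 0.0, 1.5)},
        )
        datasets, _ = sm.generate_cohorts(cfg)
        _, s1 = subsample_robustness(datasets, n_subsets=3, seed=5)
        _, s2 = subsample_robustness(datasets, n_subsets=3, seed=5)
        pd.testing.assert_frame_equal(s1, s2)
        # strong planted male effects keep their sign in female-sized subsets
        assert s1["sign_agreement_significant"].mean() > 0.9

    def test_female_excess_uses_full_males_with_warning(self):
        cfg = sm.SimulationConfig(
            n_datasets=1, n_genes=50, seed=2,
            counts={("F", "PD"): 8, ("F", "control"): 8,
                    ("M", "PD"): 4, ("M", "control"): 4},
        )
        datasets, _ = sm.generate_cohorts(cfg)
        with pytest.warns(RuntimeWarning, match="exceeds male count"):
            _, summary = subsample_robustness(datasets, n_subsets=1, seed=0)
        assert np.allclose(summary["sign_agreement_all"], 1.0)
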