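import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pairomics.diffstats import (
    bh_adjust,
    differential_table,
    paired_t,
    sign_test,
    signed_fold,
    tukey_biweight,
    tukey_biweight_fc,
    wilcoxon_signed_rank,
)
from pairomics.synthetic import SimulationConfig, generate_study
from .conftest import build_dataset, paired_design


class TestPairedT:
    def test_closed_form_example(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3)), df = 2
        p = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        t = 2.0 / (1.0 / math.sqrt(3.0))
        expected = 2.0 * stats.t.sf(t, df=2)
        assert p == pytest.approx(expected)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_swap_symmetry(self):
        a, b = [5.0, 6.0, 9.0, 4.0], [3.0, 7.0, 2.0, 8.0]
        assert paired_t(a, b) == pytest.approx(paired_t(b, a))

    def test_zero_variance_gives_one(self):
        assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_missing_pairs_dropped(self):
        p_full = paired_t([1.0, 2.0, 4.0], [0.0, 0.0, 0.0])
        p_nan = paired_t([1.0, 2.0, 4.0, np.nan], [0.0, 0.0, 0.0, 5.0])
        assert p_full == pytest.approx(p_nan)

    def test_too_few_pairs_undefined(self):
        assert np.isnan(paired_t([1.0, 2.0], [0.0, 0.0]))


def _wilcoxon_exact_dp(diffs):
    """Exact two-sided signed-rank p by DP over the rank-sum distribution."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    total = n * (n + 1) // 2
    # distribution of W+ over 2^n sign assignments (integer ranks only)
    counts = np.zeros(int(total) + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: counts.size - r].copy()
    w = int(round(w_pos))
    lower = counts[: w + 1].sum() / 2.0**n
    upper = counts[w:].sum() / 2.0**n
    return min(1.0, 2.0 * min(lower, upper))


class TestWilcoxon:
    def test_n5_all_positive(self):
        p = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], [0.0] * 5)
        assert p == pytest.approx(2.0 / 32.0)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=8)
        z = np.zeros(8)
        assert wilcoxon_signed_rank(a, z) == pytest.approx(
            wilcoxon_signed_rank(z, a)
        )

    def test_exact_matches_dp_oracle_small_n(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(5, 15)
            d = rng.normal(size=n)
            p = wilcoxon_signed_rank(d, np.zeros(n))
            assert p == pytest.approx(_wilcoxon_exact_dp(d), abs=1e-12)

    def test_boundary_n26_approx_close_to_exact(self):
        # the corrected normal approximation tracks the exact DP oracle to
        # within ~0.007 at the exact/approx switch point
        for seed in range(10):
            d = np.random.default_rng(seed).normal(0.3, 1.0, size=26)
            assert len(np.unique(np.abs(d))) == 26  # no ties
            p_approx = wilcoxon_signed_rank(d, np.zeros(26))
            p_exact = _wilcoxon_exact_dp(d)
            assert abs(p_approx - p_exact) < 0.0075

    def test_too_few_pairs_undefined(self):
        assert np.isnan(wilcoxon_signed_rank([1.0, 2.0], [0.0, 0.0]))


class TestSignTest:
    def test_13_of_15_positive(self):
        p = sign_test([1.0] * 13 + [-1.0] * 2, [0.0] * 15)
        assert p == pytest.approx(242.0 / 32768.0)

    def test_balanced_gives_one(self):
        assert sign_test([1.0] * 8 + [-1.0] * 8, [0.0] * 16) == 1.0

    def test_k_and_n_minus_k_symmetric(self):
        for k in range(16):
            pk = sign_test([1.0] * k + [-1.0] * (15 - k), [0.0] * 15)
            pnk = sign_test([1.0] * (15 - k) + [-1.0] * k, [0.0] * 15)
            assert pk == pytest.approx(pnk)

    def test_zero_differences_dropped(self):
        p = sign_test([1.0, 1.0, 1.0, 5.0], [0.0, 0.0, 0.0, 5.0])
        assert p == pytest.approx(2.0 / 8.0)

    def test_all_zero_undefined(self):
        assert np.isnan(sign_test([1.0, 2.0], [1.0, 2.0]))


def _bh_oracle(pvals):
    """Per-element BH without the sort/cummin formulation: the adjusted
    value of p_i is the smallest m*t/#(p<=t) over candidate thresholds
    t >= p_i drawn from the observed p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    out = np.empty(m)
    for i in range(m):
        cands = [t for t in p if t >= p[i] - 1e-15]
        out[i] = min(1.0, min(m * t / np.sum(p <= t + 1e-15) for t in cands))
    return out


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.07]), [0.07])

    def test_matches_oracle_on_grids(self):
        # all vectors of length <= 6 over a coarse p-grid (sampled
        # exhaustively for short lengths, randomly for longer)
        grid = [0.01, 0.04, 0.2, 0.5, 1.0]
        rng = np.random.default_rng(0)
        for n in (1, 2, 3):
            for combo in itertools.product(grid, repeat=n):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), _bh_oracle(combo), atol=1e-12
                )
        for n in (4, 5, 6):
            for _ in range(200):
                combo = rng.choice(grid, size=n)
                np.testing.assert_allclose(
                    bh_adjust(combo), _bh_oracle(combo), atol=1e-12
                )

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.03])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], _bh_oracle([0.01, 0.03]))

    def test_never_below_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestTukeyBiweightFc:
    def test_constant_ratio(self):
        assert tukey_biweight_fc([2.0, 4.0, 6.0], [1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_outlier_downweighted(self):
        # signed folds (2, 2, 2, 2, 20): outlier weight ~ 0
        est = tukey_biweight(np.array([2.0, 2.0, 2.0, 2.0, 20.0]))
        assert 2.0 <= est < 2.4
        assert est < np.mean([2, 2, 2, 2, 20])

    def test_mixed_signs_bounded_by_range(self):
        est = tukey_biweight(np.array([1.2, -1.1, 1.3]))
        assert -1.1 < est < 1.3

    def test_sub_unit_magnitude_reachable(self):
        # |tFC| < 1 arises for balanced up/down pair folds
        est = tukey_biweight(np.array([1.1, -1.2, 1.05, -1.06, 1.0]))
        assert abs(est) < 1.1

    def test_signed_fold_convention(self):
        np.testing.assert_allclose(
            signed_fold(np.array([2.0, 1.0]), np.array([1.0, 2.0])), [2.0, -2.0]
        )

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            tukey_biweight_fc([1.0, 2.0, 0.0], [1.0, 1.0, 1.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            tukey_biweight_fc([2.0, 2.0], [1.0, 1.0])

    def test_monotone_in_group_scaling(self):
        rng = np.random.default_rng(5)
        ctrl = np.exp2(rng.normal(10, 0.5, size=12))
        case = ctrl * np.exp2(rng.normal(0, 0.1, size=12))
        estimates = [
            tukey_biweight_fc(case * g, ctrl) for g in [1.0, 1.3, 1.8, 2.5]
        ]
        assert all(b > a for a, b in zip(estimates, estimates[1:]))

    def test_null_fold_near_unit_band(self):
        # signed folds have no mass in (-1, 1); under a symmetric null the
        # median sits at the +/-1 band boundary
        rng = np.random.default_rng(6)
        ctrl = np.exp2(rng.normal(10, 0.5, size=2000))
        case = ctrl * np.exp2(rng.normal(0, 0.3, size=2000))
        folds = signed_fold(case, ctrl)
        assert abs(np.median(folds)) <= 1.1


class TestDifferentialTable:
    def test_min_p_and_significance(self, toy_dataset, toy_design):
        records = differential_table(toy_dataset, toy_design)
        for r in records:
            ps = [p for p in (r.p_paired_t, r.p_wilcoxon, r.p_sign) if not np.isnan(p)]
            assert r.min_p == pytest.approx(min(ps))
            assert r.significant == (r.min_p < 0.05)
            assert r.bh_paired_t >= r.p_paired_t - 1e-15

    def test_sorted_by_tfc_descending(self, toy_dataset, toy_design):
        records = differential_table(toy_dataset, toy_design)
        tfcs = [r.tfc for r in records]
        assert tfcs == sorted(tfcs, reverse=True)

    def test_internal_standards_excluded(self):
        rng = np.random.default_rng(7)
        ds = build_dataset(
            np.exp2(rng.normal(10, 1, size=(3, 8))),
            is_internal_standard=[False, True, False],
        )
        records = differential_table(ds, paired_design(ds))
        assert len(records) == 2
        assert "F1" not in {r.feature_id for r in records}

    def test_type_one_error_calibration_small(self):
        # scaled-down version of the acceptance simulation
        cfg = SimulationConfig(
            n_pairs=15, n_features={"metabolite": 100},
            n_differential={"metabolite": 0},
            n_internal_standards={"metabolite": 0},
            network_edges=0, drift_amplitude=0.0, missing_rate=0.0,
        )
        fracs = []
        for seed in range(10):
            cfg.seed = seed
            datasets, design, _ = generate_study(cfg)
            recs = differential_table(datasets["metabolite"], design)
            fracs.append(np.mean([r.p_paired_t < 0.05 for r in recs]))
        assert abs(np.mean(fracs) - 0.05) < 0.025

    def test_planted_features_rank_high(self):
        cfg = SimulationConfig(
            n_pairs=15, n_features={"metabolite": 80},
            n_differential={"metabolite": 8}, effect_log2fc=1.5,
            n_internal_standards={"metabolite": 0},
            network_edges=0, drift_amplitude=0.0, missing_rate=0.0, seed=9,
        )
        datasets, design, truth = generate_study(cfg)
        recs = differential_table(datasets["metabolite"], design)
        by_p = sorted(recs, key=lambda r: r.min_p)
        ranks = [
            i for i, r in enumerate(by_p) if r.feature_id in truth.differential_features
        ]
        assert np.median(ranks) < len(recs) / 10  # planted in top decile
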