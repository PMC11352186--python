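import numpy as np
import pytest

from pairomics.datamodel import ValidationError
from pairomics.preprocess import (
    PreprocessOptions,
    consolidate_lipid_lines,
    knn_impute,
    nomis_normalize,
    preprocess_pipeline,
    presence_filter,
    qc_cv,
    qc_rfsc_correct,
)
from pairomics.synthetic import SimulationConfig, generate_study
from .conftest import build_dataset, paired_design

NAN = np.nan


class TestConsolidateLipidLines:
    def _two_line_ds(self, row_a, row_b):
        return build_dataset(
            [row_a, row_b],
            layer="lipid",
            feature_ids=["L.1", "L.2"],
            consolidation_keys=["L", "L"],
        )

    def test_values_summed(self):
        ds = self._two_line_ds([100.0, 10.0], [50.0, 20.0])
        out = consolidate_lipid_lines(ds)
        assert out.n_features == 1
        np.testing.assert_array_equal(out.intensities[0], [150.0, 30.0])
        assert out.feature_ids == ["L"]

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (100.0, 50.0, 150.0),
            (NAN, 50.0, 50.0),
            (100.0, NAN, 100.0),
            (NAN, NAN, NAN),
        ],
    )
    def test_missing_combinations(self, a, b, expected):
        # enumeration of the four missing/present cases
        ds = self._two_line_ds([a, 1.0], [b, 1.0])
        out = consolidate_lipid_lines(ds)
        got = out.intensities[0, 0]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_single_line_keys_unchanged(self):
        ds = build_dataset([[1.0, 2.0], [3.0, 4.0]], layer="lipid",
                           consolidation_keys=["A", "B"])
        out = consolidate_lipid_lines(ds)
        np.testing.assert_array_equal(out.intensities, ds.intensities)

    def test_conflicting_metadata_rejected(self):
        ds = build_dataset(
            [[1.0, 1.0], [1.0, 1.0]],
            layer="lipid",
            consolidation_keys=["L", "L"],
            is_internal_standard=[True, False],
        )
        with pytest.raises(ValidationError, match="conflicting"):
            consolidate_lipid_lines(ds)

    def test_non_lipid_layer_passthrough(self):
        ds = build_dataset([[1.0, 2.0], [3.0, 4.0]], layer="metabolite",
                           consolidation_keys=["K", "K"])
        out = consolidate_lipid_lines(ds)
        assert out.n_features == 2


class TestPresenceFilter:
    def _groups_ds(self, n_del_obs, n_cnt_obs, n=18):
        # one feature observed in n_del_obs of n DEL and n_cnt_obs of n CNT
        row = (
            [1.0] * n_del_obs + [NAN] * (n - n_del_obs)
            + [1.0] * n_cnt_obs + [NAN] * (n - n_cnt_obs)
        )
        groups = ["DEL"] * n + ["CNT"] * n
        pair_ids = [f"P{i}" for i in range(n)] * 2
        return build_dataset([row], groups=groups, pair_ids=pair_ids)

    def test_half_in_one_group_kept(self):
        ds = self._groups_ds(9, 4)
        out, _ = presence_filter(ds, paired_design(ds))
        assert out.n_features == 1

    def test_below_half_in_both_dropped(self):
        ds = self._groups_ds(8, 8)
        out, report = presence_filter(ds, paired_design(ds))
        assert out.n_features == 0
        assert report.dropped[0][0] == "F0"

    def test_both_rule(self):
        ds = self._groups_ds(9, 4)
        out, _ = presence_filter(ds, paired_design(ds), rule="both")
        assert out.n_features == 0

    def test_fully_measured_kept_fully_missing_dropped(self):
        ds = build_dataset([[1.0] * 4, [NAN] * 4])
        out, _ = presence_filter(ds, paired_design(ds))
        assert out.feature_ids == ["F0"]

    def test_internal_standard_always_kept(self):
        ds = build_dataset([[NAN] * 4], is_internal_standard=[True])
        out, _ = presence_filter(ds, paired_design(ds))
        assert out.n_features == 1

    def test_qc_samples_not_counted(self):
        # feature present only in QC samples is dropped
        ds = build_dataset(
            [[NAN, NAN, 5.0, 5.0]],
            roles=["study", "study", "pooled_qc", "pooled_qc"],
            groups=["DEL", "CNT", "none", "none"],
            pair_ids=["P0", "P0", "", ""],
        )
        out, _ = presence_filter(ds, paired_design(ds))
        assert out.n_features == 0


def _qc_ds(qc_values, study_values=None, orders=None):
    n_qc = len(qc_values)
    study_values = study_values if study_values is not None else [100.0, 100.0]
    row = list(study_values) + list(qc_values)
    roles = ["study"] * len(study_values) + ["pooled_qc"] * n_qc
    groups = ["DEL", "CNT"] + ["none"] * n_qc
    pair_ids = ["P0", "P0"] + [""] * n_qc
    return build_dataset([row], roles=roles, groups=groups, pair_ids=pair_ids,
                         injection_order=orders)


class TestQcRfsc:
    def test_constant_qc_passthrough(self):
        ds = _qc_ds([50.0, 50.0, 50.0, 50.0], [80.0, 90.0])
        out = qc_rfsc_correct(ds, n_trees=50, seed=0)
        np.testing.assert_allclose(out.intensities, ds.intensities, rtol=1e-9)

    def test_too_few_qc_points_flagged_passthrough(self):
        ds = build_dataset(
            [[10.0, 20.0, 5.0, NAN, NAN], [10.0, 20.0, 5.0, 6.0, 7.0]],
            roles=["study", "study", "pooled_qc", "pooled_qc", "pooled_qc"],
            groups=["DEL", "CNT", "none", "none", "none"],
            pair_ids=["P0", "P0", "", "", ""],
        )
        out = qc_rfsc_correct(ds, n_trees=50, seed=0)
        # feature 0 has only 1 usable QC value -> untouched
        np.testing.assert_array_equal(out.intensities[0], ds.intensities[0])

    def test_fewer_than_3_qc_samples_error(self):
        ds = _qc_ds([50.0, 50.0])
        with pytest.raises(ValidationError):
            qc_rfsc_correct(ds, seed=0)

    def test_all_qc_missing_error(self):
        ds = _qc_ds([NAN, NAN, NAN])
        with pytest.raises(ValidationError, match="all QC values missing"):
            qc_rfsc_correct(ds, seed=0)

    def test_planted_drift_reduces_qc_cv(self):
        cfg = SimulationConfig(
            n_pairs=10, n_features={"metabolite": 30},
            n_differential={"metabolite": 0},
            n_internal_standards={"metabolite": 0},
            network_edges=0, drift_amplitude=0.3, missing_rate=0.0, seed=11,
        )
        datasets, _, _ = generate_study(cfg)
        ds = datasets["metabolite"]
        before = qc_cv(ds)
        after = qc_cv(qc_rfsc_correct(ds, n_trees=100, seed=1))
        assert np.median(list(after.values())) < np.median(list(before.values()))

    def test_deterministic_under_seed(self):
        ds = _qc_ds([40.0, 50.0, 60.0, 70.0], [80.0, 90.0])
        a = qc_rfsc_correct(ds, n_trees=50, seed=3)
        b = qc_rfsc_correct(ds, n_trees=50, seed=3)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestKnnImpute:
    def test_exact_copy_neighbor(self):
        # feature B identical to A where both observed, and observed at the
        # missing position -> imputed value equals B there
        a = [2.0, 4.0, 8.0, NAN]
        b = [2.0, 4.0, 8.0, 16.0]
        ds = build_dataset([a, b, [100.0, 90.0, 80.0, 70.0]])
        out, _ = knn_impute(ds, k=1)
        assert out.intensities[0, 3] == pytest.approx(16.0, rel=1e-9)

    def test_equidistant_neighbors_average(self):
        # two neighbors at equal distance holding log2 values 10 and 20
        target = [2.0**5, 2.0**5, NAN]
        nb1 = [2.0**6, 2.0**6, 2.0**10]
        nb2 = [2.0**4, 2.0**4, 2.0**20]
        ds = build_dataset([target, nb1, nb2], sample_ids=["S0", "S1", "S2"],
                           groups=["DEL", "CNT", "DEL"],
                           pair_ids=["P0", "P0", "P1"])
        out, _ = knn_impute(ds, k=2)
        assert np.log2(out.intensities[0, 2]) == pytest.approx(15.0, rel=1e-9)

    def test_no_missing_unchanged(self, toy_dataset):
        out, _ = knn_impute(toy_dataset, k=3)
        np.testing.assert_array_equal(out.intensities, toy_dataset.intensities)

    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(0)
        X = np.exp2(rng.normal(10, 1, size=(8, 6)))
        X[2, 3] = NAN
        X[5, 0] = NAN
        ds = build_dataset(X)
        out, _ = knn_impute(ds, k=3)
        obs = ~np.isnan(ds.intensities)
        np.testing.assert_array_equal(out.intensities[obs], ds.intensities[obs])
        assert not np.isnan(out.intensities).any()

    def test_all_missing_feature_dropped(self):
        ds = build_dataset([[NAN, NAN], [1.0, 2.0], [3.0, 4.0]])
        out, report = knn_impute(ds, k=1)
        assert out.n_features == 2
        assert report.dropped[0][0] == "F0"

    def test_k_below_one_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            knn_impute(toy_dataset, k=0)


class TestNomis:
    def _with_standard(self, feature_rows, is_rows):
        rows = feature_rows + is_rows
        flags = [False] * len(feature_rows) + [True] * len(is_rows)
        return build_dataset(rows, is_internal_standard=flags)

    def test_constant_standard_is_noop(self):
        rng = np.random.default_rng(1)
        feats = np.exp2(rng.normal(10, 1, size=(3, 6))).tolist()
        ds = self._with_standard(feats, [[64.0] * 6])
        with pytest.warns(UserWarning):
            out = nomis_normalize(ds)
        np.testing.assert_allclose(out.intensities, np.array(feats), rtol=1e-9)

    def test_feature_equal_to_standard_flattened(self):
        rng = np.random.default_rng(2)
        is_log = rng.normal(8, 0.5, size=6)
        feature = np.exp2(is_log + 3.0)  # IS + constant on log scale
        other = np.exp2(rng.normal(10, 1, size=6))
        ds = self._with_standard([feature.tolist(), other.tolist()],
                                 [np.exp2(is_log).tolist()])
        out = nomis_normalize(ds)
        assert np.var(np.log2(out.intensities[0])) <= 1e-18

    def test_orthogonal_feature_unchanged(self):
        # construct x orthogonal to the centered IS column -> b = 0
        is_log = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5]) + 8
        s = is_log - is_log.mean()
        x = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])
        x -= (x @ s) / (s @ s) * s  # project out S
        ds = self._with_standard([np.exp2(x + 10).tolist()], [np.exp2(is_log).tolist()])
        out = nomis_normalize(ds)
        np.testing.assert_allclose(
            out.intensities[0], np.exp2(x + 10), rtol=1e-9
        )

    def test_standards_removed_from_output(self):
        rng = np.random.default_rng(3)
        ds = self._with_standard(
            np.exp2(rng.normal(10, 1, size=(2, 6))).tolist(),
            [np.exp2(rng.normal(8, 0.2, size=6)).tolist()],
        )
        out = nomis_normalize(ds)
        assert out.n_features == 2
        assert not out.feature_meta["is_internal_standard"].any()

    def test_no_standards_error(self, toy_dataset):
        with pytest.raises(ValidationError):
            nomis_normalize(toy_dataset, standards=[])


class TestQcCv:
    def test_constant_qc_zero(self):
        assert qc_cv(_qc_ds([100.0, 100.0, 100.0]))["F0"] == 0.0

    def test_hand_computed_ten_percent(self):
        assert qc_cv(_qc_ds([90.0, 100.0, 110.0]))["F0"] == pytest.approx(10.0)

    def test_single_qc_value_undefined(self):
        ds = _qc_ds([100.0, NAN, NAN])
        assert np.isnan(qc_cv(ds)["F0"])

    def test_fewer_than_two_qc_samples_error(self, toy_dataset):
        with pytest.raises(ValidationError):
            qc_cv(toy_dataset)


class TestPipeline:
    def test_identity_on_clean_data(self):
        # no duplicates, no missingness, no drift, constant standards:
        # the chain returns input features unchanged (minus standards)
        rng = np.random.default_rng(5)
        feats = np.exp2(rng.normal(12, 1, size=(5, 11)))
        rows = np.vstack([feats, np.full((1, 11), 64.0)])
        roles = ["study"] * 8 + ["pooled_qc"] * 3
        groups = ["DEL", "CNT"] * 4 + ["none"] * 3
        pair_ids = [f"P{i // 2}" for i in range(8)] + [""] * 3
        ds = build_dataset(rows, roles=roles, groups=groups, pair_ids=pair_ids,
                           is_internal_standard=[False] * 5 + [True])
        # constant QC: make QC columns equal to the row mean
        for q in (8, 9, 10):
            ds.intensities[:, q] = ds.intensities[:, :8].mean(axis=1)
        with pytest.warns(UserWarning):
            out, _ = preprocess_pipeline(ds, paired_design(ds),
                                         PreprocessOptions(n_trees=50), seed=0)
        assert out.n_features == 5
        np.testing.assert_allclose(out.intensities[:, :8], feats[:, :8], rtol=1e-6)

    def test_cv_monotone_on_synthetic_drift(self):
        cfg = SimulationConfig(
            n_pairs=12, n_features={"metabolite": 40},
            n_differential={"metabolite": 4},
            n_internal_standards={"metabolite": 3},
            network_edges=0, drift_amplitude=0.3, missing_rate=0.03, seed=2,
        )
        datasets, design, _ = generate_study(cfg)
        _, report = preprocess_pipeline(
            datasets["metabolite"], design, PreprocessOptions(n_trees=100), seed=0
        )
        meds = {
            step: np.nanmedian(list(cvs.values()))
            for step, cvs in report.qc_cv.items()
            if cvs
        }
        order = ["drift_correction", "imputation", "normalization"]
        vals = [meds[s] for s in order if s in meds]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(vals, vals[1:]))
        assert meds["drift_correction"] < meds["input"]
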