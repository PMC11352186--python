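"""LC-MS feature-table preprocessing chain.

Order of operations: lipid line consolidation -> presence filter ->
QC-based random-forest drift correction -> knn imputation -> multi-IS
least-squares normalization.  Pooled-QC coefficient of variation is
reported at each step.  Each step has an off switch in the pipeline
driver; log base 2 is used wherever a log is taken.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

from .datamodel import MatchedDesign, OmicsDataset, ValidationError, validate_dataset

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Per-step bookkeeping: feature counts, QC CVs, dropped features."""

    feature_counts: dict = field(default_factory=dict)  # step -> n features
    qc_cv: dict = field(default_factory=dict)  # step -> {feature_id: CV% or nan}
    dropped: list = field(default_factory=list)  # (feature_id, reason)
    flagged: list = field(default_factory=list)  # (feature_id, note)

    def record(self, step: str, ds: OmicsDataset) -> None:
        self.feature_counts[step] = ds.n_features
        try:
            self.qc_cv[step] = qc_cv(ds)
        except ValidationError:
            self.qc_cv[step] = {}

    def cv_table(self) -> pd.DataFrame:
        """Per-feature CV at each recorded step, wide format."""
        steps = list(self.qc_cv)
        feats = sorted({f for cvs in self.qc_cv.values() for f in cvs})
        return pd.DataFrame(
            {s: [self.qc_cv[s].get(f, np.nan) for f in feats] for s in steps},
            index=pd.Index(feats, name="feature_id"),
        )


def consolidate_lipid_lines(ds: OmicsDataset) -> OmicsDataset:
    """Sum duplicate lipid signal lines sharing a consolidation key.

    Rows with the same non-empty ``consolidation_key`` are replaced by one
    row whose per-sample value is the sum of the non-missing contributions;
    a cell stays missing only when every contributing cell is missing.
    Rows with empty keys (and non-lipid layers) pass through unchanged.
    """
    validate_dataset(ds)
    fm = ds.feature_meta
    keys = fm["consolidation_key"].fillna("")
    dup_mask = (keys != "") & (fm["layer"] == "lipid")
    if not dup_mask.any():
        return ds.copy()

    new_rows = []
    new_meta = []
    consumed = np.zeros(len(fm), dtype=bool)
    for i in range(len(fm)):
        if consumed[i]:
            continue
        if not dup_mask.iloc[i]:
            new_rows.append(ds.intensities[i, :])
            new_meta.append(fm.iloc[i])
            continue
        key = keys.iloc[i]
        members = np.where((keys == key).to_numpy() & dup_mask.to_numpy())[0]
        consumed[members] = True
        sub_meta = fm.iloc[members]
        if sub_meta["is_internal_standard"].nunique() > 1 or sub_meta["layer"].nunique() > 1:
            raise ValidationError(
                f"conflicting feature metadata within consolidation key {key!r}"
            )
        block = ds.intensities[members, :]
        all_missing = np.all(np.isnan(block), axis=0)
        summed = np.nansum(block, axis=0)
        summed[all_missing] = np.nan
        new_rows.append(summed)
        meta = sub_meta.iloc[0].copy()
        meta["feature_id"] = key
        new_meta.append(meta)

    fm_new = pd.DataFrame(new_meta).reset_index(drop=True)
    return OmicsDataset(
        intensities=np.vstack(new_rows),
        feature_meta=fm_new,
        sample_meta=ds.sample_meta.copy(),
    )


def presence_filter(
    ds: OmicsDataset,
    design: MatchedDesign,
    min_frac: float = 0.5,
    rule: str = "either",
) -> tuple[OmicsDataset, PreprocessReport]:
    """Keep features measured in >= ``min_frac`` of one phenotypic group.

    With ``rule='either'`` (default) a feature passes when its non-missing
    fraction reaches ``min_frac`` within DEL or within CNT; ``'both'``
    requires both groups.  Pooled-QC samples are not counted and internal
    standards are always retained.
    """
    validate_dataset(ds)
    design.validate_against(ds)
    sm = ds.sample_meta
    del_mask = ((sm["role"] == "study") & (sm["group"] == "DEL")).to_numpy()
    cnt_mask = ((sm["role"] == "study") & (sm["group"] == "CNT")).to_numpy()
    if del_mask.sum() == 0 or cnt_mask.sum() == 0:
        raise ValidationError("presence filter requires study samples in both groups")

    obs = ~np.isnan(ds.intensities)
    frac_del = obs[:, del_mask].mean(axis=1)
    frac_cnt = obs[:, cnt_mask].mean(axis=1)
    if rule == "either":
        keep = (frac_del >= min_frac) | (frac_cnt >= min_frac)
    elif rule == "both":
        keep = (frac_del >= min_frac) & (frac_cnt >= min_frac)
    else:
        raise ValueError(f"unknown presence rule {rule!r}")
    keep |= ds.feature_meta["is_internal_standard"].to_numpy()

    report = PreprocessReport()
    for fid in ds.feature_meta.loc[~keep, "feature_id"]:
        report.dropped.append((fid, f"present in < {min_frac:.0%} of both groups"))
    out = ds.subset_features(np.where(keep)[0])
    report.record("presence_filter", out)
    return out, report


def qc_rfsc_correct(
    ds: OmicsDataset,
    n_trees: int = 500,
    seed: int = 0,
    reference: str = "median",
    min_samples_leaf: int = 2,
) -> OmicsDataset:
    """Random-forest signal-drift correction against pooled-QC samples.

    Per feature, a random-forest regression of QC intensity on injection
    order estimates the drift value d(o) at every sample's order o, and the
    corrected intensity is ``raw * ref(QC raw) / d(o)`` where ``ref`` is
    the median (configurable to mean).  Features with fewer than 3
    non-missing QC values pass through unchanged (flagged in the log).
    """
    validate_dataset(ds)
    qc = ds.qc_mask()
    if qc.sum() < 3:
        raise ValidationError("QC-RFSC requires >= 3 pooled-QC samples")
    orders = ds.sample_meta["injection_order"].to_numpy(dtype=float)
    qc_orders = orders[qc]
    ref_fn = np.nanmedian if reference == "median" else np.nanmean

    out = ds.intensities.copy()
    any_qc_feature = False
    rng = np.random.default_rng(seed)
    for i in range(ds.n_features):
        qc_vals = ds.intensities[i, qc]
        ok = ~np.isnan(qc_vals)
        if ok.sum() < 3:
            log.warning(
                "qc_rfsc: feature %s has %d QC values, passing through",
                ds.feature_meta["feature_id"].iloc[i], int(ok.sum()),
            )
            continue
        any_qc_feature = True
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=1,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        rf.fit(qc_orders[ok, None], qc_vals[ok])
        drift = rf.predict(orders[:, None])
        drift = np.maximum(drift, 1e-12)
        out[i, :] = ds.intensities[i, :] * (ref_fn(qc_vals[ok]) / drift)
    if not any_qc_feature:
        raise ValidationError("all QC values missing for every feature")
    return OmicsDataset(
        intensities=out, feature_meta=ds.feature_meta.copy(), sample_meta=ds.sample_meta.copy()
    )


def knn_impute(ds: OmicsDataset, k: int = 10) -> tuple[OmicsDataset, PreprocessReport]:
    """Feature-wise k-nearest-neighbour imputation on log2 intensities.

    Neighbours are *features* (rows), compared by Euclidean distance over
    jointly observed samples; a missing entry becomes the distance-weighted
    average of the k nearest observed neighbours at that sample,
    back-transformed to raw scale.  Features missing everywhere are dropped.
    Observed values are never altered.
    """
    validate_dataset(ds)
    if k < 1:
        raise ValueError("k must be >= 1")
    report = PreprocessReport()

    all_missing = np.all(np.isnan(ds.intensities), axis=1)
    for fid in ds.feature_meta.loc[all_missing, "feature_id"]:
        report.dropped.append((fid, "missing in every sample"))
    ds = ds.subset_features(np.where(~all_missing)[0])

    if not np.isnan(ds.intensities).any():
        report.record("knn_impute", ds)
        return ds.copy(), report
    if ds.n_features < 2:
        raise ValidationError("knn imputation needs at least 2 features")

    k_eff = min(k, ds.n_features - 1)
    if k_eff < k:
        log.warning("knn_impute: k clamped from %d to %d", k, k_eff)

    logx = np.log2(ds.intensities)
    imputer = KNNImputer(n_neighbors=k_eff, weights="distance", metric="nan_euclidean")
    # rows = features: neighbours of a feature-row are other feature-rows
    filled = imputer.fit_transform(logx)
    out = np.exp2(filled)
    obs = ~np.isnan(ds.intensities)
    out[obs] = ds.intensities[obs]
    result = OmicsDataset(
        intensities=out, feature_meta=ds.feature_meta.copy(), sample_meta=ds.sample_meta.copy()
    )
    report.record("knn_impute", result)
    return result, report


def nomis_normalize(ds: OmicsDataset, standards: list[str] | None = None) -> OmicsDataset:
    """Remove internal-standard-correlated variation by least squares.

    On log2 scale, with S the sample-centered matrix of internal-standard
    signals, each feature x is replaced by ``x - S @ b`` where b minimizes
    ``||x_centered - S @ b||^2`` (feature mean preserved).  The standards
    themselves are removed from the output.  Rank-deficient S falls back to
    a ridge solve (lambda = 1e-8) with a warning.
    """
    validate_dataset(ds)
    if standards is None:
        standards = list(
            ds.feature_meta.loc[ds.feature_meta["is_internal_standard"], "feature_id"]
        )
    if not standards:
        raise ValidationError("no internal standards supplied")
    idx = [ds.feature_index(s) for s in standards]
    if len(idx) >= ds.n_samples:
        raise ValidationError("more internal standards than samples")
    if np.isnan(ds.intensities[idx, :]).any():
        raise ValidationError("internal standards must be complete (impute first)")

    logx = np.log2(ds.intensities)
    S = logx[idx, :].T  # samples x standards
    S = S - S.mean(axis=0, keepdims=True)

    keep = np.setdiff1d(np.arange(ds.n_features), idx)
    X = logx[keep, :].T  # samples x features, may contain NaN
    means = np.nanmean(X, axis=0, keepdims=True)
    Xc = X - means

    StS = S.T @ S
    rank = np.linalg.matrix_rank(StS) if S.size else 0
    Xfit = np.nan_to_num(Xc, nan=0.0)  # NaN contributes nothing to the fit
    if S.size == 0 or rank < S.shape[1]:
        warnings.warn("rank-deficient internal-standard matrix; ridge fallback")
        B = np.linalg.solve(StS + 1e-8 * np.eye(S.shape[1]), S.T @ Xfit)
    else:
        B, *_ = np.linalg.lstsq(S, Xfit, rcond=None)
    normalized = X - S @ B  # feature means restored implicitly (S@B is centered)

    out = np.exp2(normalized.T)
    return OmicsDataset(
        intensities=out,
        feature_meta=ds.feature_meta.iloc[keep].reset_index(drop=True),
        sample_meta=ds.sample_meta.copy(),
    )


def qc_cv(ds: OmicsDataset) -> dict[str, float]:
    """Per-feature coefficient of variation (%) over pooled-QC samples.

    CV = 100 * sample sd / mean of the non-missing raw-scale QC values;
    features with fewer than 2 QC values map to NaN (undefined).
    """
    qc = ds.qc_mask()
    if qc.sum() < 2:
        raise ValidationError("qc_cv requires >= 2 pooled-QC samples")
    result: dict[str, float] = {}
    for i, fid in enumerate(ds.feature_ids):
        vals = ds.intensities[i, qc]
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            result[fid] = float("nan")
        else:
            result[fid] = float(100.0 * np.std(vals, ddof=1) / np.mean(vals))
    return result


@dataclass
class PreprocessOptions:
    consolidate: bool = True
    presence: bool = True
    drift_correct: bool = True
    impute: bool = True
    normalize: bool = True
    min_frac: float = 0.5
    presence_rule: str = "either"
    n_trees: int = 500
    knn_k: int = 10
    rfsc_reference: str = "median"
    rfsc_leaf: int = 2


def preprocess_pipeline(
    ds: OmicsDataset,
    design: MatchedDesign,
    options: PreprocessOptions | None = None,
    seed: int = 0,
) -> tuple[OmicsDataset, PreprocessReport]:
    """Run the full chain with per-step CV reporting."""
    opts = options or PreprocessOptions()
    report = PreprocessReport()
    report.record("input", ds)
    if opts.consolidate:
        ds = consolidate_lipid_lines(ds)
        report.record("consolidate", ds)
    if opts.presence:
        ds, r = presence_filter(ds, design, opts.min_frac, opts.presence_rule)
        report.dropped.extend(r.dropped)
        report.record("presence_filter", ds)
    if opts.drift_correct:
        ds = qc_rfsc_correct(
            ds, n_trees=opts.n_trees, seed=seed,
            reference=opts.rfsc_reference, min_samples_leaf=opts.rfsc_leaf,
        )
        report.record("drift_correction", ds)
    if opts.impute:
        ds, r = knn_impute(ds, k=opts.knn_k)
        report.dropped.extend(r.dropped)
        report.record("imputation", ds)
    if opts.normalize and ds.feature_meta["is_internal_standard"].any():
        ds = nomis_normalize(ds)
        report.record("normalization", ds)
    return ds, report
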