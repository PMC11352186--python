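"""Matched-pair differential analysis.

Three paired tests per feature (t, Wilcoxon signed-rank, sign/binomial),
Benjamini-Hochberg adjustment per test within an omics layer, and a signed
one-step Tukey-biweight fold change summarizing the per-pair DEL/CNT
ratios.  A feature is called significant when its smallest nominal p-value
falls below alpha (default 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MatchedDesign, OmicsDataset, validate_dataset

#: sentinel for p-values that cannot be computed (too few usable pairs)
UNDEFINED = float("nan")

# one-step biweight tuning constants
BIWEIGHT_C = 5.0
BIWEIGHT_EPS = 1e-4


@dataclass
class DifferentialRecord:
    feature_id: str
    layer: str
    p_paired_t: float
    p_wilcoxon: float
    p_sign: float
    min_p: float
    bh_paired_t: float
    bh_wilcoxon: float
    bh_sign: float
    tfc: float
    significant: bool
    degenerate: bool = False


def _clean_pairs(case_values, control_values) -> tuple[np.ndarray, np.ndarray]:
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.shape != ctrl.shape:
        raise ValueError("case and control vectors must have equal length")
    ok = ~(np.isnan(case) | np.isnan(ctrl))
    return case[ok], ctrl[ok]


def paired_t(case_values, control_values) -> float:
    """Two-sided paired t-test p-value on the supplied (log2) values.

    Zero variance of the differences yields p = 1 (degenerate case).
    """
    case, ctrl = _clean_pairs(case_values, control_values)
    n = len(case)
    if n < 3:
        return UNDEFINED
    d = case - ctrl
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 1.0
    t = d.mean() / (sd / math.sqrt(n))
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


def wilcoxon_signed_rank(case_values, control_values) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties, a tie/continuity-corrected normal approximation
    otherwise.  Fewer than 3 usable pairs -> NaN.
    """
    case, ctrl = _clean_pairs(case_values, control_values)
    d = case - ctrl
    d = d[d != 0]
    n = len(d)
    if n < 3:
        return UNDEFINED
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(res.pvalue)


def sign_test(case_values, control_values) -> float:
    """Two-sided exact binomial test on the signs of the paired differences.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) with X ~ Binomial(n, 1/2),
    k = number of positive differences, zero differences dropped.
    """
    case, ctrl = _clean_pairs(case_values, control_values)
    d = case - ctrl
    d = d[d != 0]
    n = len(d)
    if n < 1:
        return UNDEFINED
    k = int((d > 0).sum())
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (undefined tests) are excluded from m and returned as NaN;
    order of the input is preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def signed_fold(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Per-pair signed fold: r if r >= 1 else -1/r, with r = DEL/CNT."""
    r = case / ctrl
    return np.where(r >= 1.0, r, -1.0 / r)


def tukey_biweight(values: np.ndarray, c: float = BIWEIGHT_C, eps: float = BIWEIGHT_EPS) -> float:
    """One-step Tukey biweight location estimate."""
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    if w.sum() == 0.0:
        return float(med)
    return float(np.sum(w * x) / np.sum(w))


def tukey_biweight_fc(case_values, control_values) -> float:
    """Signed robust fold change across matched pairs.

    Raw-scale intensities; each pair contributes r = DEL/CNT mapped to a
    signed fold (r or -1/r), and the one-step Tukey biweight of those folds
    is returned.  Requires >= 3 complete pairs of positive intensities.
    """
    case, ctrl = _clean_pairs(case_values, control_values)
    if len(case) < 3:
        raise ValueError("tukey_biweight_fc requires >= 3 usable pairs")
    if np.any(case <= 0) or np.any(ctrl <= 0):
        raise ValueError("intensities must be positive on the raw scale")
    return tukey_biweight(signed_fold(case, ctrl))


def differential_table(
    ds: OmicsDataset, design: MatchedDesign, alpha: float = 0.05
) -> list[DifferentialRecord]:
    """Full per-feature differential analysis for one (or more) layers.

    BH adjustment is applied separately per test and per omics layer;
    output is sorted by tFC descending.  Internal standards are excluded.
    """
    validate_dataset(ds)
    design.validate_against(ds)
    case_idx = [ds.sample_index(s) for s in design.case_ids()]
    ctrl_idx = [ds.sample_index(s) for s in design.control_ids()]

    fm = ds.feature_meta
    rows = []
    for i in range(ds.n_features):
        if fm["is_internal_standard"].iloc[i]:
            continue
        case = ds.intensities[i, case_idx]
        ctrl = ds.intensities[i, ctrl_idx]
        ok = ~(np.isnan(case) | np.isnan(ctrl))
        case, ctrl = case[ok], ctrl[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            p_t = paired_t(np.log2(case), np.log2(ctrl))
        p_w = wilcoxon_signed_rank(case, ctrl)
        p_s = sign_test(case, ctrl)
        degenerate = len(case) >= 3 and np.all(case - ctrl == 0)
        try:
            tfc = tukey_biweight_fc(case, ctrl)
        except ValueError:
            tfc = float("nan")
        rows.append(
            {
                "feature_id": fm["feature_id"].iloc[i],
                "layer": fm["layer"].iloc[i],
                "p_paired_t": p_t,
                "p_wilcoxon": p_w,
                "p_sign": p_s,
                "tfc": tfc,
                "degenerate": degenerate,
            }
        )

    df = pd.DataFrame(rows)
    if df.empty:
        return []
    for col in ("p_paired_t", "p_wilcoxon", "p_sign"):
        df["bh_" + col[2:]] = np.nan
        for layer in df["layer"].unique():
            sel = df["layer"] == layer
            df.loc[sel, "bh_" + col[2:]] = bh_adjust(df.loc[sel, col])
    df["min_p"] = df[["p_paired_t", "p_wilcoxon", "p_sign"]].min(axis=1)
    df["significant"] = df["min_p"] < alpha
    df = df.sort_values("tfc", ascending=False, kind="stable").reset_index(drop=True)

    return [
        DifferentialRecord(
            feature_id=r.feature_id,
            layer=r.layer,
            p_paired_t=r.p_paired_t,
            p_wilcoxon=r.p_wilcoxon,
            p_sign=r.p_sign,
            min_p=r.min_p,
            bh_paired_t=r.bh_paired_t,
            bh_wilcoxon=r.bh_wilcoxon,
            bh_sign=r.bh_sign,
            tfc=r.tfc,
            significant=bool(r.significant),
            degenerate=bool(r.degenerate),
        )
        for r in df.itertuples(index=False)
    ]


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
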