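"""Multi-omics signature selection.

Two stages: a hard |tFC| threshold on the significant differential records,
then elastic-net leave-one-out stability selection — features with
non-zero coefficients in more than half of the n leave-one-out elastic-net
logistic models (lambda chosen by k-fold cross-validated deviance) form
the refined signature.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from ._enet import enet_logistic_path
from .datamodel import MatchedDesign, OmicsDataset
from .diffstats import DifferentialRecord

log = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    feature_ids: list[str]
    layers: dict[str, str]  # feature_id -> layer
    rule: str  # "threshold" or "stability"
    inclusion_counts: dict = field(default_factory=dict)  # feature_id -> count
    n_models: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, c in self.inclusion_counts.items():
            if not 0 <= c <= max(self.n_models, 1):
                raise ValueError(f"inclusion count out of range for {fid!r}")

    def per_layer_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fid in self.feature_ids:
            layer = self.layers.get(fid, "?")
            counts[layer] = counts.get(layer, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.feature_ids)


def fc_threshold_select(
    records: list[DifferentialRecord], cutoff: float = 1.5
) -> SignatureSet:
    """Keep significant features with |tFC| strictly above ``cutoff``."""
    chosen = [
        r for r in records if r.significant and np.isfinite(r.tfc) and abs(r.tfc) > cutoff
    ]
    return SignatureSet(
        feature_ids=[r.feature_id for r in chosen],
        layers={r.feature_id: r.layer for r in chosen},
        rule="threshold",
        params={"cutoff": cutoff},
    )


def _fold_assignment(sample_ids: list[str], labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic, order-invariant stratified fold ids keyed by sample id.

    Samples are ordered by a seed-keyed hash of their id within each class
    and dealt round-robin, so fold membership is invariant to sample order.
    """
    def h(sid: str) -> int:
        return int.from_bytes(
            hashlib.sha256(f"{seed}:{sid}".encode()).digest()[:8], "big"
        )

    folds = np.zeros(len(sample_ids), dtype=int)
    for cls in np.unique(labels):
        idx = [i for i in range(len(sample_ids)) if labels[i] == cls]
        idx.sort(key=lambda i: h(sample_ids[i]))
        for j, i in enumerate(idx):
            folds[i] = j % n_folds
    return folds


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha_mix: float, n_lambda: int) -> np.ndarray:
    """Log-spaced lambda grid from the all-zero solution down by 1e-4."""
    n = len(y)
    ybar = y.mean()
    grad = X.T @ (y - ybar) / n
    lam_max = np.max(np.abs(grad)) / max(alpha_mix, 1e-3)
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def _fit_path(X, y, lambdas, alpha_mix) -> np.ndarray:
    """Coefficient matrix along a descending lambda path (warm-started);
    one row per lambda, intercept in the last column."""
    return enet_logistic_path(X, np.asarray(y, float), np.asarray(lambdas), alpha_mix)


def _cv_deviance_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    folds: np.ndarray,
    alpha_mix: float,
) -> np.ndarray:
    """Mean cross-validated binomial deviance for each lambda."""
    dev = np.zeros(len(lambdas))
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        if len(np.unique(y[tr])) < 2:
            raise _SingleClassFold()
        coefs = _fit_path(X[tr], y[tr], lambdas, alpha_mix)
        z = X[te] @ coefs[:, :-1].T + coefs[:, -1]  # n_test x n_lambda
        pr = np.clip(1.0 / (1.0 + np.exp(-z)), 1e-12, 1 - 1e-12)
        yt = y[te][:, None]
        dev += -2.0 * np.sum(yt * np.log(pr) + (1 - yt) * np.log(1 - pr), axis=0)
    return dev / len(y)


class _SingleClassFold(Exception):
    pass


def elastic_net_stability(
    ds: OmicsDataset,
    design: MatchedDesign,
    signature: SignatureSet,
    alpha_mix: float = 0.5,
    n_lambda: int = 100,
    cv_folds: int = 3,
    seed: int = 0,
) -> SignatureSet:
    """Leave-one-out elastic-net stability selection over a signature.

    For each of the n leave-one-out iterations an elastic-net logistic
    path is fit on the remaining samples; lambda is picked at the minimum
    cross-validated deviance and the features with non-zero coefficients
    are recorded.  Features present in more than half of the iterations
    are returned.
    """
    sample_ids, labels, X = _design_matrix(ds, design, signature)
    n = len(sample_ids)
    if n < 4:
        raise ValueError("stability selection needs at least 4 samples")

    # log2 transform + per-feature standardization over all samples
    X = np.log2(X)
    X = (X - X.mean(axis=0)) / (X.std(axis=0) + 1e-12)

    counts = {fid: 0 for fid in signature.feature_ids}
    for left_out in range(n):
        tr = np.ones(n, dtype=bool)
        tr[left_out] = False
        Xtr, ytr = X[tr], labels[tr]
        ids_tr = [sample_ids[i] for i in range(n) if tr[i]]
        lambdas = _lambda_path(Xtr, ytr, alpha_mix, n_lambda)
        fold_seed = seed
        while True:
            folds = _fold_assignment(ids_tr, ytr, cv_folds, fold_seed)
            try:
                dev = _cv_deviance_path(Xtr, ytr, lambdas, folds, alpha_mix)
                break
            except _SingleClassFold:
                log.warning("single-class CV fold; re-drawing fold assignment")
                fold_seed += 1
        best = int(np.argmin(dev))
        # refit the path on the full training fold up to the chosen lambda
        coefs = _fit_path(Xtr, ytr, lambdas[: best + 1], alpha_mix)
        nz = np.abs(coefs[-1, :-1]) > 1e-8
        for fid, keep in zip(signature.feature_ids, nz):
            if keep:
                counts[fid] += 1

    majority = [fid for fid in signature.feature_ids if counts[fid] > n / 2]
    return SignatureSet(
        feature_ids=majority,
        layers={fid: signature.layers[fid] for fid in majority},
        rule="stability",
        inclusion_counts=counts,
        n_models=n,
        params={"alpha_mix": alpha_mix, "n_lambda": n_lambda, "cv_folds": cv_folds, "seed": seed},
    )


def _design_matrix(
    ds: OmicsDataset, design: MatchedDesign, signature: SignatureSet
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Samples x signature-features raw matrix with binary DEL labels."""
    f_idx = [ds.feature_index(f) for f in signature.feature_ids]
    sample_ids = design.case_ids() + design.control_ids()
    s_idx = [ds.sample_index(s) for s in sample_ids]
    X = ds.intensities[np.ix_(f_idx, s_idx)].T
    if np.isnan(X).any():
        raise ValueError("signature matrix contains missing values; impute first")
    labels = np.array([1] * design.n_pairs + [0] * design.n_pairs)
    return sample_ids, labels, X
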