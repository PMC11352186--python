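"""Clustering and classification evaluation of a molecular signature.

UPGMA (average-linkage) clustering on 1 - Pearson correlation with a
Fisher-exact phenotype association, and PCA + SVM leave-one-out
classification with rank-based ROC AUC and a stratified bootstrap
confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.svm import SVC

from .datamodel import OmicsDataset
from .signature import SignatureSet

log = logging.getLogger(__name__)

KERNELS = ("linear", "poly", "rbf")


@dataclass
class ClusterEval:
    assignments: dict  # sample_id -> cluster index (0/1)
    misclustered_count: int
    fisher_p: float


@dataclass
class ClassifierEval:
    decision_values: dict  # sample_id -> held-out decision value
    l1o_accuracy: float  # percent
    auc: float
    auc_ci: tuple
    kernel: str
    n_components: int


def _signature_matrix(ds: OmicsDataset, features: SignatureSet | list[str]) -> tuple[np.ndarray, list[str]]:
    fids = features.feature_ids if isinstance(features, SignatureSet) else list(features)
    idx = [ds.feature_index(f) for f in fids]
    study = np.where(ds.study_mask())[0]
    X = ds.intensities[np.ix_(idx, study)]
    sample_ids = [ds.sample_ids[j] for j in study]
    if np.isnan(X).any():
        raise ValueError("signature matrix contains missing values")
    return X, sample_ids


def upgma_cluster(
    ds: OmicsDataset, features: SignatureSet | list[str]
) -> tuple[np.ndarray, dict]:
    """Average-linkage clustering of study samples, cut into 2 clusters.

    Feature rows are standardized across samples, the sample-sample
    distance is 1 - Pearson correlation of the standardized profiles, and
    samples are ordered lexicographically by id before linkage so ties
    break deterministically.

    Returns ``(linkage_matrix, {sample_id: cluster})``.
    """
    X, sample_ids = _signature_matrix(ds, features)
    order = np.argsort(sample_ids)
    sample_ids = [sample_ids[i] for i in order]
    X = X[:, order]

    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d constant feature(s) before clustering", int((~keep).sum()))
    X = X[keep, :]
    if X.shape[0] == 0:
        raise ValueError("no non-constant features to cluster on")
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)

    n = len(sample_ids)
    if n < 2:
        raise ValueError("need >= 2 samples")
    corr = np.corrcoef(Z.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust") - 1
    return link, dict(zip(sample_ids, (int(c) for c in cut)))


def cluster_eval(cut: dict, labels: dict) -> ClusterEval:
    """Score a 2-cluster cut against binary DEL/CNT labels.

    ``misclustered_count`` is the minimum number of mismatches over the two
    cluster-to-label assignments; ``fisher_p`` the two-sided Fisher exact
    p-value of the 2x2 cluster-by-label table.
    """
    samples = sorted(cut)
    cl = np.array([cut[s] for s in samples])
    lab = np.array([1 if labels[s] == "DEL" else 0 for s in samples])
    if len(np.unique(cl)) != 2:
        raise ValueError("cut must contain two non-empty clusters")
    mis_a = int(np.sum(cl != lab))
    mis_b = int(np.sum(cl == lab))
    table = [
        [int(np.sum((cl == 0) & (lab == 1))), int(np.sum((cl == 0) & (lab == 0)))],
        [int(np.sum((cl == 1) & (lab == 1))), int(np.sum((cl == 1) & (lab == 0)))],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ClusterEval(
        assignments=dict(cut),
        misclustered_count=min(mis_a, mis_b),
        fisher_p=float(p),
    )


def _pca_project(train: np.ndarray, test: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center by training means, project both sets on top PCs."""
    mean = train.mean(axis=0, keepdims=True)
    tr = train - mean
    te = test - mean
    k = min(n_components, min(tr.shape) - 1 if min(tr.shape) > 1 else 1, tr.shape[1])
    _, _, vt = np.linalg.svd(tr, full_matrices=False)
    comps = vt[:k]
    # sign convention: largest-magnitude loading positive, for determinism
    for r in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[r]))
        if comps[r, j] < 0:
            comps[r] *= -1
    return tr @ comps.T, te @ comps.T


def pca_svm_l1o(
    ds: OmicsDataset,
    features: SignatureSet | list[str],
    labels: dict,
    kernel: str = "linear",
    n_components: int = 2,
    pca_scope: str = "per_fold",
    seed: int = 0,
    svm_c: float = 1.0,
) -> ClassifierEval:
    """Leave-one-out PCA + SVM classification of study samples.

    Data are log2-transformed; mean-centering and the PCA projection use
    training-fold statistics (``pca_scope='per_fold'``) or the full data
    (``'global'``).  The SVM uses C = ``svm_c`` and, for the Gaussian
    kernel, gamma = 1 / (n_components * variance of the projected training
    data).
    """
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    X, sample_ids = _signature_matrix(ds, features)
    n = len(sample_ids)
    if n < 6:
        raise ValueError("need >= 6 samples for leave-one-out evaluation")
    y = np.array([1 if labels[s] == "DEL" else 0 for s in sample_ids])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xl = np.log2(X.T)  # samples x features

    if n_components > min(n - 1, Xl.shape[1]):
        log.warning("n_components clamped to data rank")

    if pca_scope == "global":
        # one projection shared by every fold, centered on full-data means
        P_all, _ = _pca_project(Xl, Xl[:0], n_components)
    elif pca_scope != "per_fold":
        raise ValueError(f"unknown pca_scope {pca_scope!r}")

    decisions = np.zeros(n)
    correct = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if pca_scope == "global":
            Ptr, Pte = P_all[tr], P_all[~tr]
        else:
            Ptr, Pte = _pca_project(Xl[tr], Xl[~tr], n_components)
        gamma = 1.0 / (Ptr.shape[1] * Ptr.var()) if Ptr.var() > 0 else "scale"
        svm = SVC(kernel=kernel, C=svm_c, gamma=gamma, degree=3, random_state=seed)
        svm.fit(Ptr, y[tr])
        d = float(svm.decision_function(Pte)[0])
        decisions[i] = d
        if int(svm.predict(Pte)[0]) == y[i]:
            correct += 1

    auc, lo, hi = roc_auc(decisions, y, seed=seed)
    return ClassifierEval(
        decision_values=dict(zip(sample_ids, decisions)),
        l1o_accuracy=100.0 * correct / n,
        auc=auc,
        auc_ci=(lo, hi),
        kernel=kernel,
        n_components=n_components,
    )


def best_kernel_eval(
    ds: OmicsDataset,
    features: SignatureSet | list[str],
    labels: dict,
    n_components: int = 2,
    pca_scope: str = "per_fold",
    seed: int = 0,
) -> ClassifierEval:
    """Evaluate all three kernels; return the best by L1O accuracy
    (ties broken linear > poly > rbf)."""
    evals = [
        pca_svm_l1o(ds, features, labels, k, n_components, pca_scope, seed)
        for k in KERNELS
    ]
    return max(evals, key=lambda e: (e.l1o_accuracy, -KERNELS.index(e.kernel)))


def roc_auc(
    decision_values, labels, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float, float]:
    """Rank-based (Mann-Whitney, midrank ties) AUC with bootstrap 95% CI.

    The CI is a stratified percentile bootstrap (resampling positives and
    negatives separately), truncated to [0, 1].
    """
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    def auc_of(p, ng):
        ranks = stats.rankdata(np.concatenate([p, ng]))
        return (ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2) / (len(p) * len(ng))

    auc = float(auc_of(pos, neg))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        boots[b] = auc_of(bp, bn)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
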