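"""Probabilistic-network multi-omics integration.

Structure learning is greedy hill climbing over DAGs scored by the
Gaussian BIC (linear-Gaussian node models), starting from the empty graph
with add/remove/reverse operators and a parent cap.  Edge strengths are
skeleton frequencies over bootstrap resamples; external-knowledge edges
boost strengths multiplicatively, and the final network keeps edges whose
modified strength exceeds a data-driven significance threshold (the
L1-closest ideal two-point CDF).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import ConsensusNetwork, KnowledgeGraph, ValidationError

log = logging.getLogger(__name__)

_EPS_DELTA = 1e-9


def _as_matrix(data: np.ndarray) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D samples x features matrix")
    if not np.isfinite(X).all():
        raise ValueError("data contains non-finite values")
    return X


def _hash_order(names: list[str], seed: int) -> np.ndarray:
    """Seed-keyed permutation of columns by feature name (order-invariance)."""
    def h(name: str) -> int:
        return int.from_bytes(hashlib.sha256(f"{seed}:{name}".encode()).digest()[:8], "big")

    return np.argsort([h(n) for n in names], kind="stable")


class _HillClimber:
    """Greedy DAG search maximizing the decomposable Gaussian BIC.

    Node scores are computed from the centered Gram matrix, so a score
    evaluation is an O(m^3) solve with m <= max_parents, independent of
    the sample count.
    """

    def __init__(self, X: np.ndarray, max_parents: int):
        n, p = X.shape
        if n < 3:
            raise ValueError("structure learning requires n >= 3 samples")
        self.n, self.p = n, p
        Xc = X - X.mean(axis=0, keepdims=True)
        self.C = Xc.T @ Xc
        # guard against zero-variance columns
        diag = np.diag(self.C).copy()
        diag[diag <= 0] = 1e-12
        self.C[np.diag_indices(p)] = diag
        self.max_parents = max_parents
        self.parents: list[set[int]] = [set() for _ in range(p)]
        self.children: list[set[int]] = [set() for _ in range(p)]
        self.rss = diag.copy()
        self.pen = 0.5 * np.log(n)  # BIC cost of one extra parameter
        self.add_delta = np.full((p, p), -np.inf)
        self.rem_delta = np.full((p, p), -np.inf)
        self._init_deltas()

    # -- scoring ---------------------------------------------------------
    def _rss_of(self, j: int, parent_list: list[int]) -> float:
        if not parent_list:
            return float(self.C[j, j])
        P = np.array(parent_list)
        A = self.C[np.ix_(P, P)]
        c = self.C[P, j]
        sol = np.linalg.solve(A, c)
        return float(max(self.C[j, j] - c @ sol, 1e-12))

    def _delta_from_rss(self, rss_old: float, rss_new: np.ndarray, dparams: int) -> np.ndarray:
        return -0.5 * self.n * (np.log(rss_new) - np.log(rss_old)) - dparams * self.pen

    def _init_deltas(self) -> None:
        d = np.sqrt(np.diag(self.C))
        r2 = (self.C / d[:, None] / d[None, :]) ** 2
        rss_ratio = np.clip(1.0 - r2, 1e-12, None)
        self.add_delta = -0.5 * self.n * np.log(rss_ratio) - self.pen
        np.fill_diagonal(self.add_delta, -np.inf)

    def _recompute_target(self, j: int) -> None:
        """Refresh cached deltas for every operator targeting node j."""
        P = sorted(self.parents[j])
        self.rss[j] = self._rss_of(j, P)
        self.add_delta[:, j] = -np.inf
        self.rem_delta[:, j] = -np.inf

        # removal deltas: one small solve per current parent
        for i in P:
            rest = [q for q in P if q != i]
            rss_without = self._rss_of(j, rest)
            self.rem_delta[i, j] = self._delta_from_rss(
                self.rss[j], np.array(rss_without), -1
            )

        if len(P) >= self.max_parents:
            return
        cand = np.array(
            [
                i
                for i in range(self.p)
                if i != j and i not in self.parents[j] and j not in self.parents[i]
            ],
            dtype=int,
        )
        if len(cand) == 0:
            return
        if not P:
            rss_new = np.clip(
                self.C[j, j] - self.C[cand, j] ** 2 / np.diag(self.C)[cand], 1e-12, None
            )
        else:
            Pa = np.array(P)
            A = self.C[np.ix_(Pa, Pa)]
            U = np.linalg.solve(A, self.C[np.ix_(Pa, cand)])  # m x k
            s = np.clip(np.diag(self.C)[cand] - np.sum(self.C[np.ix_(Pa, cand)] * U, axis=0), 1e-12, None)
            t = self.C[cand, j] - self.C[j, Pa] @ U
            rss_new = np.clip(self.rss[j] - t**2 / s, 1e-12, None)
        self.add_delta[cand, j] = self._delta_from_rss(self.rss[j], rss_new, +1)

    # -- graph utilities -------------------------------------------------
    def _creates_cycle(self, i: int, j: int) -> bool:
        """Would adding i -> j create a directed cycle (path j ~> i)?"""
        stack, seen = [j], {j}
        while stack:
            u = stack.pop()
            if u == i:
                return True
            for v in self.children[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    def _apply_add(self, i: int, j: int) -> None:
        self.parents[j].add(i)
        self.children[i].add(j)
        self._recompute_target(j)
        # i gaining a child invalidates add(j -> i) candidates only via the
        # two-cycle exclusion, handled inside _recompute_target(i)
        self._recompute_target(i)

    def _apply_remove(self, i: int, j: int) -> None:
        self.parents[j].discard(i)
        self.children[i].discard(j)
        self._recompute_target(j)
        self._recompute_target(i)

    # -- main loop -------------------------------------------------------
    def run(self, tie_rank: np.ndarray) -> list[tuple[int, int]]:
        """Hill climb to a local optimum; returns directed edges (i, j).

        ``tie_rank`` is a seed-keyed permutation rank per node used to
        break exact score ties deterministically but seed-dependently.
        """
        max_steps = 40 * self.p * self.p
        for _ in range(max_steps):
            op = self._best_op(tie_rank)
            if op is None:
                break
            kind, i, j = op
            if kind == "add":
                self._apply_add(i, j)
            elif kind == "rem":
                self._apply_remove(i, j)
            else:  # reverse
                self._apply_remove(i, j)
                self._apply_add(j, i)
        return [(i, j) for j in range(self.p) for i in self.parents[j]]

    def _best_op(self, tie_rank: np.ndarray):
        """Highest-delta legal operator, or None if no strict improvement.

        Candidates are ranked by (delta, tie_rank) and checked for
        acyclicity lazily, best first.
        """
        cands: list[tuple[float, int, int, int, str]] = []
        for kind, mat in (("add", self.add_delta), ("rem", self.rem_delta)):
            for i, j in np.argwhere(mat > _EPS_DELTA):
                cands.append((float(mat[i, j]), int(i), int(j), 0, kind))
        # reverse deltas derive from the two cached operator families
        for i, j in np.argwhere(self.rem_delta > -np.inf):
            if len(self.parents[i]) < self.max_parents and np.isfinite(self.add_delta[j, i]):
                d = float(self.rem_delta[i, j] + self.add_delta[j, i])
                if d > _EPS_DELTA:
                    cands.append((d, int(i), int(j), 0, "rev"))

        cands.sort(key=lambda c: (-c[0], tie_rank[c[1]], tie_rank[c[2]], c[4]))
        for d, i, j, _, kind in cands:
            if kind == "add" and self._creates_cycle(i, j):
                continue
            if kind == "rev" and self._would_cycle_on_reverse(i, j):
                continue
            return kind, i, j
        return None

    def _would_cycle_on_reverse(self, i: int, j: int) -> bool:
        # after removing i->j, adding j->i must not close a cycle
        self.children[i].discard(j)
        self.parents[j].discard(i)
        cyc = self._creates_cycle(j, i)
        self.children[i].add(j)
        self.parents[j].add(i)
        return cyc


def learn_structure(
    data: np.ndarray,
    feature_names: list[str] | None = None,
    max_parents: int = 4,
    seed: int = 0,
) -> set[tuple[str, str]]:
    """Learn a DAG by hill climbing; returns directed edges as name pairs.

    Candidate tie-breaking is keyed to a seed-dependent hash of the feature
    names, so results do not depend on column order.
    """
    X = _as_matrix(data)
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"V{i}" for i in range(p)]
    if len(set(feature_names)) != p:
        raise ValueError("duplicate feature names")
    order = _hash_order(list(feature_names), seed)
    hc = _HillClimber(X[:, order], max_parents)
    tie_rank = np.arange(p)
    edges_idx = hc.run(tie_rank)
    names = [feature_names[k] for k in order]
    return {(names[i], names[j]) for i, j in edges_idx}


def bootstrap_strengths(
    data: np.ndarray,
    feature_names: list[str] | None = None,
    B: int = 1000,
    resample_unit: str = "sample",
    pair_index: np.ndarray | None = None,
    max_parents: int = 4,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Skeleton frequency of every feature pair over B bootstrap resamples.

    ``resample_unit='pair'`` resamples matched pairs (rows grouped by
    ``pair_index``) instead of individual samples.  Every unordered pair is
    present in the result, most with strength 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = _as_matrix(data)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"V{i}" for i in range(p)]
    rng = np.random.default_rng(seed)

    if resample_unit == "pair":
        if pair_index is None:
            raise ValueError("pair resampling requires pair_index")
        pair_index = np.asarray(pair_index)
        units = [np.where(pair_index == u)[0] for u in np.unique(pair_index)]
    elif resample_unit == "sample":
        units = [np.array([i]) for i in range(n)]
    else:
        raise ValueError(f"unknown resample_unit {resample_unit!r}")

    counts: dict[tuple[str, str], int] = {}
    for _ in range(B):
        chosen = rng.integers(0, len(units), size=len(units))
        rows = np.concatenate([units[u] for u in chosen])
        Xb = X[rows, :]
        if np.any(Xb.std(axis=0) == 0):
            Xb = Xb + rng.normal(0, 1e-9, size=Xb.shape)  # degenerate resample guard
        edges = learn_structure(Xb, feature_names, max_parents, seed=int(rng.integers(2**31)))
        skel = {KnowledgeGraph.canonical(a, b) for a, b in edges}
        for e in skel:
            counts[e] = counts.get(e, 0) + 1

    strengths: dict[tuple[str, str], float] = {}
    names = sorted(feature_names)
    for a_i in range(p):
        for b_i in range(a_i + 1, p):
            e = (names[a_i], names[b_i])
            strengths[e] = counts.get(e, 0) / B
    return strengths


def apply_knowledge(
    strengths: dict[tuple[str, str], float],
    kg: KnowledgeGraph,
    weight: float = 0.3,
    mode: str = "boost",
) -> dict[tuple[str, str], float]:
    """Modify raw strengths with external-knowledge edges.

    Default boost form: ``1 - (1 - s) * (1 - weight)`` for edges in the
    knowledge graph, unchanged otherwise (maps [0,1] -> [0,1], monotone,
    never penalizes unlisted edges).  ``mode='mixture'`` uses the convex
    blend ``(1 - weight) * s + weight * kappa`` instead.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0,1]")
    out: dict[tuple[str, str], float] = {}
    for edge, s in strengths.items():
        kappa = 1.0 if edge in kg else 0.0
        if mode == "boost":
            out[edge] = 1.0 - (1.0 - s) * (1.0 - weight * kappa)
        elif mode == "mixture":
            out[edge] = (1.0 - weight) * s + weight * kappa
        else:
            raise ValueError(f"unknown knowledge mode {mode!r}")
    return out


def scutari_threshold(strengths) -> tuple[float, bool]:
    """Data-driven significance threshold on a vector of edge strengths.

    Let F be the empirical CDF of the strengths on [0, 1].  The ideal
    strength distribution of a perfectly sparse network is a two-point CDF
    equal to a constant q; the estimate picks q minimizing the L1 distance
    integral |F(s) - q| ds and returns the q-quantile of the strengths.
    Edges are significant strictly above the threshold.  Returns
    ``(threshold, degenerate)`` where ``degenerate`` marks an all-equal
    strength vector (empty significant set).
    """
    s = np.sort(np.asarray(list(strengths), dtype=float))
    if len(s) == 0:
        raise ValueError("need at least one strength value")
    if np.all(s == s[0]):
        return float(s[0]), True
    n = len(s)
    # piecewise-constant F over segment boundaries 0, s_1, ..., s_n, 1
    bounds = np.concatenate([[0.0], s, [1.0]])
    seg_len = np.diff(bounds)  # length n+1
    levels = np.arange(n + 1) / n  # F value on each segment
    qs = np.unique(levels)
    objective = np.array([np.sum(np.abs(levels - q) * seg_len) for q in qs])
    q_hat = qs[int(np.argmin(objective))]
    thr = float(np.quantile(s, q_hat))
    return thr, False


def consensus_network(
    strengths_modified: dict[tuple[str, str], float],
    threshold: float,
    feature_layers: dict[str, str],
    strengths_raw: dict[tuple[str, str], float] | None = None,
) -> ConsensusNetwork:
    """Assemble the final network from thresholded modified strengths.

    Retains edges with modified strength strictly above ``threshold``;
    nodes are the endpoints of retained edges; subnetworks are connected
    components with >= 2 nodes, reported largest first.
    """
    raw = strengths_raw or {}
    edges = {
        e: (raw.get(e, s), s)
        for e, s in strengths_modified.items()
        if s > threshold
    }
    nodes = {n for e in edges for n in e}
    node_layers = {n: feature_layers.get(n, "") for n in nodes}

    # connected components by union-find
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for node in nodes:
        comps.setdefault(find(node), []).append(node)
    subnets = sorted(
        (sorted(c) for c in comps.values() if len(c) >= 2),
        key=lambda c: (-len(c), c[0]),
    )
    return ConsensusNetwork(
        nodes=node_layers,
        edges=edges,
        threshold=float(threshold),
        subnetworks=subnets,
    )


@dataclass
class NetworkOptions:
    n_bootstrap: int = 1000
    max_parents: int = 4
    knowledge_weight: float = 0.3
    knowledge_mode: str = "boost"
    resample_unit: str = "sample"


def integrate(
    data: np.ndarray,
    feature_names: list[str],
    feature_layers: dict[str, str],
    kg: KnowledgeGraph | None = None,
    options: NetworkOptions | None = None,
    pair_index: np.ndarray | None = None,
    seed: int = 0,
) -> ConsensusNetwork:
    """Full integration pipeline: bootstrap strengths -> knowledge
    modification -> significance threshold -> consensus network."""
    opts = options or NetworkOptions()
    raw = bootstrap_strengths(
        data,
        feature_names,
        B=opts.n_bootstrap,
        resample_unit=opts.resample_unit,
        pair_index=pair_index,
        max_parents=opts.max_parents,
        seed=seed,
    )
    if kg is not None and len(kg):
        mod = apply_knowledge(raw, kg, opts.knowledge_weight, opts.knowledge_mode)
    else:
        mod = dict(raw)
    thr, degenerate = scutari_threshold(list(mod.values()))
    net = consensus_network(mod, thr, feature_layers, strengths_raw=raw)
    net.degenerate_threshold = degenerate
    if degenerate:
        log.warning("degenerate strength distribution; empty significant set")
    return net
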