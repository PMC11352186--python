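"""Synthetic matched case-control multi-omics study generator.

Produces per-layer feature tables with planted differential effects,
internal standards, injection-order drift visible in interleaved pooled-QC
samples, intensity-dependent (MNAR) missingness, and a planted cross-layer
interaction network — together with the ground truth needed for
parameter-recovery tests.

All log quantities are base 2.  Signal model for a study sample s and
feature f (log2 scale, before drift and masking):

    x[f, s] = mu_f + t_s + pair[f, p(s)] + delta_f * 1{s is DEL case}
              + sum_e lambda_e * z[e, s] + eps[f, s]

where ``t_s`` is a per-sample technical factor (shared by every feature
including internal standards, so NOMIS can remove it), ``pair`` a random
effect shared by both members of a matched pair, ``delta_f`` the planted
signed group effect, and the ``z`` terms shared latent factors realizing
planted network edges.  Internal standards carry neither group nor pair
effects.  Pooled-QC samples are the average of the study samples'
pre-drift raw signals, placed at evenly spaced injection positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import KnowledgeGraph, MatchedDesign, OmicsDataset, ValidationError


@dataclass
class SimulationConfig:
    n_pairs: int = 15
    n_features: dict = field(default_factory=lambda: {"metabolite": 219, "lipid": 161, "protein": 100})
    n_differential: dict = field(default_factory=lambda: {"metabolite": 20, "lipid": 10, "protein": 8})
    effect_log2fc: float = 1.0
    effect_sd: float = 0.25
    base_log_mean: float = 16.0
    base_log_sd: float = 2.0
    drift_amplitude: float = 0.2
    n_qc: int = 10
    missing_rate: float = 0.05
    missing_mnar_strength: float = 1.0
    n_internal_standards: dict = field(default_factory=lambda: {"metabolite": 4, "lipid": 4, "protein": 0})
    network_edges: int = 20
    seed: int = 0
    # secondary knobs (see module docstring)
    pair_sd: float = 0.5
    noise_sd: float = 0.3
    tech_sd: float = 0.15
    qc_noise_log_sd: float = 0.02
    edge_coupling_range: tuple = (0.7, 1.6)

    def validate(self) -> None:
        for layer, nf in self.n_features.items():
            nd = self.n_differential.get(layer, 0)
            if nd > nf:
                raise ValidationError(f"n_differential > n_features for layer {layer!r}")
            if self.n_internal_standards.get(layer, 0) >= nf:
                raise ValidationError(f"too many internal standards for layer {layer!r}")
        if self.n_qc < 3:
            raise ValidationError("n_qc must be >= 3")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must be in [0,1]")
        if self.missing_mnar_strength < 0:
            raise ValidationError("missing_mnar_strength must be >= 0")
        if self.n_pairs < 2:
            raise ValidationError("n_pairs must be >= 2")
        if self.network_edges < 0:
            raise ValidationError("network_edges must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated study."""

    differential_features: dict  # feature_id -> planted signed log2 fold change
    drift_curve: dict  # layer -> array of drift multipliers indexed by injection order - 1
    missing_mask: dict  # layer -> boolean matrix (features x samples), True = masked
    planted_network: set  # canonical unordered feature-id pairs
    pair_effects: dict  # layer -> (n_features x n_pairs) matrix of log2 pair effects
    internal_standards: dict  # layer -> list of feature ids

    def __post_init__(self) -> None:
        is_all = {f for ids in self.internal_standards.values() for f in ids}
        if set(self.differential_features) & is_all:
            raise ValidationError("differential features overlap internal standards")
        for a, b in self.planted_network:
            if a == b:
                raise ValidationError("planted network contains a self-loop")


def drift_multiplier(order: np.ndarray, max_order: int, amplitude: float) -> np.ndarray:
    """Smooth monotone-plus-sinusoid drift: 1 + a*(o/O) + 0.3a*sin(2*pi*o/O)."""
    frac = np.asarray(order, dtype=float) / max_order
    return 1.0 + amplitude * frac + 0.3 * amplitude * np.sin(2 * np.pi * frac)


def _interleave_qc(n_study: int, n_qc: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign injection orders 1..n_study+n_qc with QC evenly spaced."""
    total = n_study + n_qc
    qc_pos = np.unique(np.round(np.linspace(1, total, n_qc)).astype(int))
    # resolve collisions from rounding by shifting duplicates
    while len(qc_pos) < n_qc:
        missing = sorted(set(range(1, total + 1)) - set(qc_pos))
        qc_pos = np.unique(np.append(qc_pos, missing[: n_qc - len(qc_pos)]))
    study_pos = np.array(sorted(set(range(1, total + 1)) - set(qc_pos)))
    return study_pos, qc_pos


def generate_study(
    config: SimulationConfig,
) -> tuple[dict[str, OmicsDataset], MatchedDesign, SyntheticTruth]:
    """Simulate one matched case-control study across all configured layers.

    Returns ``(datasets_by_layer, design, truth)``.  Identical seeds give
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layers = list(config.n_features)
    n_pairs = config.n_pairs
    n_study = 2 * n_pairs

    # shared sample-level structure
    pair_ids = [f"P{i + 1:03d}" for i in range(n_pairs)]
    case_ids = [f"DEL{i + 1:03d}" for i in range(n_pairs)]
    ctrl_ids = [f"CNT{i + 1:03d}" for i in range(n_pairs)]
    design = MatchedDesign(zip(case_ids, ctrl_ids))
    study_ids = [sid for pair in zip(case_ids, ctrl_ids) for sid in pair]
    tech = rng.normal(0.0, config.tech_sd, size=n_study)

    # feature bookkeeping per layer
    feature_ids: dict[str, list[str]] = {}
    prefix = {"metabolite": "M", "lipid": "L", "protein": "PR"}
    for layer in layers:
        p = prefix.get(layer, layer[:2].upper())
        feature_ids[layer] = [f"{p}{i + 1:04d}" for i in range(config.n_features[layer])]

    # choose internal standards, then differential features among the rest
    is_ids: dict[str, list[str]] = {}
    diff_effects: dict[str, float] = {}
    diff_idx: dict[str, np.ndarray] = {}
    for layer in layers:
        nf = config.n_features[layer]
        n_is = config.n_internal_standards.get(layer, 0)
        idx = rng.permutation(nf)
        is_sel = np.sort(idx[:n_is])
        is_ids[layer] = [feature_ids[layer][i] for i in is_sel]
        rest = np.sort(idx[n_is:])
        nd = config.n_differential.get(layer, 0)
        d_sel = np.sort(rng.choice(rest, size=nd, replace=False))
        diff_idx[layer] = d_sel
        signs = rng.choice([-1.0, 1.0], size=nd)
        mags = np.abs(rng.normal(config.effect_log2fc, config.effect_sd, size=nd))
        for i, s, m in zip(d_sel, signs, mags):
            diff_effects[feature_ids[layer][i]] = float(s * m)

    # planted cross-layer network: disjoint feature pairs, no IS, no overlap
    all_eligible = [
        (layer, i)
        for layer in layers
        for i in range(config.n_features[layer])
        if feature_ids[layer][i] not in is_ids[layer]
    ]
    rng.shuffle(all_eligible)
    n_edges = min(config.network_edges, len(all_eligible) // 2)
    edge_members = all_eligible[: 2 * n_edges]
    planted: set[tuple[str, str]] = set()
    couplings = rng.uniform(*config.edge_coupling_range, size=n_edges)
    edge_factor_study = rng.normal(0.0, 1.0, size=(n_edges, n_study))
    edge_assign: dict[tuple[str, int], tuple[int, float]] = {}
    for e in range(n_edges):
        (la, ia), (lb, ib) = edge_members[2 * e], edge_members[2 * e + 1]
        fa, fb = feature_ids[la][ia], feature_ids[lb][ib]
        planted.add(KnowledgeGraph.canonical(fa, fb))
        edge_assign[(la, ia)] = (e, couplings[e])
        edge_assign[(lb, ib)] = (e, couplings[e])

    noise_free = config.drift_amplitude == 0.0 and config.missing_rate == 0.0

    datasets: dict[str, OmicsDataset] = {}
    drift_curves: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    pair_effects: dict[str, np.ndarray] = {}

    for layer in layers:
        nf = config.n_features[layer]
        fids = feature_ids[layer]
        is_mask = np.array([f in set(is_ids[layer]) for f in fids])

        mu = rng.normal(config.base_log_mean, config.base_log_sd, size=nf)
        pair_eff = rng.normal(0.0, config.pair_sd, size=(nf, n_pairs))
        pair_eff[is_mask, :] = 0.0
        eps = rng.normal(0.0, config.noise_sd, size=(nf, n_study))
        eps[is_mask, :] *= 0.2  # standards are technically cleaner

        # log2 signal matrix for study samples (columns alternate case/ctrl)
        log2x = mu[:, None] + tech[None, :] + eps
        for p in range(n_pairs):
            log2x[:, 2 * p] += pair_eff[:, p]
            log2x[:, 2 * p + 1] += pair_eff[:, p]
        for i in diff_idx[layer]:
            delta = diff_effects[fids[i]]
            log2x[i, 0::2] += delta  # DEL members sit in even columns
        for i in range(nf):
            if (layer, i) in edge_assign:
                e, lam = edge_assign[(layer, i)]
                log2x[i, :] += lam * edge_factor_study[e, :]

        raw_study = np.exp2(log2x)

        # pooled QC = average of study samples' pre-drift raw signals
        qc_base = raw_study.mean(axis=1)
        study_pos, qc_pos = _interleave_qc(n_study, config.n_qc)
        max_order = n_study + config.n_qc
        drift = drift_multiplier(np.arange(1, max_order + 1), max_order, config.drift_amplitude)
        drift_curves[layer] = drift

        raw_qc = np.repeat(qc_base[:, None], config.n_qc, axis=1)
        if not noise_free:
            # technical QC noise: a per-injection factor shared by all
            # features (removable by IS normalization) plus a smaller
            # feature-independent part; standards get the clean version
            sd = config.qc_noise_log_sd / np.log(2.0)
            t_q = rng.normal(0.0, 0.8 * sd, size=config.n_qc)
            iid = rng.normal(0.0, 0.6 * sd, size=raw_qc.shape)
            iid[is_mask, :] *= 0.2
            raw_qc = raw_qc * np.exp2(t_q[None, :] + iid)

        mat = np.empty((nf, n_study + config.n_qc))
        mat[:, study_pos - 1] = raw_study * drift[study_pos - 1][None, :]
        mat[:, qc_pos - 1] = raw_qc * drift[qc_pos - 1][None, :]

        # MNAR masking: P(missing) = rate * logistic(-strength * z(log2 x))
        logx = np.log2(mat)
        z = (logx - logx.mean()) / (logx.std() + 1e-12)
        p_miss = config.missing_rate / (1.0 + np.exp(config.missing_mnar_strength * z))
        mask = rng.uniform(size=mat.shape) < p_miss
        mask[is_mask, :] = False  # keep standards complete for NOMIS
        mat_masked = mat.copy()
        mat_masked[mask] = np.nan
        masks[layer] = mask
        pair_effects[layer] = pair_eff

        # assemble metadata; columns ordered by injection position
        sample_ids = [""] * (n_study + config.n_qc)
        roles = [""] * len(sample_ids)
        groups = ["none"] * len(sample_ids)
        pids = [""] * len(sample_ids)
        for k, pos in enumerate(study_pos):
            sample_ids[pos - 1] = study_ids[k]
            roles[pos - 1] = "study"
            groups[pos - 1] = "DEL" if study_ids[k].startswith("DEL") else "CNT"
            pids[pos - 1] = pair_ids[k // 2]
        for k, pos in enumerate(qc_pos):
            sample_ids[pos - 1] = f"QC{k + 1:02d}"
            roles[pos - 1] = "pooled_qc"

        sm = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "role": roles,
                "group": groups,
                "pair_id": pids,
                "injection_order": np.arange(1, len(sample_ids) + 1),
            }
        )
        fm = pd.DataFrame(
            {
                "feature_id": fids,
                "layer": layer,
                "is_internal_standard": is_mask,
                "consolidation_key": "",
            }
        )
        datasets[layer] = OmicsDataset(intensities=mat_masked, feature_meta=fm, sample_meta=sm)

    truth = SyntheticTruth(
        differential_features=diff_effects,
        drift_curve=drift_curves,
        missing_mask=masks,
        planted_network=planted,
        pair_effects=pair_effects,
        internal_standards=is_ids,
    )
    return datasets, design, truth


def generate_knowledge_graph(
    truth: SyntheticTruth, recall: float, spurious_fraction: float, seed: int
) -> KnowledgeGraph:
    """Degrade the planted network into an external-knowledge edge list.

    Each planted edge is included independently with probability ``recall``;
    ``spurious_fraction * |planted|`` random non-planted pairs over the same
    node universe are added on top.  Deterministic under ``seed``.
    """
    if not 0.0 <= recall <= 1.0:
        raise ValidationError("recall must be in [0,1]")
    if spurious_fraction < 0:
        raise ValidationError("spurious_fraction must be >= 0")
    if not truth.planted_network:
        raise ValidationError("truth has no planted network")
    rng = np.random.default_rng(seed)
    kg = KnowledgeGraph()
    planted = sorted(truth.planted_network)
    for a, b in planted:
        if rng.uniform() < recall:
            kg.add(a, b, "planted")
    nodes = sorted({n for e in planted for n in e})
    n_spurious = int(round(spurious_fraction * len(planted)))
    added = 0
    while added < n_spurious:
        a, b = rng.choice(nodes, size=2, replace=False)
        edge = KnowledgeGraph.canonical(a, b)
        if edge in truth.planted_network or edge in kg.edges:
            continue
        kg.add(*edge, "spurious")
        added += 1
    return kg
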