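"""End-to-end orchestration shared by the CLI and tests.

Stages communicate through conventional file names inside one output
directory, so each CLI subcommand can also be run standalone on the files
a previous stage produced.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig
from .datamodel import MatchedDesign, OmicsDataset
from .diffstats import differential_table, records_to_frame, DifferentialRecord
from .evaluate import best_kernel_eval, cluster_eval, pca_svm_l1o, upgma_cluster
from .network import integrate
from .preprocess import preprocess_pipeline
from .signature import SignatureSet, elastic_net_stability, fc_threshold_select
from .synthetic import generate_knowledge_graph, generate_study

log = logging.getLogger(__name__)

LAYER_FILES = {
    "metabolite": "metabolites",
    "lipid": "lipids",
    "protein": "proteins",
}


def _layer_paths(out_dir: Path, layer: str, suffix: str = "") -> tuple[Path, Path, Path]:
    stem = LAYER_FILES.get(layer, layer) + suffix
    return (
        out_dir / f"{stem}.tsv",
        out_dir / f"{stem}.features.tsv",
        out_dir / f"{stem}.samples.tsv",
    )


def simulate_stage(cfg: RunConfig, out_dir: Path, seed: int | None = None) -> None:
    sim = cfg.simulate
    if seed is not None:
        sim.seed = seed
    datasets, design, truth = generate_study(sim)
    pio.ensure_dir(out_dir)
    for layer, ds in datasets.items():
        pio.write_omics_table(ds, *_layer_paths(out_dir, layer))
    pio.write_design(design, out_dir / "design.tsv")
    kg = generate_knowledge_graph(truth, recall=0.8, spurious_fraction=0.5, seed=sim.seed + 1)
    pio.write_knowledge_graph(kg, out_dir / "knowledge.tsv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "differential_features": truth.differential_features,
                "planted_network": sorted(map(list, truth.planted_network)),
                "internal_standards": truth.internal_standards,
                "drift_curve": {k: list(v) for k, v in truth.drift_curve.items()},
            },
            fh,
            indent=1,
        )


def preprocess_stage(cfg: RunConfig, out_dir: Path, seed: int = 0) -> dict[str, OmicsDataset]:
    design = pio.read_design(out_dir / "design.tsv")
    processed = {}
    for layer in LAYER_FILES:
        paths = _layer_paths(out_dir, layer)
        if not paths[0].exists():
            continue
        ds = pio.read_omics_table(*paths)
        if layer == "protein":
            # vendor-normalized proteomics bypasses the LC-MS chain
            processed[layer] = ds
        else:
            ds_p, report = preprocess_pipeline(ds, design, cfg.preprocess, seed=seed)
            processed[layer] = ds_p
            report.cv_table().to_csv(out_dir / f"{LAYER_FILES[layer]}.qc_cv.tsv", sep="\t")
        pio.write_omics_table(processed[layer], *_layer_paths(out_dir, layer, ".processed"))
    return processed


def _load_processed(out_dir: Path) -> dict[str, OmicsDataset]:
    out = {}
    for layer in LAYER_FILES:
        paths = _layer_paths(out_dir, layer, ".processed")
        if paths[0].exists():
            out[layer] = pio.read_omics_table(*paths)
    return out


def diff_stage(cfg: RunConfig, out_dir: Path) -> list[DifferentialRecord]:
    design = pio.read_design(out_dir / "design.tsv")
    records: list[DifferentialRecord] = []
    for layer, ds in _load_processed(out_dir).items():
        records.extend(differential_table(ds, design, alpha=cfg.diff.alpha))
    df = records_to_frame(records).sort_values("tfc", ascending=False)
    df.to_csv(out_dir / "differential.tsv", sep="\t", index=False, float_format="%.6g")
    return records


def _combined_dataset(out_dir: Path, feature_ids: list[str]) -> OmicsDataset:
    """Stack processed layers restricted to study samples common to all."""
    processed = _load_processed(out_dir)
    common = None
    for ds in processed.values():
        ids = set(np.array(ds.sample_ids)[ds.study_mask()])
        common = ids if common is None else common & ids
    common = sorted(common)
    mats, fms = [], []
    sm = None
    for ds in processed.values():
        idx = [ds.sample_index(s) for s in common]
        sub = ds.subset_samples(idx)
        keep = [i for i, f in enumerate(sub.feature_ids) if f in set(feature_ids)]
        sub = sub.subset_features(keep)
        mats.append(sub.intensities)
        fms.append(sub.feature_meta)
        sm = sub.sample_meta
    return OmicsDataset(
        intensities=np.vstack(mats),
        feature_meta=pd.concat(fms, ignore_index=True),
        sample_meta=sm,
    )


def signature_stage(cfg: RunConfig, out_dir: Path, seed: int = 0) -> tuple[SignatureSet, SignatureSet]:
    df = pd.read_csv(out_dir / "differential.tsv", sep="\t")
    records = [DifferentialRecord(**row) for row in df.to_dict("records")]
    sig = fc_threshold_select(records, cutoff=cfg.signature.fc_cutoff)
    combined = _combined_dataset(out_dir, sig.feature_ids)
    design = pio.read_design(out_dir / "design.tsv")
    present = set(combined.sample_ids)
    design = MatchedDesign(
        [(c, t) for c, t in design.pairs if c in present and t in present]
    )
    refined = elastic_net_stability(
        combined,
        design,
        sig,
        alpha_mix=cfg.signature.alpha_mix,
        n_lambda=cfg.signature.n_lambda,
        cv_folds=cfg.signature.cv_folds,
        seed=seed,
    )
    rows = [
        {
            "feature_id": fid,
            "layer": sig.layers[fid],
            "inclusion_count": refined.inclusion_counts.get(fid, 0),
            "n_models": refined.n_models,
            "in_threshold_signature": True,
            "in_refined_signature": fid in refined.feature_ids,
        }
        for fid in sig.feature_ids
    ]
    pd.DataFrame(rows).to_csv(out_dir / "signature.tsv", sep="\t", index=False)
    return sig, refined


def evaluate_stage(cfg: RunConfig, out_dir: Path, seed: int = 0) -> dict:
    sig_df = pd.read_csv(out_dir / "signature.tsv", sep="\t")
    results = {}
    for name, fids in (
        ("threshold", list(sig_df["feature_id"])),
        ("refined", list(sig_df.loc[sig_df["in_refined_signature"], "feature_id"])),
    ):
        if len(fids) < 2:
            continue
        combined = _combined_dataset(out_dir, fids)
        labels = dict(zip(combined.sample_ids, combined.sample_meta["group"]))
        _, cut = upgma_cluster(combined, fids)
        ce = cluster_eval(cut, labels)
        if cfg.evaluate.kernel == "best":
            ev = best_kernel_eval(
                combined, fids, labels, cfg.evaluate.n_components, cfg.evaluate.pca_scope, seed
            )
        else:
            ev = pca_svm_l1o(
                combined, fids, labels, cfg.evaluate.kernel,
                cfg.evaluate.n_components, cfg.evaluate.pca_scope, seed,
            )
        results[name] = {
            "n_features": len(fids),
            "misclustered": ce.misclustered_count,
            "fisher_p": ce.fisher_p,
            "l1o_accuracy": ev.l1o_accuracy,
            "auc": ev.auc,
            "auc_ci": list(ev.auc_ci),
            "kernel": ev.kernel,
        }
    with open(out_dir / "evaluation.json", "w") as fh:
        json.dump(results, fh, indent=1)
    return results


def network_stage(cfg: RunConfig, out_dir: Path, seed: int = 0) -> None:
    df = pd.read_csv(out_dir / "differential.tsv", sep="\t")
    fids = list(df.loc[df["significant"], "feature_id"])
    combined = _combined_dataset(out_dir, fids)
    X = np.log2(combined.intensities.T)
    X = (X - X.mean(axis=0)) / (X.std(axis=0) + 1e-12)
    layers = dict(zip(combined.feature_ids, combined.feature_meta["layer"]))
    kg_path = out_dir / "knowledge.tsv"
    kg = pio.read_knowledge_graph(kg_path) if kg_path.exists() else None
    net = integrate(
        X, combined.feature_ids, layers, kg=kg, options=cfg.network, seed=seed
    )
    pio.write_network(net, out_dir / "network.graphml", "graphml")
    pio.write_network(net, out_dir / "network.sif", "sif")
    pio.write_network(net, out_dir / "network.tsv", "tsv")
    comp_rows = [
        {"component": i + 1, "size": len(c), "members": ";".join(c),
         "n_layers": len({layers.get(m, "") for m in c})}
        for i, c in enumerate(net.subnetworks)
    ]
    pd.DataFrame(comp_rows).to_csv(out_dir / "network.components.tsv", sep="\t", index=False)


def run_all(cfg: RunConfig, out_dir: Path, seed: int = 0) -> None:
    out_dir = Path(out_dir)
    simulate_stage(cfg, out_dir, seed=seed)
    preprocess_stage(cfg, out_dir, seed=seed)
    diff_stage(cfg, out_dir)
    signature_stage(cfg, out_dir, seed=seed)
    evaluate_stage(cfg, out_dir, seed=seed)
    network_stage(cfg, out_dir, seed=seed)
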