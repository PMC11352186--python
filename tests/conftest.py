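import numpy as np
import pandas as pd
import pytest

from pairomics.datamodel import MatchedDesign, OmicsDataset


def build_dataset(
    intensities,
    feature_ids=None,
    sample_ids=None,
    layer="metabolite",
    groups=None,
    roles=None,
    pair_ids=None,
    is_internal_standard=None,
    consolidation_keys=None,
    injection_order=None,
):
    """Construct a small OmicsDataset with sensible metadata defaults."""
    X = np.asarray(intensities, dtype=float)
    nf, ns = X.shape
    feature_ids = feature_ids or [f"F{i}" for i in range(nf)]
    sample_ids = sample_ids or [f"S{i}" for i in range(ns)]
    roles = roles or ["study"] * ns
    if groups is None:
        groups = ["DEL" if i % 2 == 0 else "CNT" for i in range(ns)]
        groups = [g if r == "study" else "none" for g, r in zip(groups, roles)]
    if pair_ids is None:
        pair_ids = [f"P{i // 2}" if r == "study" else "" for i, r in enumerate(roles)]
    fm = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "layer": [layer] * nf if isinstance(layer, str) else layer,
            "is_internal_standard": is_internal_standard or [False] * nf,
            "consolidation_key": consolidation_keys or [""] * nf,
        }
    )
    sm = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "role": roles,
            "group": groups,
            "pair_id": pair_ids,
            "injection_order": injection_order or list(range(1, ns + 1)),
        }
    )
    return OmicsDataset(intensities=X, feature_meta=fm, sample_meta=sm)


def paired_design(ds: OmicsDataset) -> MatchedDesign:
    """Pair up DEL/CNT study samples sharing a pair_id."""
    sm = ds.sample_meta
    pairs = {}
    for _, row in sm.iterrows():
        if row["role"] != "study" or not row["pair_id"]:
            continue
        pairs.setdefault(row["pair_id"], {})[row["group"]] = row["sample_id"]
    return MatchedDesign(
        [(v["DEL"], v["CNT"]) for v in pairs.values() if "DEL" in v and "CNT" in v]
    )


@pytest.fixture
def toy_dataset():
    """4 features x 6 study samples (3 pairs), no missing values."""
    rng = np.random.default_rng(42)
    return build_dataset(np.exp2(rng.normal(16, 1, size=(4, 6))))


@pytest.fixture
def toy_design(toy_dataset):
    return paired_design(toy_dataset)
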