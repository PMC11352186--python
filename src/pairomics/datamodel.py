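"""Shared data model for matched-pair multi-omics analysis.

The central object is :class:`OmicsDataset`, a feature-by-sample intensity
matrix with feature and sample metadata.  Every pipeline stage consumes and
returns validated datasets; :class:`MatchedDesign` carries the case/control
pairing that drives all paired statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LAYERS = ("metabolite", "lipid", "protein")
ROLES = ("study", "pooled_qc")
GROUPS = ("DEL", "CNT", "none")

#: feature-metadata columns required by the validator
FEATURE_META_COLS = ("feature_id", "layer", "is_internal_standard", "consolidation_key")
#: sample-metadata columns required by the validator
SAMPLE_META_COLS = ("sample_id", "role", "group", "pair_id", "injection_order")


class ValidationError(ValueError):
    """Raised when a dataset or design violates a structural invariant."""


@dataclass
class OmicsDataset:
    """Feature-by-sample intensity matrix with metadata.

    Parameters
    ----------
    intensities
        2-D float array, rows = features, columns = samples.  Missing
        values are ``NaN``; all non-missing values must be >= 0 (raw scale).
    feature_meta
        DataFrame indexed like the rows, with columns ``feature_id``,
        ``layer``, ``is_internal_standard``, ``consolidation_key``.
    sample_meta
        DataFrame indexed like the columns, with columns ``sample_id``,
        ``role``, ``group``, ``pair_id``, ``injection_order``.
    """

    intensities: np.ndarray
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.feature_meta = self.feature_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        validate_dataset(self)

    # -- convenience accessors -------------------------------------------
    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.feature_meta["feature_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta["sample_id"])

    def feature_index(self, feature_id: str) -> int:
        idx = self.feature_meta.index[self.feature_meta["feature_id"] == feature_id]
        if len(idx) == 0:
            raise KeyError(f"unknown feature id {feature_id!r}")
        return int(idx[0])

    def sample_index(self, sample_id: str) -> int:
        idx = self.sample_meta.index[self.sample_meta["sample_id"] == sample_id]
        if len(idx) == 0:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return int(idx[0])

    def qc_mask(self) -> np.ndarray:
        return (self.sample_meta["role"] == "pooled_qc").to_numpy()

    def study_mask(self) -> np.ndarray:
        return (self.sample_meta["role"] == "study").to_numpy()

    def subset_features(self, keep: Sequence[int] | np.ndarray) -> "OmicsDataset":
        keep = np.asarray(keep)
        return OmicsDataset(
            intensities=self.intensities[keep, :].copy(),
            feature_meta=self.feature_meta.iloc[keep].reset_index(drop=True),
            sample_meta=self.sample_meta.copy(),
        )

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "OmicsDataset":
        keep = np.asarray(keep)
        return OmicsDataset(
            intensities=self.intensities[:, keep].copy(),
            feature_meta=self.feature_meta.copy(),
            sample_meta=self.sample_meta.iloc[keep].reset_index(drop=True),
        )

    def copy(self) -> "OmicsDataset":
        return OmicsDataset(
            intensities=self.intensities.copy(),
            feature_meta=self.feature_meta.copy(),
            sample_meta=self.sample_meta.copy(),
        )


def validate_dataset(ds: OmicsDataset) -> None:
    """Check all :class:`OmicsDataset` invariants, raising ``ValidationError``.

    Run by every pipeline stage on entry; errors carry row/column context.
    """
    fm, sm = ds.feature_meta, ds.sample_meta
    for col in FEATURE_META_COLS:
        if col not in fm.columns:
            raise ValidationError(f"feature metadata missing column {col!r}")
    for col in SAMPLE_META_COLS:
        if col not in sm.columns:
            raise ValidationError(f"sample metadata missing column {col!r}")
    if ds.intensities.ndim != 2:
        raise ValidationError("intensity matrix must be 2-D")
    if ds.intensities.shape != (len(fm), len(sm)):
        raise ValidationError(
            f"shape mismatch: intensities {ds.intensities.shape} vs "
            f"{len(fm)} features x {len(sm)} samples"
        )

    dup_f = fm["feature_id"][fm["feature_id"].duplicated()]
    if len(dup_f):
        raise ValidationError(f"duplicate feature id(s): {sorted(set(dup_f))}")
    dup_s = sm["sample_id"][sm["sample_id"].duplicated()]
    if len(dup_s):
        raise ValidationError(f"duplicate sample id(s): {sorted(set(dup_s))}")

    bad_layer = set(fm["layer"]) - set(LAYERS)
    if bad_layer:
        raise ValidationError(f"unknown layer value(s): {sorted(bad_layer)}")
    bad_role = set(sm["role"]) - set(ROLES)
    if bad_role:
        raise ValidationError(f"unknown sample role(s): {sorted(bad_role)}")
    bad_group = set(sm["group"]) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"unknown group value(s): {sorted(bad_group)}")

    qc = sm[sm["role"] == "pooled_qc"]
    bad_qc = qc[(qc["group"] != "none") | (qc["pair_id"] != "")]
    if len(bad_qc):
        raise ValidationError(
            "pooled_qc samples must have group='none' and empty pair_id; "
            f"violated by {list(bad_qc['sample_id'])}"
        )

    orders = sm["injection_order"]
    if not np.issubdtype(orders.dtype, np.integer):
        if not np.all(orders == orders.astype(int)):
            raise ValidationError("injection_order must be integer-valued")
    if (orders < 1).any():
        bad = list(sm.loc[orders < 1, "sample_id"])
        raise ValidationError(f"injection_order must be >= 1; violated by {bad}")
    if orders.duplicated().any():
        dup = sorted(set(orders[orders.duplicated()]))
        raise ValidationError(f"duplicate injection order(s): {dup}")

    with np.errstate(invalid="ignore"):
        neg = np.nan_to_num(ds.intensities, nan=0.0) < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"negative intensity at feature {fm['feature_id'].iloc[i]!r}, "
            f"sample {sm['sample_id'].iloc[j]!r}"
        )


@dataclass(frozen=True)
class MatchedDesign:
    """Ordered list of (case sample id, control sample id) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        object.__setattr__(self, "pairs", tuple((str(a), str(b)) for a, b in pairs))
        seen: set[str] = set()
        for case, ctrl in self.pairs:
            for sid in (case, ctrl):
                if sid in seen:
                    raise ValidationError(f"sample {sid!r} appears in more than one pair")
                seen.add(sid)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def case_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    def control_ids(self) -> list[str]:
        return [p[1] for p in self.pairs]

    def validate_against(self, ds: OmicsDataset) -> None:
        """Check ids exist in ``ds`` and carry the expected group labels."""
        sm = ds.sample_meta.set_index("sample_id")
        for case, ctrl in self.pairs:
            for sid, want in ((case, "DEL"), (ctrl, "CNT")):
                if sid not in sm.index:
                    raise ValidationError(f"design references unknown sample {sid!r}")
                got = sm.loc[sid, "group"]
                if got != want:
                    raise ValidationError(
                        f"sample {sid!r} has group {got!r}, expected {want!r}"
                    )


@dataclass
class KnowledgeGraph:
    """Externally curated molecule-molecule interaction edges.

    Edges are unordered feature-id pairs, stored in canonical (sorted)
    order, each with a free-text source tag.  Self-loops are rejected.
    """

    edges: dict[tuple[str, str], str] = field(default_factory=dict)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, source: str = "") -> None:
        if a == b:
            raise ValidationError(f"self-loop on {a!r} not allowed")
        self.edges[self.canonical(a, b)] = source

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return self.canonical(*edge) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], source: str = "") -> "KnowledgeGraph":
        kg = cls()
        for a, b in pairs:
            kg.add(a, b, source)
        return kg


@dataclass
class ConsensusNetwork:
    """Undirected consensus interaction network with edge strengths.

    ``nodes`` maps feature id -> layer.  ``edges`` maps a canonical
    unordered pair -> (strength_raw, strength_modified).  ``threshold`` is
    the estimated significance cutoff; ``subnetworks`` the connected
    components with >= 2 nodes, largest first.
    """

    nodes: dict[str, str]
    edges: dict[tuple[str, str], tuple[float, float]]
    threshold: float
    subnetworks: list[list[str]] = field(default_factory=list)
    degenerate_threshold: bool = False

    def __post_init__(self) -> None:
        for (a, b), (raw, mod) in self.edges.items():
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if not (0.0 <= raw <= 1.0 and 0.0 <= mod <= 1.0):
                raise ValidationError(f"strengths out of [0,1] on edge {(a, b)}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


__all__ = [
    "OmicsDataset",
    "MatchedDesign",
    "KnowledgeGraph",
    "ConsensusNetwork",
    "ValidationError",
    "validate_dataset",
    "LAYERS",
    "ROLES",
    "GROUPS",
    "FEATURE_META_COLS",
    "SAMPLE_META_COLS",
    "replace",
]
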