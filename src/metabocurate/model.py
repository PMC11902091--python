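"""Core data model for the plasma-metabolome pipeline.

The containers here mirror what an untargeted LC-MS feature-alignment export
carries: a feature (peak) annotation block, a run design describing which
injection belongs to which animal / timepoint / replicate, and the raw
features x runs intensity matrix.  Missing intensities are genuine
non-detections (``NaN``), never zero: the curation stage later imputes them
at half the per-metabolite limit of detection.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

#: Allowed run groups: three plasma timepoints, the supplement extract, and
#: extraction blanks.
GROUPS = ("basal", "day4", "day7", "cse", "blank")

#: Node types of the layered metabolic knowledge graph.
NODE_TYPES = ("pathway", "module", "enzyme", "reaction", "compound")


class ValidationError(ValueError):
    """Raised when a table or design violates a structural invariant."""


@dataclass(frozen=True)
class RunDesign:
    """A single injection: which subject, which timepoint, which replicate."""

    run_id: str
    subject_id: str
    group: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"run {self.run_id!r}: unknown group {self.group!r} (expected one of {GROUPS})"
            )
        if self.group != "blank" and not self.subject_id:
            raise ValidationError(f"non-blank run {self.run_id!r} must have a subject_id")
        if self.replicate < 1:
            raise ValidationError(f"run {self.run_id!r}: replicate must be >= 1")


@dataclass
class FeatureAnnotation:
    """Annotation attached to one aligned LC-MS feature.

    ``identity_key`` is the InChIKey when present, else the (name, adduct)
    pair; features sharing a key are treated as adducts/duplicates of the
    same metabolite and merged during curation.
    """

    feature_id: str
    name: str = ""
    chemical_family: str = ""
    rt_min: float = math.nan
    formula: str = ""
    adduct: str = ""
    observed_mz: float = math.nan
    calculated_mz: float = math.nan
    error_ppm: float = math.nan
    inchikey: str = ""
    kegg_id: str = ""
    hmdb_id: str = ""
    pubchem_cid: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.rt_min) and self.rt_min < 0:
            raise ValidationError(f"feature {self.feature_id!r}: rt_min must be >= 0")
        if not math.isnan(self.observed_mz) and self.observed_mz <= 0:
            raise ValidationError(f"feature {self.feature_id!r}: observed_mz must be > 0")

    @property
    def identity_key(self):
        if self.inchikey:
            return self.inchikey
        return (self.name, self.adduct)

    @property
    def is_identified(self) -> bool:
        """A feature counts as library-identified when it has a name and a usable identity key."""
        return bool(self.name) and (bool(self.inchikey) or bool(self.name))


ANNOTATION_COLUMNS = [f.name for f in dataclasses.fields(FeatureAnnotation)]


@dataclass
class PeakTable:
    """Aligned peak table: features x runs, ``NaN`` marking non-detection."""

    features: list[FeatureAnnotation]
    runs: list[RunDesign]
    intensity: pd.DataFrame  # index: feature_id, columns: run_id

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fids = [f.feature_id for f in self.features]
        if len(set(fids)) != len(fids):
            dup = sorted({x for x in fids if fids.count(x) > 1})
            raise ValidationError(f"duplicate feature_id(s): {dup}")
        rids = [r.run_id for r in self.runs]
        if len(set(rids)) != len(rids):
            raise ValidationError("run_ids are not unique")
        if list(self.intensity.index) != fids or list(self.intensity.columns) != rids:
            raise ValidationError("intensity matrix index/columns do not match feature/run lists")
        vals = self.intensity.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("intensities must be >= 0 where present")
        # replicates per (subject, group) consecutive from 1
        per_sample: dict[tuple[str, str], list[int]] = {}
        for r in self.runs:
            per_sample.setdefault((r.subject_id, r.group), []).append(r.replicate)
        for key, reps in per_sample.items():
            if sorted(reps) != list(range(1, len(reps) + 1)):
                raise ValidationError(
                    f"replicates for sample {key} must be consecutive from 1, got {sorted(reps)}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.intensity.columns)

    def annotation(self, feature_id: str) -> FeatureAnnotation:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def runs_in_group(self, group: str) -> list[RunDesign]:
        return [r for r in self.runs if r.group == group]

    def subset_features(self, keep: Iterable[str]) -> "PeakTable":
        keep = list(keep)
        keep_set = set(keep)
        feats = [f for f in self.features if f.feature_id in keep_set]
        order = [f.feature_id for f in feats]
        return PeakTable(feats, list(self.runs), self.intensity.loc[order])

    def copy(self) -> "PeakTable":
        return PeakTable(list(self.features), list(self.runs), self.intensity.copy())


@dataclass
class CuratedMatrix:
    """Metabolites x samples matrix after curation.

    ``values`` has no missing cells; ``imputed`` flags the cells that were
    filled at half the limit of detection (``lld``).  ``samples`` are
    (subject, group) pairs, one column per pair, keyed ``subject:group``.
    """

    metabolites: list[FeatureAnnotation]
    samples: list[tuple[str, str]]
    values: pd.DataFrame
    lld: pd.Series
    imputed: pd.DataFrame
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("curated matrix must have no missing values")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    def columns_for_group(self, group: str) -> list[str]:
        return [f"{s}:{g}" for s, g in self.samples if g == group]

    def subjects_for_group(self, group: str) -> list[str]:
        return [s for s, g in self.samples if g == group]

    def annotation(self, metabolite_id: str) -> FeatureAnnotation:
        for f in self.metabolites:
            if f.feature_id == metabolite_id:
                return f
        raise KeyError(metabolite_id)


def sample_column(subject_id: str, group: str) -> str:
    return f"{subject_id}:{group}"


@dataclass
class Pathway:
    pathway_id: str
    name: str
    members: frozenset[str]
    graph: Optional[nx.Graph] = None  # optional internal topology


@dataclass
class PathwayLibrary:
    """Compound-set library with per-pathway relative-betweenness importances."""

    pathways: dict[str, Pathway]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways.values():
            out |= p.members
        return frozenset(out)


@dataclass
class KnowledgeGraph:
    """Undirected, typed, layered metabolic graph (pathway/module/enzyme/reaction/compound)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            t = data.get("node_type")
            if t not in NODE_TYPES:
                raise ValidationError(f"node {node!r}: unknown node type {t!r}")

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type)

    @property
    def compounds(self) -> list[str]:
        return self.nodes_of_type("compound")

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)
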