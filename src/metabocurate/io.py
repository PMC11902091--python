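"""Readers and writers for the delimited formats the pipeline consumes.

One canonical dialect is used throughout: TSV (CSV accepted by sniffing the
delimiter), decimal point only, empty cell = non-detection.  Numeric fields
accept the typographic minus sign "−" as "-", since published tables often
use it.  A thin shim handles MS-DIAL-style alignment exports whose leading
header rows are skipped by count.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    ANNOTATION_COLUMNS,
    FeatureAnnotation,
    KnowledgeGraph,
    Pathway,
    PathwayLibrary,
    PeakTable,
    RunDesign,
    ValidationError,
)

PathLike = Union[str, Path]

_NUMERIC_ANNOTATIONS = {"rt_min", "observed_mz", "calculated_mz", "error_ppm"}


def parse_number(text) -> float:
    """Parse a decimal number, accepting the Unicode minus sign; empty -> NaN."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return math.nan
    s = str(text).strip().replace("−", "-")
    if not s:
        return math.nan
    return float(s)


def _sniff_sep(path: PathLike) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_design(path: PathLike) -> list[RunDesign]:
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str).fillna("")
    required = {"run_id", "subject_id", "group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"run design {path}: missing column(s) {sorted(missing)}")
    return [
        RunDesign(row.run_id, row.subject_id, row.group, int(row.replicate))
        for row in df.itertuples()
    ]


def write_design(runs: list[RunDesign], path: PathLike) -> None:
    pd.DataFrame(
        {
            "run_id": [r.run_id for r in runs],
            "subject_id": [r.subject_id for r in runs],
            "group": [r.group for r in runs],
            "replicate": [r.replicate for r in runs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_peak_table(path: PathLike, design_path: PathLike, skip_rows: int = 0) -> PeakTable:
    """Read a feature-alignment export plus its run design.

    The first column must be ``feature_id``; annotation columns are
    recognised by name; every remaining column must be a ``run_id`` declared
    in the design.  ``skip_rows`` skips MS-DIAL-style preamble rows.
    """
    runs = read_design(design_path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, skiprows=skip_rows)
    if df.columns[0] != "feature_id":
        raise ValidationError(f"{path}: first column must be 'feature_id', got {df.columns[0]!r}")
    df = df.set_index("feature_id")
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"{path}: duplicate feature_id(s): {dup}")

    run_ids = [r.run_id for r in runs]
    ann_cols = [c for c in df.columns if c in ANNOTATION_COLUMNS]
    run_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    unknown = [c for c in run_cols if c not in run_ids]
    if unknown:
        raise ValidationError(f"{path}: intensity column(s) not in run design: {unknown}")
    absent = [r for r in run_ids if r not in run_cols]
    if absent:
        raise ValidationError(f"design references run(s) absent from the table: {absent}")

    features = []
    for fid in df.index:
        kwargs = {}
        for col in ann_cols:
            raw = df.at[fid, col]
            if col in _NUMERIC_ANNOTATIONS:
                kwargs[col] = parse_number(raw)
            else:
                kwargs[col] = "" if pd.isna(raw) else str(raw)
        features.append(FeatureAnnotation(feature_id=str(fid), **kwargs))

    intensity = df[run_ids].map(parse_number).astype(float)
    return PeakTable(features, runs, intensity)


def write_peak_table(table: PeakTable, path: PathLike, design_path: Optional[PathLike] = None) -> None:
    """Write a peak table; missing intensities become empty cells, not zeros."""
    ann = pd.DataFrame(
        {
            col: [getattr(f, col) for f in table.features]
            for col in ANNOTATION_COLUMNS
            if col != "feature_id"
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    # drop annotation columns that are entirely empty/NaN to keep exports lean
    keep = [
        c
        for c in ann.columns
        if not (
            ann[c].map(lambda v: v == "" or (isinstance(v, float) and math.isnan(v))).all()
        )
    ]
    out = pd.concat([ann[keep], table.intensity], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", index=True, float_format="%.10g")
    if design_path is not None:
        write_design(table.runs, design_path)


def read_msdial_export(path: PathLike, design_path: PathLike, header_rows: int = 4) -> PeakTable:
    """Shim for MS-DIAL alignment exports: skip the preamble rows, then parse canonically."""
    return read_peak_table(path, design_path, skip_rows=header_rows)


def read_pathway_sets(path: PathLike) -> PathwayLibrary:
    """Read a GMT-style pathway file: id, description, then member compound ids."""
    pathways: dict[str, Pathway] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields (id, description, members)"
                )
            pid, desc, *members = fields
            members = [m for m in members if m.strip()]
            pathways[pid] = Pathway(pid, desc, frozenset(members))
    if not pathways:
        raise ValidationError(f"{path}: no pathways")
    return PathwayLibrary(pathways)


def read_graph(nodes_path: PathLike, edges_path: PathLike) -> KnowledgeGraph:
    """Read a typed node table + edge list into an undirected knowledge graph.

    Isolated declared nodes are retained; edges touching undeclared nodes
    are an error.
    """
    nodes = pd.read_csv(nodes_path, sep=_sniff_sep(nodes_path), dtype=str)
    if list(nodes.columns[:2]) != ["node_id", "node_type"]:
        raise ValidationError(f"{nodes_path}: expected columns node_id, node_type")
    g = nx.Graph()
    for row in nodes.itertuples():
        g.add_node(row.node_id, node_type=row.node_type)
    edges = pd.read_csv(edges_path, sep=_sniff_sep(edges_path), dtype=str)
    for row in edges.itertuples():
        s, t = row[1], row[2]
        for n in (s, t):
            if n not in g:
                raise ValidationError(f"{edges_path}: edge references undeclared node {n!r}")
        g.add_edge(s, t)
    return KnowledgeGraph(g)


def write_curated(cm, path: PathLike) -> None:
    """Write a curated matrix with annotations, LLD, and per-cell values."""
    from .model import CuratedMatrix  # local to avoid import noise

    assert isinstance(cm, CuratedMatrix)
    ann = pd.DataFrame(
        {
            "name": [m.name for m in cm.metabolites],
            "chemical_family": [m.chemical_family for m in cm.metabolites],
            "inchikey": [m.inchikey for m in cm.metabolites],
            "lld": [cm.lld[m.feature_id] for m in cm.metabolites],
        },
        index=pd.Index(cm.metabolite_ids, name="feature_id"),
    )
    pd.concat([ann, cm.values], axis=1).to_csv(path, sep="\t", float_format="%.10g")


def load_fixture_frame(name: str) -> pd.DataFrame:
    """Load a packaged TSV fixture as a DataFrame, numbers parsed leniently."""
    from importlib.resources import files

    src = files("metabocurate.fixtures").joinpath(name)
    with src.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in df.columns:
        try:
            parsed = df[col].map(parse_number)
        except ValueError:
            continue
        if not parsed.isna().all():
            df[col] = parsed
    return df


def fixture_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("metabocurate.fixtures").joinpath(name)))
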