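"""Shared builders for tiny hand-constructed peak tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from metabocurate.model import FeatureAnnotation, PeakTable, RunDesign


def runs_spec(spec: list[tuple]) -> list[RunDesign]:
    """Each entry: (run_id, subject, group, replicate)."""
    return [RunDesign(*entry) for entry in spec]


def tiny_table(values: dict[str, list], runs: list[RunDesign], annotations: dict | None = None) -> PeakTable:
    """Build a PeakTable from {feature_id: row values} (None = missing)."""
    annotations = annotations or {}
    feats = []
    for fid in values:
        kw = annotations.get(fid, {})
        kw.setdefault("name", fid)
        kw.setdefault("inchikey", f"IK-{fid}")
        feats.append(FeatureAnnotation(feature_id=fid, **kw))
    data = pd.DataFrame(
        {r.run_id: [np.nan if v is None else float(v) for v in col] for r, col in
         zip(runs, zip(*values.values()))},
        index=pd.Index(list(values), name="feature_id"),
    )
    return PeakTable(feats, runs, data)


def replicate_runs(subjects: list[str], groups: list[str], n_rep: int = 1) -> list[RunDesign]:
    """Group-major run order; collapsed-style ids ("s:g") when n_rep == 1."""
    return [
        RunDesign(f"{s}:{g}" if n_rep == 1 else f"{s}_{g}_r{r}", s, g, r)
        for g in groups
        for s in subjects
        for r in range(1, n_rep + 1)
    ]


def blank_runs(n: int = 2) -> list[RunDesign]:
    return [RunDesign(f"blk_r{r}", "", "blank", r) for r in range(1, n + 1)]
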