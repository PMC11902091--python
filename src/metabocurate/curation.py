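"""Post-processing of aligned peak tables.

The chain, in order: collapse triplicate injections to per-sample medians;
drop features whose maximum sample height is less than k times their mean
extraction-blank height; drop features never reaching a minimum height;
drop unidentified features; drop features not detected in at least n_min
samples of any one timepoint; impute remaining non-detections at half the
per-metabolite limit of detection; merge adducts/duplicates that share an
identity key.

All three thresholds remove on strict "less than", so equality retains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CuratedMatrix,
    FeatureAnnotation,
    PeakTable,
    RunDesign,
    ValidationError,
    sample_column,
)


@dataclass
class CurationConfig:
    blank_multiplier: float = 3.0  # k: sample max must reach k x mean blank height
    min_intensity: float = 1000.0  # counts
    min_prevalence: int = 3  # detections required in at least one group
    require_identified: bool = True

    def __post_init__(self) -> None:
        if self.blank_multiplier < 0:
            raise ValidationError("blank_multiplier must be >= 0")
        if self.min_intensity < 0:
            raise ValidationError("min_intensity must be >= 0")
        if self.min_prevalence < 1:
            raise ValidationError("min_prevalence must be >= 1")


def collapse_replicates(table: PeakTable) -> PeakTable:
    """Collapse replicate injections: one column per (subject, group), cell = median of detected replicates."""
    groups: dict[tuple[str, str], list[str]] = {}
    for r in table.runs:
        groups.setdefault((r.subject_id, r.group), []).append(r.run_id)
    cols = {}
    new_runs = []
    for (subject, group), run_ids in groups.items():
        col = sample_column(subject, group)
        cols[col] = table.intensity[run_ids].median(axis=1, skipna=True)
        new_runs.append(RunDesign(col, subject, group, 1))
    intensity = pd.DataFrame(cols, index=table.intensity.index)
    return PeakTable(list(table.features), new_runs, intensity)


def blank_means(blanks: PeakTable, feature_ids) -> pd.Series:
    """Mean blank height per feature; missing-in-blank counts as 0, absent features get 0."""
    filled = blanks.intensity.fillna(0.0)
    means = filled.mean(axis=1)
    return means.reindex(feature_ids, fill_value=0.0)


def filter_blank(table: PeakTable, blanks: PeakTable, cfg: CurationConfig) -> PeakTable:
    """Retain features whose max sample height is >= k x mean extraction-blank height."""
    mx = table.intensity.max(axis=1, skipna=True).fillna(0.0)
    bm = blank_means(blanks, table.feature_ids)
    keep = mx[mx >= cfg.blank_multiplier * bm].index
    return table.subset_features(keep)


def filter_intensity(table: PeakTable, cfg: CurationConfig) -> PeakTable:
    """Retain features whose max sample height is >= the minimum-intensity threshold."""
    mx = table.intensity.max(axis=1, skipna=True).fillna(0.0)
    keep = mx[mx >= cfg.min_intensity].index
    return table.subset_features(keep)


def filter_identified(table: PeakTable, cfg: CurationConfig) -> PeakTable:
    """Drop features without a library identification (no name / identity key)."""
    if not cfg.require_identified:
        return table.copy()
    keep = [f.feature_id for f in table.features if f.is_identified]
    return table.subset_features(keep)


def filter_prevalence(table: PeakTable, cfg: CurationConfig) -> PeakTable:
    """Retain features detected in >= n_min samples of at least one group."""
    detected = table.intensity.notna()
    group_cols: dict[str, list[str]] = {}
    for r in table.runs:
        if r.group != "blank":
            group_cols.setdefault(r.group, []).append(r.run_id)
    keep = []
    for fid in table.feature_ids:
        row = detected.loc[fid]
        if any(row[cols].sum() >= cfg.min_prevalence for cols in group_cols.values()):
            keep.append(fid)
    return table.subset_features(keep)


def impute_half_lld(table: PeakTable) -> CuratedMatrix:
    """Fill non-detections at half the per-metabolite limit of detection.

    The limit of detection of a metabolite is its minimum detected intensity
    over all retained samples; detected cells are untouched.
    """
    values = table.intensity.copy()
    imputed = values.isna()
    lld = values.min(axis=1, skipna=True)
    if lld.isna().any():
        bad = list(lld.index[lld.isna()])
        raise ValidationError(f"metabolite(s) with no detected value, cannot set LLD: {bad}")
    fill = lld / 2.0
    for fid in values.index[imputed.any(axis=1)]:
        values.loc[fid] = values.loc[fid].fillna(fill[fid])
    samples = [(r.subject_id, r.group) for r in table.runs]
    return CuratedMatrix(
        metabolites=list(table.features),
        samples=samples,
        values=values,
        lld=lld,
        imputed=imputed,
        audit={},
    )


def merge_duplicates(cm: CuratedMatrix) -> CuratedMatrix:
    """Merge features sharing an identity key (adducts/duplicates of one metabolite).

    The representative annotation is the member with the highest overall
    median intensity; merged cell values are the member maximum (height
    semantics, idempotent under regrouping).
    """
    by_key: dict[object, list[FeatureAnnotation]] = {}
    for f in cm.metabolites:
        key = f.identity_key
        if not f.inchikey and not f.name:  # no usable identity: never merge
            key = ("__anonymous__", f.feature_id)
        by_key.setdefault(key, []).append(f)

    keep_rows: list[str] = []
    merged_members: dict[str, list[str]] = {}
    values = cm.values.copy()
    imputed = cm.imputed.copy()
    lld = cm.lld.copy()
    for key, members in by_key.items():
        ids = [m.feature_id for m in members]
        medians = values.loc[ids].median(axis=1)
        rep = medians.idxmax()
        if len(ids) > 1:
            values.loc[rep] = values.loc[ids].max(axis=0)
            # a merged cell counts as measured if any member measured it
            imputed.loc[rep] = imputed.loc[ids].all(axis=0)
            lld[rep] = cm.lld[ids].min()
            merged_members[rep] = sorted(ids)
        keep_rows.append(rep)

    order = [fid for fid in cm.metabolite_ids if fid in set(keep_rows)]
    metabolites = [cm.annotation(fid) for fid in order]
    audit = dict(cm.audit)
    audit["merged_groups"] = merged_members
    audit["n_merged_away"] = len(cm.metabolite_ids) - len(order)
    return CuratedMatrix(metabolites, list(cm.samples), values.loc[order], lld[order],
                         imputed.loc[order], audit)


def curate(table: PeakTable, blanks: PeakTable, cfg: CurationConfig | None = None) -> CuratedMatrix:
    """Run the full curation chain and record per-step survivor/removal counts."""
    cfg = cfg or CurationConfig()
    audit: dict = {"initial": len(table.features)}
    t = collapse_replicates(table)
    audit["after_collapse"] = len(t.features)

    t2 = filter_blank(t, blanks, cfg)
    audit["removed_blank"] = len(t.features) - len(t2.features)
    t3 = filter_intensity(t2, cfg)
    audit["removed_intensity"] = len(t2.features) - len(t3.features)
    t4 = filter_identified(t3, cfg)
    audit["removed_unidentified"] = len(t3.features) - len(t4.features)
    t5 = filter_prevalence(t4, cfg)
    audit["removed_prevalence"] = len(t4.features) - len(t5.features)
    audit["after_filters"] = len(t5.features)

    cm = impute_half_lld(t5)
    cm = merge_duplicates(cm)
    audit["removed_duplicates"] = cm.audit["n_merged_away"]
    audit["merged_groups"] = cm.audit["merged_groups"]
    audit["final"] = len(cm.metabolites)
    cm.audit = audit
    return cm
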