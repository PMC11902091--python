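"""Synthetic supplement-study generator with ground-truth manifests.

The generator emulates the statistical structure the analysis assumes: N
subjects sampled at baseline, day 4 and day 7, three injection replicates
per sample, extraction blanks, log-normal intensities with subject and
replicate noise, left-censoring below a detection floor, supplement-only
(exogenous) compounds, and a small set of bioavailable spikes that are
present in the extract and appear in plasma only after supplementation.
Studies can additionally plant one violation of each curation rule so the
audit counts of the curation chain can be checked against a manifest.

Day 4 is generated close to baseline (quarter-strength effects on the log
scale), matching the design where differential inference uses baseline vs
day 7 only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import load_fixture_frame, read_graph, read_pathway_sets, fixture_path
from .model import (
    FeatureAnnotation,
    KnowledgeGraph,
    PathwayLibrary,
    PeakTable,
    RunDesign,
    ValidationError,
)

SUBCLASSES = (
    "Amino acids",
    "Dipeptides",
    "Xanthines",
    "Phospholipids",
    "Fatty acids",
    "Alkaloids",
    "(Poly)phenols",
    "Cholines",
)

PLASMA_GROUPS = ("basal", "day4", "day7")


@dataclass
class SimulationConfig:
    n_subjects: int = 8
    n_replicates: int = 3
    n_blanks: int = 4
    n_endogenous: int = 60
    n_exogenous: int = 20  # supplement-only compounds, never in plasma
    n_bioavailable: int = 3  # supplement compounds crossing into plasma at day 7
    n_shared_endogenous: int = 5  # endogenous compounds also present in the extract
    n_decreased: int = 12
    n_increased: int = 4
    # endogenous compounds that vanish below the detection floor by day 7
    # (the "basal-only" region of the detection Venn) and ones that appear
    # only at day 7 without being supplied by the extract
    n_basal_only: int = 12
    n_day7_only: int = 3
    # per-metabolite true day7/basal ratios are drawn log-uniformly from these
    # ranges (heavy-tailed decreases dominate, as in real supplement studies);
    # a scalar override fixes the ratio for every affected metabolite instead
    decreased_ratio_range: tuple[float, float] = (1 / 150.0, 1 / 2.0)
    increased_ratio_range: tuple[float, float] = (2.0, 20.0)
    decreased_ratio: Optional[float] = None
    increased_ratio: Optional[float] = None
    effects: Optional[dict[str, float]] = None  # metabolite name -> day7/basal ratio override
    mean_log10_low: float = 3.8
    mean_log10_high: float = 5.2
    subject_sd_log10: float = 0.15
    replicate_cv: float = 0.15
    detection_floor: float = 500.0
    blank_contamination_fraction: float = 0.10
    blank_contamination_level: float = 100.0
    # planted curation-rule violations (all removed by exactly one filter)
    n_blank_violations: int = 0
    n_low_intensity: int = 0
    n_unidentified: int = 0
    n_low_prevalence: int = 0
    n_duplicate_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_replicates < 1 or self.n_blanks < 1:
            raise ValidationError("counts must be >= 1")
        for r in (self.decreased_ratio, self.increased_ratio):
            if r is not None and r <= 0:
                raise ValidationError("effect ratios must be > 0")
        if self.detection_floor >= 10**self.mean_log10_low:
            raise ValidationError("detection floor sits above typical abundance; nothing would be detected")
        if self.n_bioavailable + self.n_shared_endogenous > 0 and self.n_subjects < 3:
            raise ValidationError("need >= 3 subjects for a meaningful study")


@dataclass
class SyntheticTruth:
    seed: int
    compounds: pd.DataFrame  # index inchikey: kind, in_cse, in_basal, in_day7, true_ratio, subclass, pathway
    planted: dict = field(default_factory=dict)  # expected per-filter removal counts

    @property
    def bioavailable(self) -> frozenset[str]:
        c = self.compounds
        return frozenset(c.index[(c.kind == "bioavailable")])


@dataclass
class SimulatedStudy:
    plasma: PeakTable
    cse: PeakTable
    blanks: PeakTable
    truth: SyntheticTruth
    config: SimulationConfig


def _rep_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    # log-normal replicate noise with the requested coefficient of variation
    sd = math.sqrt(math.log(1 + cv**2))
    return np.exp(rng.normal(0.0, sd, size=size))


def simulate_study(cfg: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a full study: plasma + extract + blank peak tables and a truth manifest."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    # ---- metabolite roster -------------------------------------------------
    defs = []  # dicts: feature_id, name, inchikey, subclass, kind, ratio, adduct

    def add(kind, i, name=None, inchikey=None, ratio=1.0, adduct="[M+H]+", subclass=None):
        n = len(defs)
        defs.append(
            {
                "feature_id": f"F{n+1:04d}",
                "name": name if name is not None else f"{kind.capitalize()}_{i+1:03d}",
                "inchikey": inchikey if inchikey is not None else f"IK-{kind}-{i+1:04d}",
                "subclass": subclass or SUBCLASSES[n % len(SUBCLASSES)],
                "kind": kind,
                "ratio": ratio,
                "adduct": adduct,
            }
        )
        return defs[-1]

    def draw_ratio(scalar, lo_hi):
        if scalar is not None:
            return scalar
        lo, hi = lo_hi
        return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))

    endo = []
    for i in range(cfg.n_endogenous):
        if i < cfg.n_decreased:
            ratio = draw_ratio(cfg.decreased_ratio, cfg.decreased_ratio_range)
        elif i < cfg.n_decreased + cfg.n_increased:
            ratio = draw_ratio(cfg.increased_ratio, cfg.increased_ratio_range)
        else:
            ratio = 1.0
        endo.append(add("endogenous", i, ratio=ratio))
    if cfg.effects:
        by_name = {d["name"]: d for d in defs}
        for name, ratio in cfg.effects.items():
            if name not in by_name:
                raise ValidationError(f"effect override for unknown metabolite {name!r}")
            by_name[name]["ratio"] = ratio

    basal_only = [add("basal_only", i) for i in range(cfg.n_basal_only)]
    day7_only = [add("day7_only", i) for i in range(cfg.n_day7_only)]
    spikes = [add("bioavailable", i) for i in range(cfg.n_bioavailable)]
    exo = [add("exogenous", i) for i in range(cfg.n_exogenous)]
    dups = []
    for i in range(cfg.n_duplicate_pairs):
        partner = endo[cfg.n_decreased + cfg.n_increased + i]  # a null endogenous metabolite
        dups.append(
            add("duplicate", i, name=partner["name"], inchikey=partner["inchikey"],
                adduct="[M+Na]+", subclass=partner["subclass"])
        )
    v_blank = [add("blank_violation", i) for i in range(cfg.n_blank_violations)]
    v_low = [add("low_intensity", i) for i in range(cfg.n_low_intensity)]
    v_unid = [add("unidentified", i, name="", inchikey="") for i in range(cfg.n_unidentified)]
    v_prev = [add("low_prevalence", i) for i in range(cfg.n_low_prevalence)]

    plasma_kinds = {"endogenous", "basal_only", "day7_only", "bioavailable", "duplicate",
                    "blank_violation", "low_intensity", "unidentified", "low_prevalence"}
    plasma_defs = [d for d in defs if d["kind"] in plasma_kinds]
    cse_kinds = {"exogenous", "bioavailable"}
    cse_defs = [d for d in defs if d["kind"] in cse_kinds] + endo[: cfg.n_shared_endogenous]

    # ---- run designs -------------------------------------------------------
    subjects = [f"S{i+1:02d}" for i in range(cfg.n_subjects)]
    plasma_runs = [
        RunDesign(f"{s}_{g}_r{r}", s, g, r)
        for s in subjects
        for g in PLASMA_GROUPS
        for r in range(1, cfg.n_replicates + 1)
    ]
    cse_runs = [RunDesign(f"EXT_cse_r{r}", "EXT", "cse", r) for r in range(1, cfg.n_replicates + 1)]
    blank_runs = [RunDesign(f"BLK_blank_r{r}", "", "blank", r) for r in range(1, cfg.n_blanks + 1)]

    # ---- baseline abundances and plasma matrix -----------------------------
    n_feat = len(plasma_defs)
    n_runs = len(plasma_runs)
    fid_index = {d["feature_id"]: i for i, d in enumerate(plasma_defs)}
    subj_index = {s: i for i, s in enumerate(subjects)}
    run_subj = np.array([subj_index[r.subject_id] for r in plasma_runs])
    run_exp = np.array([{"basal": 0.0, "day4": 0.25, "day7": 1.0}[r.group] for r in plasma_runs])
    is_day7 = np.array([r.group == "day7" for r in plasma_runs])

    mu = 10 ** rng.uniform(cfg.mean_log10_low, cfg.mean_log10_high, size=n_feat)
    subj_eff = 10 ** rng.normal(0.0, cfg.subject_sd_log10, size=(n_feat, cfg.n_subjects))
    ratio = np.array([d["ratio"] for d in plasma_defs])
    noise_sd = math.sqrt(math.log(1 + cfg.replicate_cv**2))
    noise = np.exp(rng.normal(0.0, noise_sd, size=(n_feat, n_runs)))
    jitter_mat = rng.uniform(0.95, 1.05, size=(n_feat, n_runs))

    values = mu[:, None] * subj_eff[:, run_subj] * (ratio[:, None] ** run_exp[None, :]) * noise
    low_prev_runs = np.array([r.subject_id in subjects[:2] for r in plasma_runs])
    for d in plasma_defs:
        i = fid_index[d["feature_id"]]
        kind = d["kind"]
        if kind in ("bioavailable", "day7_only"):
            values[i] = np.where(
                is_day7, 10**4.3 * subj_eff[i, run_subj] * noise[i], np.nan
            )
        elif kind == "basal_only":
            values[i] = np.where(is_day7, np.nan, values[i])
        elif kind == "blank_violation":
            values[i] = 2000.0 * jitter_mat[i]  # < 3 x blank mean of 1000
        elif kind == "low_intensity":
            values[i] = 800.0 * jitter_mat[i]  # above floor, below the 1000-count threshold
        elif kind == "low_prevalence":
            values[i] = np.where(low_prev_runs, 5000.0 * jitter_mat[i], np.nan)
    # duplicates track their partner at reduced response (same metabolite, weaker adduct)
    for d in dups:
        partner = next(e for e in endo if e is not d and e["inchikey"] == d["inchikey"])
        values[fid_index[d["feature_id"]]] = 0.6 * values[fid_index[partner["feature_id"]]]
    values = np.where(values >= cfg.detection_floor, values, np.nan)

    plasma = pd.DataFrame(
        values,
        index=[d["feature_id"] for d in plasma_defs],
        columns=[r.run_id for r in plasma_runs],
    )
    jitter = lambda base, size: base * rng.uniform(0.95, 1.05, size=size)

    # ---- extract (CSE) matrix ----------------------------------------------
    cse = pd.DataFrame(
        np.nan, index=[d["feature_id"] for d in cse_defs], columns=[r.run_id for r in cse_runs]
    )
    for d in cse_defs:
        base = 10 ** rng.uniform(3.5, 5.2)
        vals = base * _rep_noise(rng, cfg.replicate_cv, len(cse_runs))
        cse.loc[d["feature_id"]] = np.where(vals >= cfg.detection_floor, vals, np.nan)

    # ---- extraction blanks --------------------------------------------------
    blanks = pd.DataFrame(
        np.nan, index=plasma.index, columns=[r.run_id for r in blank_runs]
    )
    n_contaminated = int(round(cfg.blank_contamination_fraction * len(endo)))
    contaminated = [d["feature_id"] for d in endo[-n_contaminated:]] if n_contaminated else []
    for fid in contaminated:
        blanks.loc[fid] = jitter(cfg.blank_contamination_level, cfg.n_blanks)
    for d in v_blank:
        blanks.loc[d["feature_id"]] = 1000.0

    # ---- assemble tables -----------------------------------------------------
    def annotations(dd):
        return [
            FeatureAnnotation(
                feature_id=d["feature_id"],
                name=d["name"],
                chemical_family=d["subclass"] if d["name"] else "",
                adduct=d["adduct"],
                inchikey=d["inchikey"],
            )
            for d in dd
        ]

    plasma_table = PeakTable(annotations(plasma_defs), plasma_runs, plasma)
    cse_table = PeakTable(annotations(cse_defs), cse_runs, cse)
    blank_table = PeakTable(annotations(plasma_defs), blank_runs, blanks)

    # ---- truth manifest -------------------------------------------------------
    # membership flags are read off the emitted matrix, so the manifest is
    # verifiable by direct inspection even when an extreme decrease censors a
    # metabolite out of day 7 entirely
    detected = plasma.notna()
    group_runs = {
        g: [r.run_id for r in plasma_runs if r.group == g] for g in PLASMA_GROUPS
    }
    rows = []
    for d in defs:
        if d["kind"] == "duplicate":
            continue  # same compound as its partner
        in_cse = d["kind"] in cse_kinds or d in endo[: cfg.n_shared_endogenous]
        in_plasma = d["kind"] in plasma_kinds
        rows.append(
            {
                "inchikey": d["inchikey"],
                "name": d["name"],
                "kind": d["kind"],
                "in_cse": in_cse,
                "in_basal": in_plasma and bool(detected.loc[d["feature_id"], group_runs["basal"]].any()),
                "in_day7": in_plasma and bool(detected.loc[d["feature_id"], group_runs["day7"]].any()),
                "true_ratio": d["ratio"] if d["kind"] == "endogenous" else float("nan"),
                "subclass": d["subclass"],
                "pathway": f"PW:{d['subclass']}",
            }
        )
    compounds = pd.DataFrame(rows).set_index("inchikey")
    planted = {
        "removed_blank": cfg.n_blank_violations,
        "removed_intensity": cfg.n_low_intensity,
        "removed_unidentified": cfg.n_unidentified,
        "removed_prevalence": cfg.n_low_prevalence,
        "removed_duplicates": cfg.n_duplicate_pairs,
    }
    truth = SyntheticTruth(seed=cfg.seed, compounds=compounds, planted=planted)
    return SimulatedStudy(plasma_table, cse_table, blank_table, truth, cfg)


def simulate_null(cfg: SimulationConfig | None = None) -> SimulatedStudy:
    """A study with no true effects and no spikes: every true ratio is 1."""
    cfg = cfg or SimulationConfig()
    return simulate_study(
        replace(cfg, n_decreased=0, n_increased=0, n_bioavailable=0,
                n_basal_only=0, n_day7_only=0, effects=None)
    )


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def recovery_report(truth: SyntheticTruth, results, called_bioavailable) -> dict:
    """Score pipeline outputs against the manifest.

    ``results`` is the per-metabolite differential list; metabolites are
    matched to truth by InChIKey.  Reports bioavailable precision/recall,
    sign agreement of significant calls with true ratios, and RMSE of the
    estimated log10 ratio over truly affected metabolites.
    """
    true_bio = truth.bioavailable
    called = frozenset(called_bioavailable)
    tp = len(called & true_bio)
    precision = tp / len(called) if called else (1.0 if not true_bio else 0.0)
    recall = tp / len(true_bio) if true_bio else 1.0

    sign_ok = sign_total = 0
    sq_errors = []
    false_sign_claims = 0
    for r in results:
        ik = r.metabolite.inchikey
        if ik not in truth.compounds.index:
            continue
        true_ratio = truth.compounds.at[ik, "true_ratio"]
        if isinstance(true_ratio, pd.Series):  # duplicated index safety
            true_ratio = float(true_ratio.iloc[0])
        est_log = math.log10(r.median_day7 / r.median_basal)
        if not math.isnan(true_ratio) and true_ratio != 1.0:
            sq_errors.append((est_log - math.log10(true_ratio)) ** 2)
            if r.significant:
                sign_total += 1
                if math.copysign(1, est_log) == math.copysign(1, math.log10(true_ratio)):
                    sign_ok += 1
        elif r.significant and not math.isnan(true_ratio):
            false_sign_claims += 1
    return {
        "bioavailable_precision": precision,
        "bioavailable_recall": recall,
        "n_called_bioavailable": len(called),
        "sign_agreement": sign_ok / sign_total if sign_total else float("nan"),
        "n_significant_true_effects": sign_total,
        "n_false_sign_claims": false_sign_claims,
        "fc_rmse_log10": math.sqrt(np.mean(sq_errors)) if sq_errors else float("nan"),
    }


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def packaged_fixtures() -> dict:
    """Load the packaged in-study tables and the miniature library/graph.

    Returns the extract profile table, the plasma differential table, the
    toy pathway library, the toy layered knowledge graph, and the planted
    manifest describing them.
    """
    with open(fixture_path("toy_manifest.json")) as fh:
        manifest = json.load(fh)
    return {
        "cse_profile": load_fixture_frame("cse_profile.tsv"),
        "plasma_differential": load_fixture_frame("plasma_differential.tsv"),
        "toy_library": read_pathway_sets(fixture_path("toy_pathways.gmt")),
        "toy_graph": read_graph(
            fixture_path("toy_graph_nodes.tsv"), fixture_path("toy_graph_edges.tsv")
        ),
        "manifest": manifest,
    }
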