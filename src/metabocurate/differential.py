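"""Univariate differential abundance between baseline and day 7.

Inference is paired and nonparametric: per metabolite, an exact Wilcoxon
signed-rank test on per-subject (basal, day 7) pairs, with
Benjamini-Hochberg control of the false discovery rate across metabolites.
Effect sizes are signed fold changes of the group medians: day7/basal when
the metabolite rises, -(basal/day7) when it falls, so |FC| >= 1 always and
an exact tie reports +1.

The intermediate timepoint (day 4) is carried for chemometrics but excluded
from inference, mirroring the design where day 4 is not distinguishable
from baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CuratedMatrix, FeatureAnnotation, ValidationError

EXACT_MAX_N = 25  # exact signed-rank null enumerated up to here, normal approx above


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _signed_rank_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of the signed-rank statistic (on doubled ranks) over all 2^n sign flips."""
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def _exact_two_sided_p(w_doubled: int, doubled_ranks: tuple[int, ...]) -> float:
    counts = _signed_rank_counts(doubled_ranks)
    n_total = counts.sum()
    cdf = counts[: w_doubled + 1].sum() / n_total
    sf = counts[w_doubled:].sum() / n_total
    return min(1.0, 2.0 * min(cdf, sf))


def paired_test(x_basal, x_day7) -> float:
    """Exact two-sided Wilcoxon signed-rank p for paired per-subject values.

    Zero differences are dropped; ties in |difference| are handled exactly
    (average ranks, null enumerated conditional on the tie pattern) for
    n <= 25 and by a tie-corrected normal approximation above.
    """
    if isinstance(x_basal, pd.Series) and isinstance(x_day7, pd.Series):
        if set(x_basal.index) != set(x_day7.index):
            raise ValidationError("paired test requires the same subjects in both groups")
        x_day7 = x_day7.reindex(x_basal.index)
    a = np.asarray(x_basal, dtype=float)
    b = np.asarray(x_day7, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired test requires equal-length, subject-aligned vectors")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))  # average ranks; multiples of 0.5
    w_plus = ranks[d > 0].sum()
    if n <= EXACT_MAX_N:
        doubled = tuple(int(round(2 * r)) for r in np.sort(ranks))
        return _exact_two_sided_p(int(round(2 * w_plus)), doubled)
    # tie-corrected normal approximation with continuity correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# transforms, screens, multiplicity
# ---------------------------------------------------------------------------

def log_transform(cm: CuratedMatrix) -> CuratedMatrix:
    """Elementwise log10; imputation guarantees positivity, but verify anyway."""
    bad = cm.values.index[(cm.values <= 0).any(axis=1)]
    if len(bad):
        raise ValidationError(f"nonpositive value(s) in metabolite(s): {list(bad)}")
    out = CuratedMatrix(
        metabolites=list(cm.metabolites),
        samples=list(cm.samples),
        values=np.log10(cm.values),
        lld=cm.lld.copy(),
        imputed=cm.imputed.copy(),
        audit=dict(cm.audit),
    )
    return out


def shapiro_screen(cm: CuratedMatrix) -> pd.Series:
    """Shapiro-Wilk normality p per metabolite (diagnostic only; NaN for n<3 or constant)."""
    out = {}
    for fid in cm.metabolite_ids:
        v = cm.values.loc[fid].to_numpy(dtype=float)
        if v.size < 3 or np.ptp(v) == 0:
            out[fid] = math.nan
        else:
            out[fid] = float(stats.shapiro(v).pvalue)
    return pd.Series(out, name="shapiro_p")


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def signed_fc(median_basal: float, median_day7: float) -> float:
    """Signed fold change of day 7 vs baseline medians; |FC| >= 1, ties -> +1."""
    if median_basal <= 0 or median_day7 <= 0:
        raise ValidationError("medians must be > 0 for fold-change computation")
    if median_day7 >= median_basal:
        return median_day7 / median_basal
    return -(median_basal / median_day7)


# ---------------------------------------------------------------------------
# per-metabolite and per-subclass tables
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    metabolite: FeatureAnnotation
    median_basal: float
    median_day7: float
    iqr_basal: float
    iqr_day7: float
    fc: float
    p: float
    q: float
    significant: bool


@dataclass
class SubclassResult:
    subclass: str
    n_members: int
    median_log_fc: float
    p: float
    q: float
    significant: bool
    low_power: bool


def differential_table(
    cm: CuratedMatrix, alpha: float = 0.05
) -> tuple[list[DifferentialResult], dict]:
    """Per-metabolite signed FC + exact paired test + BH-FDR, with a sign summary."""
    subjects = sorted(set(cm.subjects_for_group("basal")) & set(cm.subjects_for_group("day7")))
    if len(subjects) < 3:
        raise ValidationError("need >= 3 subjects present at both basal and day 7")
    basal_cols = [f"{s}:basal" for s in subjects]
    day7_cols = [f"{s}:day7" for s in subjects]

    rows = []
    pvals = []
    for fid in cm.metabolite_ids:
        vb = cm.values.loc[fid, basal_cols].to_numpy(dtype=float)
        v7 = cm.values.loc[fid, day7_cols].to_numpy(dtype=float)
        mb, m7 = float(np.median(vb)), float(np.median(v7))
        iqb = float(np.percentile(vb, 75) - np.percentile(vb, 25))
        iq7 = float(np.percentile(v7, 75) - np.percentile(v7, 25))
        p = paired_test(np.log10(vb), np.log10(v7))
        pvals.append(p)
        rows.append((fid, mb, m7, iqb, iq7, p))

    qvals = bh_fdr(pvals)
    results = []
    for (fid, mb, m7, iqb, iq7, p), q in zip(rows, qvals):
        fc = signed_fc(mb, m7)
        results.append(
            DifferentialResult(
                metabolite=cm.annotation(fid),
                median_basal=mb,
                median_day7=m7,
                iqr_basal=iqb,
                iqr_day7=iq7,
                fc=fc,
                p=p,
                q=float(q),
                significant=bool(q <= alpha),
            )
        )
    summary = summarize(results)
    return results, summary


def summarize(results: list[DifferentialResult]) -> dict:
    sig = [r for r in results if r.significant]
    return {
        "n_metabolites": len(results),
        "n_sig": len(sig),
        "n_up": sum(1 for r in sig if r.fc > 0),
        "n_down": sum(1 for r in sig if r.fc < 0),
    }


def summary_from_frame(frame: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Sign summary for an externally supplied differential table (fc + fdr columns)."""
    sig = frame[frame["fdr"] <= alpha]
    return {
        "n_metabolites": len(frame),
        "n_sig": len(sig),
        "n_up": int((sig["fc"] > 0).sum()),
        "n_down": int((sig["fc"] < 0).sum()),
    }


def audit_printed_fc(frame: pd.DataFrame) -> dict:
    """Recompute signed fold changes from a printed differential table.

    Rows whose printed medians truncate to 0 at the table's precision
    cannot be recomputed and are skipped.  Reports 1-decimal agreement
    counts, the worst absolute mismatch (a median-rounding artifact), and
    sign agreement.
    """
    n_match = n_testable = n_sign = 0
    worst = 0.0
    for _, row in frame.iterrows():
        mb, m7 = float(row["median_basal_e4"]), float(row["median_day7_e4"])
        printed = float(row["fc"])
        # sign agreement needs only the median ordering, so it works even
        # when a median truncates to 0 at the printed precision
        expected_sign = 1.0 if m7 >= mb else -1.0
        if math.copysign(1.0, printed) == expected_sign or (m7 == mb and printed >= 1.0):
            n_sign += 1
        if mb <= 0 or m7 <= 0:
            continue
        n_testable += 1
        fc = signed_fc(mb, m7)
        if round(fc, 1) == printed:
            n_match += 1
        else:
            worst = max(worst, abs(round(fc, 1) - printed))
    return {
        "n_rows": len(frame),
        "n_testable": n_testable,
        "n_match": n_match,
        "worst_mismatch": worst,
        "n_sign_match": n_sign,
    }


def results_frame(results: list[DifferentialResult], scale: float = 1.0) -> pd.DataFrame:
    """Render results as a report table (medians optionally on a display scale)."""
    return pd.DataFrame(
        {
            "name": [r.metabolite.name for r in results],
            "chemical_family": [r.metabolite.chemical_family for r in results],
            "median_basal": [r.median_basal / scale for r in results],
            "iqr_basal": [r.iqr_basal / scale for r in results],
            "median_day7": [r.median_day7 / scale for r in results],
            "iqr_day7": [r.iqr_day7 / scale for r in results],
            "fc": [round(r.fc, 1) for r in results],
            "p_value": [r.p for r in results],
            "fdr": [r.q for r in results],
            "significant": [r.significant for r in results],
        },
        index=pd.Index([r.metabolite.feature_id for r in results], name="feature_id"),
    )


def subclass_fc(
    results: list[DifferentialResult], alpha: float = 0.05
) -> list[SubclassResult]:
    """Aggregate fold changes by chemical subclass.

    Each member metabolite contributes one log10(day7/basal) ratio; the
    subclass test is a Wilcoxon signed-rank of those log ratios against 0,
    BH-adjusted across subclasses.  Unannotated metabolites pool into
    "unknown"; singleton subclasses are flagged low-power (p = 1).
    """
    groups: dict[str, list[float]] = {}
    for r in results:
        sub = r.metabolite.chemical_family or "unknown"
        groups.setdefault(sub, []).append(math.log10(r.median_day7 / r.median_basal))

    names = sorted(groups)
    pvals = []
    for name in names:
        ratios = np.asarray(groups[name])
        if ratios.size < 2:
            pvals.append(1.0)
        else:
            pvals.append(paired_test(np.zeros_like(ratios), ratios))
    qvals = bh_fdr(pvals)
    out = []
    for name, p, q in zip(names, pvals, qvals):
        ratios = groups[name]
        out.append(
            SubclassResult(
                subclass=name,
                n_members=len(ratios),
                median_log_fc=float(np.median(ratios)),
                p=float(p),
                q=float(q),
                significant=bool(q <= alpha),
                low_power=len(ratios) < 2,
            )
        )
    return out
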