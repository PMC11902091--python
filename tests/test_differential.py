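"""Paired nonparametric inference, signed fold changes, FDR, subclass rollup."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from helpers import replicate_runs, tiny_table
from scipy import stats

from metabocurate import curation, differential
from metabocurate.differential import (
    bh_fdr,
    log_transform,
    paired_test,
    shapiro_screen,
    signed_fc,
    subclass_fc,
)
from metabocurate.model import ValidationError
from metabocurate.simulate import SimulationConfig, simulate_null


# ---------------------------------------------------------------------------
# independent oracle: enumerate all sign assignments of the differences
# ---------------------------------------------------------------------------

def brute_force_signed_rank_p(diffs) -> float:
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([False, True], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    cdf = np.mean(ws <= w_obs + 1e-9)
    sf = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(cdf, sf))


def test_all_zero_differences_give_p_one():
    assert paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0


def test_eight_same_sign_differences_hit_exact_tail():
    basal = np.arange(1.0, 9.0)
    day7 = basal + np.linspace(0.1, 0.9, 8)  # distinct positive differences
    assert paired_test(basal, day7) == pytest.approx(2 / 2**8, abs=1e-15)


def test_exact_p_matches_brute_force_enumeration():
    rng = np.random.default_rng(42)
    for n in (3, 4, 6, 9, 11):
        for _ in range(8):
            d = np.round(rng.normal(size=n), 1)  # rounding creates ties/zeros
            assert paired_test(np.zeros(n), d) == pytest.approx(
                brute_force_signed_rank_p(d), abs=1e-12
            )


def test_pairing_invariance_under_permutation():
    rng = np.random.default_rng(7)
    a, b = rng.normal(size=12), rng.normal(size=12)
    perm = rng.permutation(12)
    assert paired_test(a, b) == pytest.approx(paired_test(a[perm], b[perm]), abs=1e-15)


def test_mismatched_subjects_error():
    a = pd.Series([1.0, 2.0], index=["s1", "s2"])
    b = pd.Series([1.0, 2.0], index=["s1", "s3"])
    with pytest.raises(ValidationError, match="same subjects"):
        paired_test(a, b)


def test_large_n_normal_approximation_is_close_to_scipy():
    rng = np.random.default_rng(0)
    a = rng.normal(size=40)
    b = a + rng.normal(0.3, 1.0, size=40)
    ours = paired_test(a, b)
    ref = stats.wilcoxon(b - a, correction=True, method="approx").pvalue
    assert ours == pytest.approx(ref, rel=0.05)


# ---------------------------------------------------------------------------
# transforms and multiplicity
# ---------------------------------------------------------------------------

def _curated(values_by_met, subjects=("s1", "s2", "s3"), groups=("basal", "day7")):
    runs = replicate_runs(list(subjects), list(groups))
    t = tiny_table(values_by_met, runs)
    return curation.impute_half_lld(t)


def test_log_transform_power_grid():
    cm = _curated({"A": [1, 100, 10, 1000, 10, 10]})
    lg = log_transform(cm)
    assert list(lg.values.loc["A"]) == [0.0, 2.0, 1.0, 3.0, 1.0, 1.0]


def test_log_transform_rejects_nonpositive():
    cm = _curated({"A": [1, 1, 1, 1, 1, 1]})
    cm.values.loc["A", "s1:basal"] = 0.0
    with pytest.raises(ValidationError, match="A"):
        log_transform(cm)


def test_shapiro_screen_flags_undefined_and_detects_lognormal():
    rng = np.random.default_rng(3)
    raw = {f"M{i}": list(10 ** rng.normal(4, 0.8, size=8)) for i in range(40)}
    cm = _curated(raw, subjects=[f"s{j}" for j in range(1, 5)], groups=("basal", "day7"))
    p_raw = shapiro_screen(cm)
    p_log = shapiro_screen(log_transform(cm))
    # heavy log-normal raw data: the log scale must look far more normal
    assert p_log.median() > p_raw.median()
    tiny = _curated({"A": [5, 6]}, subjects=["s1"], groups=("basal", "day7"))
    assert math.isnan(shapiro_screen(tiny).loc["A"])


def test_bh_fdr_hand_cases():
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_fdr([0.04, 0.04, 0.04]) == pytest.approx([0.04, 0.04, 0.04])
    q = bh_fdr([0.001, 0.02, 0.9, 0.04])
    assert np.all(q >= [0.001, 0.02, 0.9, 0.04]) and np.all(q <= 1)


# ---------------------------------------------------------------------------
# signed fold change
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mb,m7,expected",
    [
        (3.54, 2.33, -1.5),  # creatine
        (1.50, 0.25, -6.0),  # kynurenine
        (1.04, 0.44, -2.4),  # Leu-Ala
        (8.21, 5.42, -1.5),  # Asp-Lys
        (11.8, 10.8, -1.1),  # cytidine
        (4.91, 12.0, 2.4),  # caffeine medians (printed 2.5; unrounded 2.444)
        (2.0, 2.0, 1.0),  # tie convention
    ],
)
def test_signed_fc_values(mb, m7, expected):
    assert round(signed_fc(mb, m7), 1) == expected


def test_signed_fc_antisymmetry():
    rng = np.random.default_rng(1)
    for _ in range(100):
        a, b = rng.uniform(0.1, 50, size=2)
        fc, rev = signed_fc(a, b), signed_fc(b, a)
        if a != b:
            assert fc == pytest.approx(-rev)
    assert signed_fc(3.0, 3.0) == 1.0 == signed_fc(3.0, 3.0)


def test_signed_fc_rejects_nonpositive_medians():
    with pytest.raises(ValidationError):
        signed_fc(0.0, 1.0)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def test_differential_table_single_metabolite_consistency():
    rng = np.random.default_rng(5)
    vals = list(10 ** rng.normal(4, 0.1, 8)) + list(10 ** rng.normal(4.6, 0.1, 8))
    cm = _curated({"A": vals}, subjects=[f"s{j}" for j in range(1, 9)])
    results, summary = differential.differential_table(cm)
    r = results[0]
    assert summary["n_sig"] == int(r.significant)
    assert summary["n_up"] == int(r.significant and r.fc > 0)
    assert r.q >= r.p and abs(r.fc) >= 1


def test_fixture_fc_audit_sign_agreement(fixtures):
    audit = differential.audit_printed_fc(fixtures["plasma_differential"])
    assert audit["n_sign_match"] == audit["n_rows"]
    # the five anchor rows recompute exactly at one decimal
    assert audit["n_match"] >= 5


def test_null_study_calibration_is_subuniform():
    """On null data the exact test is valid: P(p <= a) <= a at achievable levels."""
    rng = np.random.default_rng(9)
    pvals = []
    for _ in range(30):
        study = simulate_null(SimulationConfig(seed=int(rng.integers(2**31)), n_endogenous=40))
        cm = curation.curate(study.plasma, study.blanks)
        results, _ = differential.differential_table(cm)
        pvals.extend(r.p for r in results)
    pvals = np.asarray(pvals)
    for a in (0.01, 0.05, 0.1, 0.25, 0.5):
        assert np.mean(pvals <= a) <= a + 3 * math.sqrt(a * (1 - a) / pvals.size)


def test_randomized_null_pvalues_are_uniform():
    """The randomized version of the discrete p-value is exactly U(0,1) under the null."""
    rng = np.random.default_rng(2)
    n = 8
    # null distribution of the exact p at this n, from the test itself
    pvs = []
    for _ in range(4000):
        d = rng.normal(size=n)
        pvs.append(paired_test(np.zeros(n), d))
    pvs = np.asarray(pvs)
    levels = np.unique(pvs)
    cdf_at = {lv: np.mean(pvs <= lv) for lv in levels}
    prev = {lv: (0.0 if i == 0 else float(levels[i - 1])) for i, lv in enumerate(levels)}
    # randomize within each achievable level using its theoretical mass
    u = np.array([prev[p] + rng.uniform() * (p - prev[p]) for p in pvs])
    assert stats.kstest(u, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# subclasses
# ---------------------------------------------------------------------------

def _result(name, family, mb, m7, significant=True):
    from metabocurate.model import FeatureAnnotation

    ann = FeatureAnnotation(feature_id=name, name=name, chemical_family=family)
    return differential.DifferentialResult(
        ann, mb, m7, 0.0, 0.0, signed_fc(mb, m7), 0.01, 0.01, significant
    )


def test_subclass_single_member_is_low_power():
    out = subclass_fc([_result("a", "Xanthines", 1.0, 2.0)])
    assert out[0].p == 1.0 and out[0].low_power


def test_subclass_six_members_same_direction():
    members = [
        _result(f"m{i}", "Phospholipids", 1.0, 1.0 + 0.1 * (i + 1)) for i in range(6)
    ]
    out = subclass_fc(members)
    assert out[0].p == pytest.approx(2 / 2**6, abs=1e-12)
    assert out[0].n_members == 6 and out[0].median_log_fc > 0


def test_unannotated_metabolites_pool_into_unknown():
    members = [_result(f"m{i}", "", 1.0, 2.0) for i in range(4)]
    out = subclass_fc(members)
    assert len(out) == 1 and out[0].subclass == "unknown"
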