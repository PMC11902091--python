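"""Scaling, sphericity, PCA/varimax, Ward clustering."""

import numpy as np
import pandas as pd
import pytest

from metabocurate import chemometrics as chemo
from metabocurate.curation import curate
from metabocurate.model import ValidationError
from metabocurate.simulate import SimulationConfig, simulate_study


def frame(rows: dict, cols=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    if cols is not None:
        df.columns = cols
    return df


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def test_scale_three_points_to_unit_interval():
    out = chemo.scale_matrix(frame({"A": [1.0, 2.0, 3.0]}))
    assert list(out.loc["A"]) == pytest.approx([-1.0, 0.0, 1.0])


def test_scale_drops_constant_metabolite_with_warning():
    with pytest.warns(UserWarning, match="zero-variance"):
        out = chemo.scale_matrix(frame({"A": [1, 2, 3], "B": [5, 5, 5]}))
    assert list(out.index) == ["A"]


def test_scale_idempotent_up_to_rounding():
    rng = np.random.default_rng(0)
    x = frame({f"M{i}": rng.normal(size=10) for i in range(5)})
    once = chemo.scale_matrix(x)
    twice = chemo.scale_matrix(once)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)
    assert once.abs().to_numpy().max() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Bartlett sphericity
# ---------------------------------------------------------------------------

def test_bartlett_independent_variables_accept_sphericity():
    rng = np.random.default_rng(1)
    x = frame({f"M{i}": rng.normal(size=200) for i in range(5)})
    assert chemo.bartlett_sphericity(chemo.scale_matrix(x)) > 0.05


def test_bartlett_correlated_pair_rejects():
    rng = np.random.default_rng(2)
    base = rng.normal(size=100)
    x = frame({"A": base, "B": base + rng.normal(0, 0.01, 100), "C": rng.normal(size=100)})
    assert chemo.bartlett_sphericity(chemo.scale_matrix(x)) < 1e-6


def test_bartlett_factor_structure_rejects():
    rng = np.random.default_rng(3)
    factor = rng.normal(size=150)
    x = frame({f"M{i}": 0.8 * factor + 0.3 * rng.normal(size=150) for i in range(6)})
    assert chemo.bartlett_sphericity(chemo.scale_matrix(x)) < 1e-3


# ---------------------------------------------------------------------------
# PCA + varimax
# ---------------------------------------------------------------------------

def test_rank_one_matrix_explains_everything_on_first_component():
    v = np.array([1.0, -2.0, 0.5, 3.0])
    x = pd.DataFrame(np.outer([2.0, -1.0, 0.5], v),
                     index=["A", "B", "C"], columns=list("wxyz"))
    res = chemo.pca(x, k=1)
    assert res.variance_explained[0] == pytest.approx(1.0)


def test_two_feature_variance_shares_match_hand_eigendecomposition():
    rng = np.random.default_rng(4)
    n = 2000
    a = rng.normal(0, 2.0, n)
    b = 0.5 * a + rng.normal(0, 1.0, n)
    x = pd.DataFrame(np.vstack([a, b]), index=["A", "B"])
    eig = np.linalg.eigvalsh(np.corrcoef(a, b))[::-1]
    res = chemo.pca(x, k=2)
    assert res.variance_explained == pytest.approx(eig / eig.sum(), rel=1e-6)


def test_pca_reconstructs_scaled_matrix_and_fractions_sum_to_one():
    rng = np.random.default_rng(5)
    x = chemo.scale_matrix(frame({f"M{i}": rng.normal(size=7) for i in range(5)}))
    res = chemo.pca(x, k=2)
    assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
    xc = x.to_numpy().T - x.to_numpy().T.mean(0)
    xs = xc / xc.std(0)
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(recon, xs, atol=1e-10)


def test_pca_k_too_large_errors():
    x = frame({"A": [1.0, 2.0, 1.5], "B": [0.5, 1.0, 2.0]})
    with pytest.raises(ValidationError):
        chemo.pca(x, k=4)


def test_varimax_preserves_communality_and_never_decreases_criterion():
    rng = np.random.default_rng(6)
    L = rng.normal(size=(12, 2))
    rot, R = chemo.varimax(L)
    assert np.allclose((rot**2).sum(1), (L**2).sum(1), atol=1e-8)
    assert np.allclose(R.T @ R, np.eye(2), atol=1e-10)
    # on the unweighted problem the criterion itself must not decrease
    plain, _ = chemo.varimax(L, kaiser=False)
    assert chemo.varimax_criterion(plain) >= chemo.varimax_criterion(L) - 1e-12


def test_varimax_matches_independent_svd_reference():
    def svd_varimax(L, tol=1e-10, max_iter=2000):
        p, k = L.shape
        R = np.eye(k)
        d = 0.0
        for _ in range(max_iter):
            lr = L @ R
            u, s, vt = np.linalg.svd(L.T @ (lr**3 - (lr @ np.diag((lr**2).sum(0))) / p))
            R = u @ vt
            d_new = s.sum()
            if d_new < d * (1 + tol):
                break
            d = d_new
        return L @ R

    rng = np.random.default_rng(17)
    for _ in range(5):
        L = rng.normal(size=(15, 2))
        mine, _ = chemo.varimax(L, kaiser=False, tol=1e-10)
        ref = svd_varimax(L)
        assert chemo.varimax_criterion(mine) == pytest.approx(
            chemo.varimax_criterion(ref), abs=1e-7
        )


def test_varimax_fixed_point():
    # a perfectly simple structure is already varimax-optimal
    L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.95]])
    rot, _ = chemo.varimax(L)
    assert np.allclose(np.abs(rot), np.abs(L), atol=1e-6)


def test_top_loadings_recovers_planted_high_impact_metabolites():
    # ten lipid-like drivers with day-7 shifts far above the noise floor,
    # no other structure in the study
    cfg = SimulationConfig(
        seed=21,
        n_endogenous=40,
        n_decreased=0,
        n_increased=0,
        n_bioavailable=0,
        n_basal_only=0,
        n_day7_only=0,
        effects={f"Endogenous_{i+1:03d}": 50.0 for i in range(10)},
    )
    study = simulate_study(cfg)
    cm = curate(study.plasma, study.blanks)
    scaled = chemo.scale_matrix(cm)
    res = chemo.pca(scaled, k=2)
    top = chemo.top_loadings(res, top=10)
    planted = {f"F{i+1:04d}" for i in range(10)}
    assert planted == set(top.index)


def test_top_loadings_deterministic_tie_break():
    x = pd.DataFrame(np.eye(3), index=["b", "a", "c"])
    res = chemo.pca(chemo.scale_matrix(x), k=2)
    t = chemo.top_loadings(res, top=3)
    strengths = t["max_abs_loading"].round(12)
    for s in strengths.unique():
        ids = list(t.index[strengths == s])
        assert ids == sorted(ids)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def test_identical_samples_merge_first_at_zero_height():
    x = pd.DataFrame(
        {"u": [1.0, 2.0], "v": [1.0, 2.0], "w": [9.0, 8.0]}, index=["A", "B"]
    )
    d = chemo.ward_cluster(x, axis="samples")
    a, b, h = d.merges[0]
    assert {d.labels[a], d.labels[b]} == {"u", "v"} and h == 0.0


def test_three_points_on_line_merge_nearest_pair_first():
    # brute force over the three possible first merges: {0,1} is cheapest
    x = pd.DataFrame({"p": [0.0], "q": [1.0], "r": [10.0]}, index=["A"])
    d = chemo.ward_cluster(x, axis="samples")
    a, b, _ = d.merges[0]
    assert {d.labels[a], d.labels[b]} == {"p", "q"}
    assert np.all(np.diff(d.heights) >= -1e-12)  # ultrametric monotone merges


def test_day7_effect_separates_samples_at_two_clusters():
    """Under the default study conditions, cutting the sample dendrogram at two
    clusters separates day-7 samples from {basal, day-4} (high Rand index)."""
    from sklearn.metrics import rand_score

    scores = []
    for seed in range(5):
        study = simulate_study(SimulationConfig(seed=100 + seed))
        cm = curate(study.plasma, study.blanks)
        scaled = chemo.scale_matrix(cm)
        d = chemo.ward_cluster(scaled, axis="samples")
        assign = d.cut(2)
        labels = sorted(assign)
        pred = [assign[lbl] for lbl in labels]
        true = [1 if lbl.endswith(":day7") else 0 for lbl in labels]
        scores.append(rand_score(true, pred))
    assert np.median(scores) > 0.9


def test_heatmap_export_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    x = chemo.scale_matrix(frame({f"M{i}": rng.normal(size=6) for i in range(4)}))
    dr = chemo.ward_cluster(x, axis="metabolites")
    dc = chemo.ward_cluster(x, axis="samples")
    out_path = tmp_path / "heat.tsv"
    out = chemo.heatmap_export(x, dr, dc, out_path)
    back = pd.read_csv(out_path, sep="\t", index_col=0)
    back.columns = [int(c) if c.isdigit() else c for c in back.columns]
    assert np.allclose(back.to_numpy(), out.to_numpy())
    assert list(out.index) == [dr.labels[i] for i in dr.leaf_order]
    assert out.shape == x.shape
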