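"""Multivariate chemometrics: scaling, sphericity, PCA + varimax, Ward clustering.

The scaled representation standardises each metabolite across samples
(z-score) and then divides by the maximum |z| so every metabolite lands in
[-1, 1].  PCA is a singular-value decomposition of the samples x
metabolites scaled matrix; the first K loading columns are varimax-rotated
(Kaiser-normalised pairwise rotations) for interpretability, with the same
rotation applied to the scores so the decomposition still reconstructs the
data.  Sample/metabolite dendrograms use Euclidean distance with Ward's
minimum-variance criterion (ward.D2 semantics).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .model import CuratedMatrix, ValidationError


def _as_frame(m: Union[CuratedMatrix, pd.DataFrame]) -> pd.DataFrame:
    return m.values if isinstance(m, CuratedMatrix) else m


def scale_matrix(m: Union[CuratedMatrix, pd.DataFrame]) -> pd.DataFrame:
    """Per-metabolite z-score then divide by max |z|, landing in [-1, 1].

    Zero-variance metabolites carry no contrast and are dropped with a
    warning.
    """
    x = _as_frame(m).astype(float)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance metabolite(s): "
            f"{list(x.index[flat])[:5]}...",
            stacklevel=2,
        )
        x = x.loc[~flat]
        mu, sd = mu[~flat], sd[~flat]
    z = x.sub(mu, axis=0).div(sd, axis=0)
    return z.div(z.abs().max(axis=1), axis=0)


def bartlett_sphericity(scaled: pd.DataFrame) -> float:
    """Bartlett's test of sphericity on the metabolite correlation matrix.

    chi^2 = -(n-1-(2p+5)/6) * ln det(R) with p(p-1)/2 degrees of freedom;
    a singular correlation matrix (more metabolites than samples) gives
    det -> 0 and hence p -> 0, i.e. sphericity is firmly rejected.
    """
    x = scaled.to_numpy(dtype=float).T  # samples x metabolites
    n, p = x.shape
    if p < 2 or n < 4:
        raise ValidationError("Bartlett sphericity needs >= 2 metabolites and >= 4 samples")
    corr = np.corrcoef(x, rowvar=False)
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or not np.isfinite(logdet):
        return 0.0
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(stats.chi2.sf(chi2, df))


def varimax(loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 200,
            kaiser: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by iterative pairwise planar rotations.

    Returns (rotated loadings, rotation matrix R) with rotated = loadings @ R.
    Kaiser normalisation divides rows by their communality before rotating.
    The varimax criterion (sum of column variances of squared loadings) is
    non-decreasing across sweeps.
    """
    L = np.array(loadings, dtype=float)
    p, k = L.shape
    R = np.eye(k)
    if k < 2:
        return L, R
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser:
        h_safe = np.where(h > 0, h, 1.0)
        L = L / h_safe[:, None]
    for _ in range(max_iter):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                u = L[:, i] ** 2 - L[:, j] ** 2
                v = 2.0 * L[:, i] * L[:, j]
                num = 2.0 * (u * v).sum() - 2.0 * u.sum() * v.sum() / p
                den = (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * math.atan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = math.cos(phi), math.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        if max_angle < tol:
            break
    if kaiser:
        L = L * np.where(h > 0, h, 1.0)[:, None]
    return L, R


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over components of the variance of squared loadings."""
    sq = np.asarray(loadings, dtype=float) ** 2
    return float((sq.var(axis=0)).sum())


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components (first K varimax-rotated)
    variance_explained: np.ndarray  # fraction per component, pre-rotation order
    bartlett_p: float
    k_rotated: int


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Flip each component so its largest-|loading| entry is positive (in place)."""
    for j in range(loadings.shape[1]):
        idx = np.argmax(np.abs(loadings[:, j]))
        if loadings[idx, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def pca(scaled: pd.DataFrame, k: int = 2) -> PcaResult:
    """Unit-variance (correlation) PCA of samples over the metabolite space.

    Metabolites are standardised to mean 0 / variance 1 before the SVD, so
    the standardized loadings are variable-component correlations scaled by
    the singular values.  ``scores @ loadings.T`` reconstructs the
    standardised matrix at full rank; the first ``k`` components are
    varimax-rotated jointly in scores and loadings, which leaves that
    reconstruction unchanged.
    """
    x = scaled.to_numpy(dtype=float).T  # samples x metabolites
    n, p = x.shape
    if k > min(n, p):
        raise ValidationError(f"k={k} exceeds matrix rank bound {min(n, p)}")
    xc = x - x.mean(axis=0, keepdims=True)
    sd = xc.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # zero-variance columns should be dropped upstream
    xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    # standardized loadings: component-scaled eigenvectors (variable-component
    # covariances on the scaled data); scores scaled so scores @ loadings.T
    # still reconstructs the centred matrix exactly
    denom = math.sqrt(max(n - 1, 1))
    loadings = vt.T * (s / denom)
    scores = u * denom
    _fix_signs(scores, loadings)

    rot_l, rot = varimax(loadings[:, :k])
    loadings = loadings.copy()
    loadings[:, :k] = rot_l
    scores = scores.copy()
    scores[:, :k] = scores[:, :k] @ rot
    _fix_signs(scores, loadings)

    comp_names = [f"PC{i+1}" for i in range(loadings.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=scaled.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=scaled.index, columns=comp_names),
        variance_explained=var_frac,
        bartlett_p=bartlett_sphericity(scaled) if min(n, p) >= 4 and p >= 2 else math.nan,
        k_rotated=k,
    )


def top_loadings(result: PcaResult, top: int = 10) -> pd.DataFrame:
    """Metabolites ranked by max |rotated loading| over the rotated components."""
    sub = result.loadings.iloc[:, : result.k_rotated].abs()
    strength = sub.max(axis=1)
    order = sorted(strength.index, key=lambda fid: (-strength[fid], fid))
    chosen = order[:top]
    return pd.DataFrame(
        {
            "max_abs_loading": strength[chosen],
            "component": sub.loc[chosen].idxmax(axis=1),
        }
    )


@dataclass
class DendrogramResult:
    merges: list[tuple[int, int, float]]  # scipy linkage encoding (a, b, height)
    leaf_order: list[int]
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def cut(self, n_clusters: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        z = np.array(
            [[a, b, h, 0] for a, b, h in self.merges], dtype=float
        )
        # recompute cluster sizes column expected by scipy
        sizes = _merge_sizes(self.merges, len(self.labels))
        z[:, 3] = sizes
        assign = fcluster(z, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, assign.tolist()))


def _merge_sizes(merges, n_leaves):
    sizes = []
    size_of = {i: 1 for i in range(n_leaves)}
    for idx, (a, b, _) in enumerate(merges):
        s = size_of[int(a)] + size_of[int(b)]
        size_of[n_leaves + idx] = s
        sizes.append(s)
    return sizes


def ward_cluster(scaled: pd.DataFrame, axis: str = "samples") -> DendrogramResult:
    """Agglomerative Ward clustering on Euclidean distances along one axis."""
    if axis == "samples":
        data = scaled.to_numpy(dtype=float).T
        labels = list(scaled.columns)
    elif axis == "metabolites":
        data = scaled.to_numpy(dtype=float)
        labels = list(scaled.index)
    else:
        raise ValidationError("axis must be 'samples' or 'metabolites'")
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 observations to cluster")
    z = linkage(data, method="ward")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return DendrogramResult(merges=merges, leaf_order=list(map(int, leaves_list(z))), labels=labels)


def heatmap_export(
    scaled: pd.DataFrame,
    dendro_rows: DendrogramResult,
    dendro_cols: DendrogramResult,
    path,
    image_path=None,
) -> pd.DataFrame:
    """Write the dendrogram-reordered matrix as TSV (optionally render an image)."""
    rows = [dendro_rows.labels[i] for i in dendro_rows.leaf_order]
    cols = [dendro_cols.labels[i] for i in dendro_cols.leaf_order]
    out = scaled.loc[rows, cols]
    out.to_csv(path, sep="\t", float_format="%.10g")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 10))
        im = ax.imshow(out.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=5)
        ax.set_yticks(range(len(rows)), rows, fontsize=4)
        fig.colorbar(im, ax=ax, label="scaled intensity")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return out
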