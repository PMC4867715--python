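"""Principal component analysis of tangent-space shape coordinates.

After GPA, each specimen is a 30-vector of tangent coordinates. PCA of
their covariance matrix (no column scaling) decomposes shape variance into
orthogonal modes; for k=15 2D landmarks the superimposition removes 4
degrees of freedom (2 translation, 1 rotation, 1 scale), so at most
2k - 4 = 26 components carry variance. Fossil or other out-of-sample
configurations superimposed on the same consensus are projected onto the
extant axes. The shape change along a component is visualized by warping a
rectangular grid with a thin-plate spline interpolant that maps the
consensus onto the consensus displaced along that component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .superimposition import AlignedShapes, ShapeError

MAX_NONNULL = 26  # 2k - 4 for k = 15 landmarks in 2D


@dataclass
class ShapePCA:
    """Eigenstructure of the tangent-coordinate covariance matrix."""

    eigenvalues: np.ndarray          # descending, >= 0, full length 2k
    percent_variance: np.ndarray     # 100 * eigenvalue / total
    scores: np.ndarray               # (n_specimens, n_components)
    loadings: np.ndarray             # (n_components, 2k), rows orthonormal
    mean: np.ndarray                 # mean tangent vector of the fitted specimens
    ids: list[str]
    n_nonnull: int

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)

    def variance_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(k)],
                "eigenvalue": self.eigenvalues[:k],
                "percent_variance": self.percent_variance[:k],
                "cumulative_percent": np.cumsum(self.percent_variance[:k]),
            }
        )


def fit_pca(
    aligned: AlignedShapes,
    include: list[str] | None = None,
    rank_tol: float = 1e-10,
) -> ShapePCA:
    """PCA of the tangent coordinates of the included specimens.

    ``include`` selects specimens by id (default: all). Scores are centred
    projections; the eigenvector sign convention makes the largest-magnitude
    loading coordinate positive, so axes are reproducible across runs.
    """
    tang = aligned.tangent_frame()
    ids = list(aligned.ids)
    if include is not None:
        idx = [aligned.index_of(i) for i in include]
        tang = tang[idx]
        ids = list(include)
    n = tang.shape[0]
    if n < 3:
        raise ShapeError(f"PCA needs at least 3 specimens, got {n}")

    mean = tang.mean(axis=0)
    centered = tang - mean
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    total = evals.sum()
    n_nonnull = int(min((evals > rank_tol * max(total, 1.0)).sum(), MAX_NONNULL, n - 1))
    loadings = evecs[:, :n_nonnull].T.copy()
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    scores = centered @ loadings.T
    percent = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return ShapePCA(
        eigenvalues=evals,
        percent_variance=percent,
        scores=scores,
        loadings=loadings,
        mean=mean,
        ids=ids,
        n_nonnull=n_nonnull,
    )


def project(pca: ShapePCA, tangent_vector: np.ndarray) -> np.ndarray:
    """Project a tangent-space vector (or stack of them) onto the PC axes."""
    v = np.asarray(tangent_vector, dtype=float)
    if v.shape[-1] != pca.loadings.shape[1]:
        raise ShapeError(
            f"dimension mismatch: vector has {v.shape[-1]} coordinates, "
            f"PCA space has {pca.loadings.shape[1]}"
        )
    return (v - pca.mean) @ pca.loadings.T


# ---------------------------------------------------------------------------
# Thin-plate spline deformation grids
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, written on squared distances; U(0) = 0
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out


@dataclass
class ThinPlateSpline:
    """2D thin-plate spline interpolant through control-point pairs.

    Solves the classical bordered system [[K, P], [P^T, 0]] for the radial
    weights and the affine part; ``bending_energy`` is the quadratic form
    w^T K w summed over output dimensions (zero iff the map is affine).
    """

    control: np.ndarray   # (k, 2) source landmarks
    weights: np.ndarray   # (k, 2) non-affine weights per output dimension
    affine: np.ndarray    # (3, 2) rows: constant, x, y

    @classmethod
    def fit(cls, source: np.ndarray, target: np.ndarray) -> "ThinPlateSpline":
        src = np.asarray(source, dtype=float)
        dst = np.asarray(target, dtype=float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise ShapeError("TPS needs matching (k, 2) source and target")
        k = src.shape[0]
        d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
        off = d2[~np.eye(k, dtype=bool)]
        if off.size and off.min() == 0.0:
            raise ShapeError("singular TPS system: coincident control points")
        kmat = _tps_kernel(d2)
        p = np.hstack([np.ones((k, 1)), src])
        sys = np.zeros((k + 3, k + 3))
        sys[:k, :k] = kmat
        sys[:k, k:] = p
        sys[k:, :k] = p.T
        rhs = np.zeros((k + 3, 2))
        rhs[:k] = dst
        try:
            sol = np.linalg.solve(sys, rhs)
        except np.linalg.LinAlgError as exc:
            raise ShapeError(f"singular TPS system (coincident landmarks?): {exc}")
        return cls(control=src, weights=sol[:k], affine=sol[k:])

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        d2 = ((pts[:, None, :] - self.control[None, :, :]) ** 2).sum(axis=2)
        u = _tps_kernel(d2)
        return (
            u @ self.weights
            + self.affine[0][None, :]
            + pts @ self.affine[1:]
        )

    @property
    def bending_energy(self) -> float:
        d2 = ((self.control[:, None, :] - self.control[None, :, :]) ** 2).sum(axis=2)
        kmat = _tps_kernel(d2)
        return float(sum(self.weights[:, j] @ kmat @ self.weights[:, j] for j in range(2)))


@dataclass
class DeformationGrid:
    component: int
    score: float
    grid_points: np.ndarray       # (m, 2) undeformed lattice
    warped_grid: np.ndarray       # (m, 2) lattice after warping
    warped_consensus: np.ndarray  # (k, 2) consensus displaced along the PC
    grid_shape: tuple[int, int]
    bending_energy: float


def warp_grid(
    pca: ShapePCA,
    consensus: np.ndarray,
    component: int,
    score: float,
    lattice: tuple[int, int] = (20, 20),
    margin: float = 0.10,
    score_range_factor: float = 1.5,
) -> DeformationGrid:
    """Thin-plate-spline deformation grid for a PC at a given score.

    The target shape is consensus + score * loading (reshaped to (k, 2));
    the spline is exact at the 15 landmarks and is applied to a rectangular
    lattice covering the consensus bounding box with a 10% margin. ``score``
    must lie within 1.5x the observed score range of the component.
    """
    if not 0 <= component < pca.loadings.shape[0]:
        raise ShapeError(f"component {component} out of range")
    obs = pca.scores[:, component]
    lo, hi = obs.min(), obs.max()
    half = max(abs(lo), abs(hi))
    if abs(score) > score_range_factor * half and half > 0:
        raise ShapeError(
            f"score {score} outside {score_range_factor}x the observed range "
            f"[{lo:.4g}, {hi:.4g}] of PC{component + 1}"
        )
    cons = np.asarray(consensus, dtype=float)
    target = cons + score * pca.loadings[component].reshape(cons.shape)

    mins = cons.min(axis=0)
    maxs = cons.max(axis=0)
    span = maxs - mins
    mins -= margin * span
    maxs += margin * span
    nx, ny = lattice
    gx, gy = np.meshgrid(np.linspace(mins[0], maxs[0], nx), np.linspace(mins[1], maxs[1], ny))
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    tps = ThinPlateSpline.fit(cons, target)
    return DeformationGrid(
        component=component,
        score=float(score),
        grid_points=grid,
        warped_grid=tps(grid),
        warped_consensus=tps(cons),
        grid_shape=(nx, ny),
        bending_energy=tps.bending_energy,
    )


def plot_pc_scatter(
    pca: ShapePCA,
    groups: np.ndarray | None = None,
    fossil_scores: pd.DataFrame | None = None,
    ax=None,
    ellipse_coverage: float = 0.95,
):
    """PC1 x PC2 scatter with per-group data ellipses and fossil overlays.

    Ellipses are 95% data (not confidence-of-mean) ellipses of each group's
    scores, drawn from the chi-square quantile of the 2D normal fit.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse
    from scipy.stats import chi2

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    xy = pca.scores[:, :2]
    if groups is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=10, alpha=0.6)
    else:
        groups = np.asarray(groups)
        radius = np.sqrt(chi2.ppf(ellipse_coverage, df=2))
        for g in sorted(set(groups)):
            pts = xy[groups == g]
            sc = ax.scatter(pts[:, 0], pts[:, 1], s=10, alpha=0.6, label=str(g))
            if len(pts) >= 3:
                cov = np.cov(pts.T)
                evals, evecs = np.linalg.eigh(cov)
                angle = np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1]))
                ax.add_patch(
                    Ellipse(
                        pts.mean(axis=0),
                        2 * radius * np.sqrt(evals[-1]),
                        2 * radius * np.sqrt(evals[0]),
                        angle=angle,
                        fill=False,
                        color=sc.get_facecolor()[0],
                    )
                )
        ax.legend(fontsize=7, loc="best")
    if fossil_scores is not None:
        ax.scatter(
            fossil_scores.iloc[:, 0],
            fossil_scores.iloc[:, 1],
            marker="*",
            s=120,
            color="black",
            zorder=5,
        )
        for sid, row in fossil_scores.iterrows():
            ax.annotate(str(sid), (row.iloc[0], row.iloc[1]), fontsize=7)
    ax.set_xlabel(f"PC1 ({pca.percent_variance[0]:.2f}%)")
    ax.set_ylabel(f"PC2 ({pca.percent_variance[1]:.2f}%)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    return ax
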