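"""Generalized Procrustes analysis and Procrustes distances.

Shape is what remains of a landmark configuration after translation, scale
and rotation are removed. Pairs of configurations are compared by ordinary
(orthogonal) Procrustes superimposition; a sample is aligned by generalized
Procrustes analysis (GPA): centre and scale every configuration to unit
centroid size, rotate each onto the running consensus, re-estimate the
consensus, and iterate to convergence. Aligned shapes live on a sphere in
Kendall's shape space; for linear multivariate statistics they are
orthogonally projected onto the tangent space at the consensus.

Specimens are kept at unit centroid size throughout (partial Procrustes
fit); the optional full-Procrustes scaling (cos(rho) shrink) is available
via ``gpa(..., full_procrustes=True)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class ShapeError(ValueError):
    """Degenerate or incompatible shapes."""


def _as_shape(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ShapeError(f"expected (k, 2) landmark array, got shape {x.shape}")
    return x


def centroid_size(shape: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from the centroid."""
    x = _as_shape(shape)
    if x.shape[0] < 2:
        raise ShapeError("centroid size needs at least 2 landmarks")
    cs = float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum()))
    if cs == 0.0:
        raise ShapeError("all landmarks identical: centroid size is zero")
    return cs


def center_and_scale(shape: np.ndarray) -> np.ndarray:
    """Translate centroid to the origin and scale to unit centroid size."""
    x = _as_shape(shape)
    x = x - x.mean(axis=0)
    return x / centroid_size(x)


def optimal_superimpose(
    source: np.ndarray,
    target: np.ndarray,
    allow_reflection: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superimposition of ``source`` onto ``target``.

    Both shapes are centred and scaled to unit centroid size; ``source`` is
    then rotated to minimize the summed squared landmark distances to
    ``target``. With ``allow_reflection=False`` the rotation is proper
    (determinant +1).

    Returns ``(aligned_source, rotation, residual)`` where ``residual`` is
    the minimized sum of squared coordinate differences.
    """
    a = _as_shape(source)
    b = _as_shape(target)
    if a.shape != b.shape:
        raise ShapeError(f"landmark-count mismatch: {a.shape} vs {b.shape}")
    a = center_and_scale(a)
    b = center_and_scale(b)
    # Kabsch: rotation maximizing trace(R a^T b)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection:
        corr = np.ones(2)
    else:
        corr = np.array([1.0, d])
    rot = u @ np.diag(corr) @ vt
    aligned = a @ rot
    residual = float(((aligned - b) ** 2).sum())
    return aligned, rot, residual


def procrustes_distance(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False) -> float:
    """Partial Procrustes distance: root residual after optimal superimposition."""
    _, _, residual = optimal_superimpose(a, b, allow_reflection=allow_reflection)
    return float(np.sqrt(max(residual, 0.0)))


def procrustes_distance_matrix(
    shapes: np.ndarray, ids: list[str] | None = None
) -> "ProcrustesDistanceMatrix":
    """All pairwise partial Procrustes distances among ``shapes`` (n, k, 2)."""
    shapes = np.asarray(shapes, dtype=float)
    n = shapes.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = procrustes_distance(shapes[i], shapes[j])
    return ProcrustesDistanceMatrix(ids=ids or [str(i) for i in range(n)], d=d)


@dataclass(frozen=True)
class ProcrustesDistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ShapeError("distance matrix shape does not match id list")
        if not np.allclose(d, d.T) or np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
            raise ShapeError("distance matrix must be symmetric with zero diagonal")


@dataclass
class AlignedShapes:
    """Output of GPA.

    ``consensus`` has unit centroid size and is oriented along its principal
    axes; ``procrustes_coords`` are the unit-size aligned configurations;
    ``tangent_coords`` (n, 2k) are their orthogonal projections onto the
    tangent space at the consensus.
    """

    ids: list[str]
    consensus: np.ndarray
    procrustes_coords: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    tangent_coords: np.ndarray | None = None
    objective_history: list[float] | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def tangent_frame(self) -> np.ndarray:
        if self.tangent_coords is None:
            raise ShapeError("tangent_project has not been run")
        return self.tangent_coords

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)


def _principal_axis_orient(consensus: np.ndarray) -> np.ndarray:
    """Rotation aligning the consensus to its principal axes, with a fixed
    sign rule (largest-|coordinate| positive on each axis) so the
    orientation is reproducible across runs and input orderings."""
    c = consensus - consensus.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    rot = vt.T
    if np.linalg.det(rot) < 0:  # keep a proper rotation
        rot[:, 1] = -rot[:, 1]
    oriented = c @ rot
    for axis in range(2):
        col = oriented[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            rot[:, axis] = -rot[:, axis]
            oriented[:, axis] = -oriented[:, axis]
    if np.linalg.det(rot) < 0:
        # sign fixes may have produced an improper transform; flipping the
        # minor axis restores a rotation while keeping the major-axis rule
        rot[:, 1] = -rot[:, 1]
    return rot


def gpa(
    shapes: np.ndarray,
    ids: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    allow_reflection: bool = False,
    full_procrustes: bool = False,
) -> AlignedShapes:
    """Generalized Procrustes analysis of ``shapes`` (n, k, 2).

    Iteratively superimposes every configuration on the consensus and
    re-estimates the consensus (rescaled to unit centroid size) until the
    consensus moves less than ``tol`` (root summed squared displacement) or
    ``max_iter`` is reached. The result is invariant (within tolerance) to
    specimen order and to similarity transforms of any input.
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim != 3 or shapes.shape[2] != 2:
        raise ShapeError(f"expected (n, k, 2) array, got {shapes.shape}")
    n = shapes.shape[0]
    if n < 2:
        raise ShapeError("GPA needs at least 2 shapes")
    ids = ids or [str(i) for i in range(n)]

    sizes = np.array([centroid_size(s) for s in shapes])
    aligned = np.stack([center_and_scale(s) for s in shapes])

    consensus = center_and_scale(aligned[0])
    converged = False
    it = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        for i in range(n):
            a, _, _ = optimal_superimpose(aligned[i], consensus, allow_reflection)
            if full_procrustes:
                # shrink toward the consensus by cos(rho): the full-Procrustes
                # least-squares scale beta = sum(a*c)
                a = a * float((a * consensus).sum())
            aligned[i] = a
        new_consensus = center_and_scale(aligned.mean(axis=0))
        shift = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        history.append(gpa_objective(aligned, consensus))
        if shift < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)

    # orient the consensus (and every specimen with it) along principal axes
    rot = _principal_axis_orient(consensus)
    consensus = (consensus - consensus.mean(axis=0)) @ rot
    consensus /= centroid_size(consensus)
    aligned = aligned @ rot

    return AlignedShapes(
        ids=list(ids),
        consensus=consensus,
        procrustes_coords=aligned,
        centroid_sizes=sizes,
        iterations=it,
        converged=converged,
        objective_history=history,
    )


def tangent_project(aligned: AlignedShapes) -> AlignedShapes:
    """Project aligned coordinates onto the tangent space at the consensus.

    The flattened consensus vector c (unit norm, since centroid size 1) is
    the pole; each specimen vector x is replaced by x - (x.c) c, the
    component orthogonal to c. Fills ``tangent_coords`` in place and returns
    the same object.
    """
    c = aligned.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    flat = aligned.procrustes_coords.reshape(aligned.n, -1)
    aligned.tangent_coords = flat - np.outer(flat @ c, c)
    return aligned


def project_new(aligned: AlignedShapes, shape: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Superimpose an out-of-sample configuration on the consensus and return
    its tangent-space vector (same convention as :func:`tangent_project`)."""
    a, _, _ = optimal_superimpose(shape, aligned.consensus, allow_reflection)
    c = aligned.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    x = a.reshape(-1)
    return x - (x @ c) * c


def gpa_objective(aligned_coords: np.ndarray, consensus: np.ndarray) -> float:
    """Summed squared distances of aligned specimens to the consensus."""
    return float(((aligned_coords - consensus[None]) ** 2).sum())
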