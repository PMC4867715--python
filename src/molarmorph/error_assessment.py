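"""Intra-observer digitization-error assessment.

A small panel of specimens is digitized repeatedly over several sessions.
Measurement error is summarized three ways: (1) the Procrustes distances
between all unordered pairs of repetitions of the same specimen (their mean
and SD measure how far repeated digitizations of one tooth scatter in shape
space); (2) Mantel correlations between the specimen-by-specimen Procrustes
distance matrices computed from each repetition (high r means the relative
arrangement of specimens is stable across digitization sessions); (3) a
permutational (distance-based) MANOVA with repetition as the grouping
factor — a near-zero pseudo-F with p near 1 means repetition explains none
of the shape variation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .superimposition import gpa, procrustes_distance, tangent_project


class ErrorStudyError(ValueError):
    pass


@dataclass
class RepetitionStudy:
    """Repeated digitizations: ``coords[specimen][rep]`` is a (k, 2) shape."""

    specimen_ids: list[str]
    coords: dict[str, list[np.ndarray]]
    day_labels: list[int]  # per repetition index, e.g. [1,1,1,2,2,2,3,3,3]

    def __post_init__(self) -> None:
        counts = {s: len(self.coords[s]) for s in self.specimen_ids}
        n_rep = set(counts.values())
        if len(n_rep) != 1:
            raise ErrorStudyError(f"unequal repetition counts: {counts}")
        self.n_rep = n_rep.pop()
        if self.n_rep < 2:
            raise ErrorStudyError("need at least 2 repetitions per specimen")
        if len(self.day_labels) != self.n_rep:
            raise ErrorStudyError("day_labels must have one entry per repetition")


@dataclass
class ErrorStudyResult:
    mean_pairwise_procrustes: float
    sd_pairwise_procrustes: float
    per_specimen: pd.DataFrame
    mantel_r_mean: float
    manova_F: float
    manova_p: float


def paired_repetition_distances(
    study: RepetitionStudy,
) -> tuple[float, float, pd.DataFrame]:
    """Procrustes distances over all unordered repetition pairs, per specimen.

    Returns the pooled mean, pooled SD, and a per-specimen table of the
    individual pairwise values (unit-centroid-size shapes).
    """
    records = []
    for sid in study.specimen_ids:
        reps = study.coords[sid]
        for i, j in itertools.combinations(range(len(reps)), 2):
            records.append(
                {"specimen_id": sid, "rep_i": i, "rep_j": j,
                 "procrustes_distance": procrustes_distance(reps[i], reps[j])}
            )
    table = pd.DataFrame(records)
    vals = table["procrustes_distance"].to_numpy()
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd, table


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    r is computed on the strictly-lower-triangle entries; the null
    distribution permutes the rows and columns of ``d2`` jointly. The
    p-value uses the (b + 1) / (m + 1) convention, counting the observed
    statistic as one permutation.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ErrorStudyError("matrices must be square and of equal shape")
    for d in (d1, d2):
        if not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 1e-12:
            raise ErrorStudyError("matrices must be symmetric with zero diagonal")
    n = d1.shape[0]
    if n < 3:
        raise ErrorStudyError("Mantel test needs at least 3 objects")
    tri = np.tril_indices(n, k=-1)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        av, bv = a[tri], b[tri]
        av = av - av.mean()
        bv = bv - bv.mean()
        denom = np.sqrt((av * av).sum() * (bv * bv).sum())
        if denom == 0:
            raise ErrorStudyError("constant distance matrix: Mantel r undefined")
        return float((av * bv).sum() / denom)

    r_obs = corr(d1, d2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d1, d2[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            hits += 1
    if alternative != "greater":
        raise ErrorStudyError(f"unsupported alternative {alternative!r}")
    p = (hits + 1) / (n_perm + 1)
    return r_obs, p


def _gower_center(d2: np.ndarray) -> np.ndarray:
    """Double-centred matrix of -0.5 * squared distances (Gower's G)."""
    n = d2.shape[0]
    a = -0.5 * d2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def perm_manova(
    coords: np.ndarray,
    group_labels: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Distance-based (permutational) one-way MANOVA pseudo-F.

    ``coords`` is an (n, p) matrix (e.g. tangent coordinates); Euclidean
    distances among rows define the partition SS_total = SS_between +
    SS_within via sums of squared interpoint distances:
    SS_total = sum_{i<j} d_ij^2 / n, SS_within summed per group with its own
    size. F = (SS_between / (a - 1)) / (SS_within / (N - a)); the p-value
    permutes group labels, (b + 1) / (m + 1) convention.
    """
    x = np.asarray(coords, dtype=float)
    labels = np.asarray(group_labels)
    if x.ndim != 2 or len(labels) != x.shape[0]:
        raise ErrorStudyError("coords must be (n, p) with one label per row")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ErrorStudyError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ErrorStudyError(f"group {g!r} has fewer than 2 observations")
    n = x.shape[0]
    a = len(groups)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_total = d2.sum() / (2 * n)
        ss_within = 0.0
        for g in groups:
            m = lab == g
            ng = m.sum()
            ss_within += d2[np.ix_(m, m)].sum() / (2 * ng)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if pseudo_f(labels[rng.permutation(n)]) >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(f_obs), float(p)


def repetition_distance_matrices(study: RepetitionStudy) -> list[np.ndarray]:
    """One specimen-by-specimen Procrustes distance matrix per repetition."""
    n_spec = len(study.specimen_ids)
    mats = []
    for r in range(study.n_rep):
        d = np.zeros((n_spec, n_spec))
        for i, j in itertools.combinations(range(n_spec), 2):
            d[i, j] = d[j, i] = procrustes_distance(
                study.coords[study.specimen_ids[i]][r],
                study.coords[study.specimen_ids[j]][r],
            )
        mats.append(d)
    return mats


def run_error_study(
    study: RepetitionStudy,
    n_perm: int = 999,
    seed: int | None = None,
    group_by: str = "repetition",
    mantel_pairs: str = "all",
) -> ErrorStudyResult:
    """Full repeatability analysis of a repetition study.

    The Mantel summary is the mean r over all unordered pairs of the
    repetition-specific specimen distance matrices. The MANOVA groups the
    jointly-GPA-aligned digitizations by ``repetition`` (default) or by
    ``day``.
    """
    mean_d, sd_d, table = paired_repetition_distances(study)
    per_spec = (
        table.groupby("specimen_id")["procrustes_distance"].agg(["mean", "std"]).reset_index()
    )

    mats = repetition_distance_matrices(study)
    if mantel_pairs != "all":
        raise ErrorStudyError(f"unknown mantel_pairs mode {mantel_pairs!r}")
    rs = [
        mantel(mats[i], mats[j], n_perm=0, seed=0)[0]
        for i, j in itertools.combinations(range(len(mats)), 2)
    ]
    mantel_r_mean = float(np.mean(rs))

    # one joint GPA over all digitizations, grouped by repetition (or day)
    all_shapes, labels = [], []
    for sid in study.specimen_ids:
        for r, shp in enumerate(study.coords[sid]):
            all_shapes.append(shp)
            labels.append(r if group_by == "repetition" else study.day_labels[r])
    aligned = tangent_project(gpa(np.stack(all_shapes)))
    f, p = perm_manova(aligned.tangent_coords, np.array(labels), n_perm=n_perm, seed=seed)

    return ErrorStudyResult(
        mean_pairwise_procrustes=mean_d,
        sd_pairwise_procrustes=sd_d,
        per_specimen=per_spec,
        mantel_r_mean=mantel_r_mean,
        manova_F=f,
        manova_p=p,
    )
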