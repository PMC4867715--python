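"""Linear discriminant classification of molar shapes.

PC scores of the extant sample are classified at four nested grouping
levels (family, two subfamily schemes, genus). The discriminant axes solve
the generalized eigenproblem of the between-group covariance against the
pooled within-group covariance; each eigenvalue's share of the eigenvalue
sum is the variance explained by that discriminant function. Specimens
(training cases, held-out cases, and fossils) are assigned to the group
with the smallest Mahalanobis distance to the group centroid under the
pooled covariance; posterior probabilities are prior * exp(-d^2 / 2),
normalized — the standard Gaussian equal-covariance model, so the decision
boundaries are linear. Reliability is the percentage of correctly
classified cases (pcc), before and after leave-one-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

GROUPING_LEVELS = ("family", "subfamily_G", "subfamily_R", "genus")


class DiscriminantError(ValueError):
    pass


@dataclass
class LDAModel:
    """Fitted discriminant model in the retained-PC space."""

    groups: list[str]                # sorted labels
    centroids: np.ndarray            # (g, p) group means
    pooled_cov: np.ndarray           # (p, p)
    pooled_prec: np.ndarray          # (p, p) inverse of pooled_cov
    priors: np.ndarray               # (g,)
    df_axes: np.ndarray              # (n_df, p) discriminant function axes
    df_eigenvalues: np.ndarray       # (n_df,)
    n_components_in: int

    def mahalanobis_sq(self, x: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of row(s) ``x`` to every centroid."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.centroids.shape[1]:
            raise DiscriminantError(
                f"dimension mismatch: case has {x.shape[1]} features, "
                f"model uses {self.centroids.shape[1]}"
            )
        diff = x[:, None, :] - self.centroids[None, :, :]
        return np.einsum("ngp,pq,ngq->ng", diff, self.pooled_prec, diff)

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        d2 = self.mahalanobis_sq(x)
        # subtract the row minimum before exponentiating for stability
        logp = np.log(self.priors)[None, :] - 0.5 * d2
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        post = self.posteriors(x)
        # argmax with deterministic lexicographic tie-break (groups sorted)
        best = post.argmax(axis=1)
        ties = (post == post[np.arange(len(post)), best][:, None]).sum(axis=1) > 1
        if ties.any():
            logger.warning("posterior ties broken lexicographically for %d case(s)", ties.sum())
        return np.array([self.groups[b] for b in best])


@dataclass
class LDAResult:
    factor: str
    model: LDAModel
    df_percent: np.ndarray
    pcc_original: float
    pcc_crossval: float | None
    confusion_original: pd.DataFrame
    confusion_crossval: pd.DataFrame | None
    posteriors: pd.DataFrame | None = None   # rows = unknown specimens
    predicted: pd.Series | None = None


def _validate_groups(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise DiscriminantError("need at least 2 groups")
    counts = {g: int((labels == g).sum()) for g in groups}
    singletons = [g for g, c in counts.items() if c < 2]
    if singletons:
        raise DiscriminantError(f"groups with fewer than 2 specimens: {singletons}")
    return labels, groups


def select_n_components(
    scores: np.ndarray, labels: np.ndarray, max_components: int | None = None,
    cond_limit: float = 1e8,
) -> int:
    """Largest PC count whose pooled within-group covariance is well
    conditioned (condition number below ``cond_limit``)."""
    labels, groups = _validate_groups(labels)
    n, p_all = scores.shape
    p = min(max_components or p_all, p_all, n - len(groups))
    while p > 1:
        sw = _pooled_cov(scores[:, :p], labels, groups)
        if np.linalg.cond(sw) < cond_limit:
            break
        p -= 1
    return p


def _pooled_cov(x: np.ndarray, labels: np.ndarray, groups: list[str]) -> np.ndarray:
    n, p = x.shape
    sw = np.zeros((p, p))
    for g in groups:
        xg = x[labels == g]
        xc = xg - xg.mean(axis=0)
        sw += xc.T @ xc
    return sw / (n - len(groups))


def _fit_model(
    scores: np.ndarray,
    labels: np.ndarray,
    n_components_in: int | None,
    priors: str | np.ndarray,
) -> tuple[LDAModel, np.ndarray, np.ndarray]:
    """Core model fit; returns (model, df_percent, truncated design matrix)."""
    scores = np.asarray(scores, dtype=float)
    labels, groups = _validate_groups(labels)
    if n_components_in is None:
        n_components_in = select_n_components(scores, labels)
    x = scores[:, :n_components_in]
    n, p = x.shape
    g = len(groups)

    centroids = np.stack([x[labels == gr].mean(axis=0) for gr in groups])
    sw = _pooled_cov(x, labels, groups)
    cond = np.linalg.cond(sw)
    if cond > 1e12:
        raise DiscriminantError(
            f"pooled within-group covariance is singular (cond={cond:.2g}); "
            "retain fewer PCs"
        )
    grand = x.mean(axis=0)
    counts = np.array([(labels == gr).sum() for gr in groups])
    dev = centroids - grand
    sb = (counts[:, None] * dev).T @ dev / (g - 1)

    # generalized eigenproblem Sb v = lambda Sw v; top min(g-1, p) axes
    evals, evecs = scipy.linalg.eigh(sb, sw)
    order = np.argsort(evals)[::-1]
    n_df = min(g - 1, p)
    df_eig = np.clip(evals[order][:n_df], 0.0, None)
    df_axes = evecs[:, order][:, :n_df].T
    df_percent = 100.0 * df_eig / df_eig.sum() if df_eig.sum() > 0 else np.zeros(n_df)

    if isinstance(priors, str):
        if priors == "equal":
            prior_vec = np.full(g, 1.0 / g)
        elif priors == "proportional":
            prior_vec = counts / counts.sum()
        else:
            raise DiscriminantError(f"unknown priors {priors!r}")
    else:
        prior_vec = np.asarray(priors, dtype=float)
        if prior_vec.shape != (g,) or not np.isclose(prior_vec.sum(), 1.0):
            raise DiscriminantError("explicit priors must be a probability vector over groups")

    model = LDAModel(
        groups=groups,
        centroids=centroids,
        pooled_cov=sw,
        pooled_prec=np.linalg.inv(sw),
        priors=prior_vec,
        df_axes=df_axes,
        df_eigenvalues=df_eig,
        n_components_in=n_components_in,
    )
    return model, df_percent, x


def fit_lda(
    scores: np.ndarray,
    labels: np.ndarray,
    n_components_in: int | None = None,
    priors: str | np.ndarray = "equal",
) -> LDAResult:
    """Fit the discriminant model and classify the training cases.

    ``scores`` is the (n, p) PC-score matrix; ``n_components_in`` retains
    the first PCs (default: as many as keep the pooled covariance well
    conditioned). ``priors`` is ``"equal"``, ``"proportional"``, or an
    explicit vector over the sorted group labels.
    """
    labels = np.asarray(labels)
    model, df_percent, x = _fit_model(scores, labels, n_components_in, priors)
    pred = model.predict(x)
    confusion = confusion_matrix(labels, pred, model.groups)
    pcc = 100.0 * float((pred == labels).mean())
    return LDAResult(
        factor="",
        model=model,
        df_percent=df_percent,
        pcc_original=pcc,
        pcc_crossval=None,
        confusion_original=confusion,
        confusion_crossval=None,
    )


def confusion_matrix(true: np.ndarray, pred: np.ndarray, groups: list[str]) -> pd.DataFrame:
    index = {g: i for i, g in enumerate(groups)}
    mat = np.zeros((len(groups), len(groups)), dtype=int)
    np.add.at(
        mat,
        (
            np.array([index[t] for t in true]),
            np.array([index[p] for p in pred]),
        ),
        1,
    )
    out = pd.DataFrame(mat, index=groups, columns=groups)
    out.index.name = "true"
    out.columns.name = "predicted"
    return out


def loocv_pcc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_components_in: int | None = None,
    priors: str | np.ndarray = "equal",
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated pcc: refit on n-1 cases, classify the
    held-out one. A fold that would empty a group classifies the held-out
    case against the remaining groups, with a warning."""
    scores = np.asarray(scores, dtype=float)
    labels, groups = _validate_groups(labels)
    if n_components_in is None:
        n_components_in = select_n_components(scores, labels)
    n = len(labels)
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_labels = labels[mask]
        remaining = sorted(set(train_labels.tolist()))
        if len(remaining) < len(groups):
            logger.warning(
                "LOOCV fold %d removes the last member of a group; classifying "
                "against the remaining %d groups", i, len(remaining)
            )
        model, _, _ = _fit_model(scores[mask], train_labels, n_components_in, priors)
        preds.append(model.predict(scores[i, :n_components_in])[0])
    preds = np.array(preds)
    confusion = confusion_matrix(labels, preds, groups)
    return 100.0 * float((preds == labels).mean()), confusion


def classify_unknown(result: LDAResult, case_scores: np.ndarray) -> tuple[np.ndarray, str]:
    """Posterior probability per group and predicted label for one case
    (given as a vector of PC scores in the same space the model was fit in)."""
    x = np.asarray(case_scores, dtype=float).reshape(1, -1)[:, : result.model.n_components_in]
    post = result.model.posteriors(x)[0]
    pred = result.model.predict(x)[0]
    return post, pred


def run_lda_factor(
    scores: np.ndarray,
    labels: np.ndarray,
    factor: str,
    unknown_scores: pd.DataFrame | None = None,
    n_components_in: int | None = None,
    priors: str | np.ndarray = "equal",
    crossval: bool = True,
) -> LDAResult:
    """Fit one grouping factor end to end: training classification, LOOCV,
    and posterior classification of any unknown (fossil) cases."""
    res = fit_lda(scores, labels, n_components_in, priors)
    res.factor = factor
    if crossval:
        res.pcc_crossval, res.confusion_crossval = loocv_pcc(
            scores, labels, res.model.n_components_in, priors
        )
    if unknown_scores is not None and len(unknown_scores):
        rows, preds = [], []
        for sid, row in unknown_scores.iterrows():
            post, pred = classify_unknown(res, row.to_numpy())
            rows.append(post)
            preds.append(pred)
        res.posteriors = pd.DataFrame(
            np.stack(rows), index=unknown_scores.index, columns=res.model.groups
        )
        res.predicted = pd.Series(preds, index=unknown_scores.index, name="predicted")
    return res


def run_all_ldas(
    scores: np.ndarray,
    taxonomy_labels: dict[str, np.ndarray],
    unknown_scores: pd.DataFrame | None = None,
    n_components_in: int | None = None,
    priors: str | np.ndarray = "equal",
    crossval: bool = True,
) -> dict[str, LDAResult]:
    """Run the LDA at every grouping level in ``taxonomy_labels``
    (factor name -> per-specimen labels, aligned with ``scores`` rows)."""
    out = {}
    for factor in taxonomy_labels:
        out[factor] = run_lda_factor(
            scores,
            taxonomy_labels[factor],
            factor,
            unknown_scores=unknown_scores,
            n_components_in=n_components_in,
            priors=priors,
            crossval=crossval,
        )
    return out


def summary_table(results: dict[str, LDAResult]) -> pd.DataFrame:
    """Machine-readable summary: DF1/DF2 variance shares, original and
    cross-validated pcc, per grouping factor (the published table layout)."""
    rows = {}
    for factor, res in results.items():
        dfp = res.df_percent
        rows[factor] = {
            "DF1": float(dfp[0]) if len(dfp) > 0 else np.nan,
            "DF2": float(dfp[1]) if len(dfp) > 1 else np.nan,
            "Classification": res.pcc_original,
            "Cross-validation": res.pcc_crossval,
            "n_pcs": res.model.n_components_in,
            "n_groups": len(res.model.groups),
        }
    return pd.DataFrame(rows).T
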