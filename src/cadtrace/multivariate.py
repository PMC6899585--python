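"""PCA, two-class OPLS-DA, S-plot and threshold-based feature selection.

OPLS-DA splits the predictor variance of a feature matrix into one component
predictive of a two-class contrast (transgenic vs control, coded +1/-1) and
components orthogonal to it (orthogonal signal correction, OSC).  The S-plot
then scatters, per feature, the covariance p[1] between the predictive score
t and the feature column against their Pearson correlation p(corr)[1];
features extreme in both are reliable class markers.  Selection applies the
cut-offs |p[1]| > 0.02 and |p(corr)[1]| > 0.02 on the scaled matrix.

Model quality is summarized by R2X (predictive), R2X (orthogonal, cumulative)
and the cross-validated Q2 (cumulative) = 1 - PRESS/SS over held-out class
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .feature_core import FeatureID, FeatureMatrix

SCALING_MODES = ("center", "unit_variance", "pareto")


class MultivariateError(ValueError):
    pass


# -- preprocessing ---------------------------------------------------------


@dataclass
class ScaledData:
    """A centered/scaled samples x features matrix with inversion info.

    Constant (zero-variance) columns cannot be variance-scaled; they are
    dropped with a warning and recorded in ``dropped``.
    """

    X: np.ndarray
    scaling: str
    means: np.ndarray
    scales: np.ndarray
    feature_ids: list[FeatureID] | None = None
    dropped: list[FeatureID] | None = None


def scale_matrix(X: np.ndarray, scaling: str = "unit_variance",
                 feature_ids: list[FeatureID] | None = None) -> ScaledData:
    """Center and scale a samples x features matrix.

    ``center`` subtracts column means; ``unit_variance`` additionally divides
    by the column SD; ``pareto`` divides by sqrt(SD) (the S-plot literature's
    compromise that keeps part of the intensity information).
    """
    if scaling not in SCALING_MODES:
        raise MultivariateError(f"unknown scaling {scaling!r}; expected {SCALING_MODES}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise MultivariateError("need a 2-D matrix with >= 2 samples")
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = np.ones(X.shape[1], dtype=bool)
    dropped: list[FeatureID] = []
    if scaling in ("unit_variance", "pareto"):
        keep = sd > 0
        if not np.all(keep):
            if feature_ids is not None:
                dropped = [f for f, k in zip(feature_ids, keep) if not k]
            warnings.warn(f"dropping {int((~keep).sum())} constant column(s) "
                          f"before {scaling} scaling")
    scales = np.ones_like(sd)
    if scaling == "unit_variance":
        scales = np.where(keep, sd, 1.0)
    elif scaling == "pareto":
        scales = np.where(keep, np.sqrt(sd), 1.0)
    Xs = (X[:, keep] - means[keep]) / scales[keep]
    kept_ids = None
    if feature_ids is not None:
        kept_ids = [f for f, k in zip(feature_ids, keep) if k]
    return ScaledData(Xs, scaling, means[keep], scales[keep], kept_ids, dropped)


def scaled_from_matrix(matrix: FeatureMatrix,
                       scaling: str = "unit_variance") -> ScaledData:
    """Scale a FeatureMatrix (features x samples) into samples x features."""
    return scale_matrix(matrix.intensities.T, scaling, list(matrix.features))


# -- PCA -------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray           # samples x components
    loadings: np.ndarray         # features x components
    explained_variance_ratio: np.ndarray


def fit_pca(data: ScaledData, n_components: int = 2) -> PcaResult:
    """PCA by singular-value decomposition of the scaled matrix."""
    X = data.X
    if X.shape[0] < 2:
        raise MultivariateError("PCA needs at least 2 samples")
    rank = min(X.shape)
    if not 1 <= n_components <= rank:
        raise MultivariateError(f"n_components must lie in [1, {rank}]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(X ** 2))
    ratio = (s ** 2) / total if total > 0 else np.zeros_like(s)
    return PcaResult(U[:, :n_components] * s[:n_components],
                     Vt[:n_components].T,
                     ratio[:n_components])


# -- OPLS-DA ---------------------------------------------------------------


@dataclass
class OplsModel:
    """One predictive + ``n_orthogonal`` orthogonal components of an OPLS-DA fit."""

    y: np.ndarray
    t: np.ndarray                 # predictive scores
    w: np.ndarray                 # predictive weights (unit norm)
    p: np.ndarray                 # predictive loadings X't/(t't)
    t_orth: np.ndarray            # samples x n_orthogonal
    p_orth: np.ndarray            # features x n_orthogonal
    w_orth: np.ndarray            # features x n_orthogonal
    r2x_predictive: float
    r2x_orthogonal: float
    q2_cumulative: float | None = None
    c: float = 0.0                # inner relation y ~ c * t

    @property
    def n_orthogonal(self) -> int:
        return self.t_orth.shape[1]

    def summary(self) -> dict[str, float]:
        out = {"R2X_predictive": self.r2x_predictive,
               "R2X_orthogonal": self.r2x_orthogonal,
               "n_orthogonal": float(self.n_orthogonal)}
        if self.q2_cumulative is not None:
            out["Q2_cumulative"] = self.q2_cumulative
        return out


def _check_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if not (len(classes) == 2 and set(classes) == {-1.0, 1.0}):
        raise MultivariateError("y must contain both classes coded +1/-1")
    return y


def fit_oplsda(data: ScaledData, y: np.ndarray, n_orthogonal: int = 0) -> OplsModel:
    """Fit orthogonal-signal-corrected PLS-DA.

    Iteratively extracts ``n_orthogonal`` components of X-variation orthogonal
    to the class contrast, deflates them from X, then fits a one-component
    PLS1 on the filtered matrix.  With ``n_orthogonal=0`` this reduces
    exactly to the first NIPALS PLS1 component.  The predictive weight sign
    is fixed so that the mean score of class +1 is positive.
    """
    y = _check_two_class(y)
    X = np.array(data.X, dtype=float)
    n, k = X.shape
    if len(y) != n:
        raise MultivariateError("y length does not match number of samples")
    if n_orthogonal < 0:
        raise MultivariateError("n_orthogonal must be >= 0")
    rank = np.linalg.matrix_rank(X)
    if n_orthogonal >= rank:
        raise MultivariateError(f"n_orthogonal={n_orthogonal} >= rank {rank}")
    yc = y - y.mean()
    ss_x = float(np.sum(X ** 2))

    w = X.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise MultivariateError("X carries no covariance with y")
    w = w / norm

    t_orths, p_orths, w_orths = [], [], []
    for _ in range(n_orthogonal):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:        # no orthogonal variation left
            break
        w_o = w_o / n_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        t_orths.append(t_o)
        p_orths.append(p_o)
        w_orths.append(w_o)
        # re-derive the predictive weight on the deflated matrix
        w = X.T @ yc
        w = w / np.linalg.norm(w)

    t = X @ w
    if t[y > 0].mean() < 0:    # sign convention: class +1 scores positive
        w, t = -w, -t
    p = X.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))

    t_orth = np.column_stack(t_orths) if t_orths else np.zeros((n, 0))
    p_orth = np.column_stack(p_orths) if p_orths else np.zeros((k, 0))
    w_orth = np.column_stack(w_orths) if w_orths else np.zeros((k, 0))
    r2x_pred = float(np.sum(np.outer(t, p) ** 2) / ss_x) if ss_x > 0 else 0.0
    r2x_orth = 0.0
    for t_o, p_o in zip(t_orths, p_orths):
        r2x_orth += float(np.sum(np.outer(t_o, p_o) ** 2) / ss_x)
    return OplsModel(y, t, w, p, t_orth, p_orth, w_orth, r2x_pred, r2x_orth, c=c)


def predict_scores(model: OplsModel, X_new: np.ndarray) -> np.ndarray:
    """Project new (already scaled) samples: strip orthogonal variation, score."""
    X = np.array(X_new, dtype=float)
    for j in range(model.n_orthogonal):
        t_o = X @ model.w_orth[:, j]
        X = X - np.outer(t_o, model.p_orth[:, j])
    return X @ model.w


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    assignments = np.empty(len(y), dtype=int)
    for cls in (-1.0, 1.0):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, sample in enumerate(idx):
            assignments[sample] = pos % folds
    return [np.flatnonzero(assignments == f) for f in range(folds)]


def q2_cross_validation(data: ScaledData, y: np.ndarray, folds: int = 7,
                        seed: int = 0, n_orthogonal: int = 0) -> float:
    """Cross-validated Q2 = 1 - PRESS/SS with class-stratified folds.

    Folds are assigned per class round-robin after a seeded shuffle, so every
    fold contains both classes whenever each class has >= ``folds`` members;
    otherwise folds lacking a class are refit without stratification errors
    by skipping the missing-class check at train time (training always
    retains both classes when folds <= min class size).
    """
    y = _check_two_class(y)
    n = len(y)
    if not 2 <= folds <= n:
        raise MultivariateError("folds must lie in [2, n_samples]")
    min_class = min(int(np.sum(y == c)) for c in (-1.0, 1.0))
    if folds > min_class and min_class >= 2:
        folds = min_class  # refold so every training split keeps both classes
    rng = np.random.default_rng(seed)
    fold_idx = _stratified_folds(y, folds, rng)
    yc = y - y.mean()
    press = 0.0
    for test in fold_idx:
        if len(test) == 0:
            continue
        train = np.setdiff1d(np.arange(n), test)
        if len(np.unique(y[train])) < 2:
            raise MultivariateError("a training fold lost one class entirely")
        sub = ScaledData(data.X[train], data.scaling, data.means, data.scales)
        model = fit_oplsda(sub, y[train], n_orthogonal)
        t_new = predict_scores(model, data.X[test])
        y_hat = model.c * t_new + y[train].mean()
        press += float(np.sum((y[test] - y_hat) ** 2))
    ss = float(np.sum(yc ** 2))
    return 1.0 - press / ss


def fit_oplsda_auto(data: ScaledData, y: np.ndarray, folds: int = 7,
                    seed: int = 0, max_orthogonal: int = 5,
                    q2_improvement: float = 0.01) -> OplsModel:
    """Add orthogonal components while cross-validated Q2 improves by > 0.01."""
    y = _check_two_class(y)
    rank = np.linalg.matrix_rank(data.X)
    best_n = 0
    best_q2 = q2_cross_validation(data, y, folds, seed, 0)
    for n_orth in range(1, min(max_orthogonal, rank - 1) + 1):
        q2 = q2_cross_validation(data, y, folds, seed, n_orth)
        if q2 > best_q2 + q2_improvement:
            best_q2, best_n = q2, n_orth
        else:
            break
    model = fit_oplsda(data, y, best_n)
    model.q2_cumulative = best_q2
    return model


# -- S-plot and selection --------------------------------------------------


@dataclass(frozen=True)
class SPlotPoint:
    """Per-feature covariance/correlation with the predictive score."""

    feature: FeatureID | int
    p1: float      # cov(t, x_j), 1/(n-1) normalization
    pcorr: float   # corr(t, x_j); 0 (flagged) for zero-variance columns
    zero_variance: bool = False


@dataclass(frozen=True)
class SelectionParams:
    p1_cutoff: float = 0.02
    pcorr_cutoff: float = 0.02

    def __post_init__(self) -> None:
        if self.p1_cutoff <= 0 or self.pcorr_cutoff <= 0:
            raise MultivariateError("selection cut-offs must be > 0")


def splot(model: OplsModel, data: ScaledData) -> list[SPlotPoint]:
    """Covariance and correlation of every feature with the predictive score."""
    X = data.X
    if X.shape[0] != len(model.t):
        raise MultivariateError("model and data disagree on sample count")
    n = X.shape[0]
    t = model.t - model.t.mean()
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ t / (n - 1)
    sd_x = Xc.std(axis=0, ddof=1)
    sd_t = t.std(ddof=1)
    points = []
    ids = data.feature_ids if data.feature_ids is not None else list(range(X.shape[1]))
    for j, fid in enumerate(ids):
        if sd_x[j] == 0 or sd_t == 0:
            points.append(SPlotPoint(fid, float(cov[j]), 0.0, zero_variance=True))
        else:
            points.append(SPlotPoint(fid, float(cov[j]),
                                     float(cov[j] / (sd_x[j] * sd_t))))
    return points


def select_differential(points: list[SPlotPoint],
                        params: SelectionParams = SelectionParams()
                        ) -> tuple[list[SPlotPoint], list[SPlotPoint]]:
    """Partition features passing both cut-offs by sign.

    Returns ``(case, control)``: positive p1/pcorr features associate with
    the class coded +1, negative with the class coded -1.
    """
    case, control = [], []
    for pt in points:
        if pt.zero_variance:
            continue
        if abs(pt.p1) > params.p1_cutoff and abs(pt.pcorr) > params.pcorr_cutoff:
            (case if pt.p1 > 0 else control).append(pt)
    return case, control
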