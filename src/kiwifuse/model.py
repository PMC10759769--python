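"""Feature fusion, PCA reduction and grid-searched SVM/SVR modeling.

The modeling protocol:

* feature-level fusion: the 46 visual features concatenated with the 13 MSR
  aroma features into one 59-element vector;
* standardization (calibration statistics only) followed by PCA, keeping the
  first four principal components by default;
* a degree-2 polynomial-kernel SVM (classification) or SVR (regression),
  grid-searched over cost c and gamma in {0.01, 0.1, 1, 10, 100} — 25
  candidates — selecting the pair with the smallest 10-fold cross-validation
  RMSE (classification RMSE is taken on the integer region codes 1..3);
* reporting RMSE plus accuracy (classification) or R^2 (regression) for the
  calibration fit, the pooled cross-validation predictions, and the held-out
  test third.

No statistic leaks: scaling and PCA are fit on calibration data and reused,
frozen, on test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SkPCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

__all__ = [
    "FusedFeatureVector",
    "PCAModel",
    "SVMConfig",
    "FitReport",
    "GridSearchResult",
    "split_dataset",
    "split_indices",
    "fuse_features",
    "fit_pca",
    "grid_search_svm",
    "grid_search_svr",
    "evaluate_classifier",
    "evaluate_regressor",
]


@dataclass(frozen=True)
class FusedFeatureVector:
    """Concatenation of the 46 image features then the 13 e-nose features."""

    values: np.ndarray

    def __post_init__(self):
        if np.asarray(self.values).shape != (59,):
            raise ValueError("a fused feature vector has exactly 59 entries")


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameter grid: degree-2 polynomial kernel, 5 x 5 (c, gamma)."""

    degree: int = 2
    costs: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    gammas: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    coef0: float = 1.0
    # solver iteration cap: degenerate grid extremes (near-constant or huge
    # polynomial kernels) can stall libsvm's SMO loop indefinitely; capped
    # fits simply score poorly in CV and lose the grid search
    max_iter: int = 20000

    @property
    def grid(self) -> list:
        """(c, gamma) pairs in row-major order; ties resolve to the first."""
        return [(c, g) for c in self.costs for g in self.gammas]


@dataclass(frozen=True)
class FitReport:
    """Metrics for one stage of one fitted model.

    ``rmse`` is in target units (integer class codes for classifiers);
    ``accuracy`` and ``r_squared`` are percentages.
    """

    stage: str                     # calibration | validation | test
    rmse: float
    accuracy: float | None = None  # classification only
    r_squared: float | None = None  # regression only
    c: float | None = None
    gamma: float | None = None

    def as_dict(self) -> dict:
        d = {"stage": self.stage, "rmse": self.rmse}
        if self.accuracy is not None:
            d["accuracy"] = self.accuracy
        if self.r_squared is not None:
            d["r_squared"] = self.r_squared
        if self.c is not None:
            d.update(c=self.c, gamma=self.gamma)
        return d


@dataclass
class GridSearchResult:
    """A fitted estimator plus its per-stage reports and full candidate log."""

    estimator: object
    best_c: float
    best_gamma: float
    reports: dict                       # stage -> FitReport
    candidates: list = field(default_factory=list)  # (c, gamma, cv_rmse)


# ---------------------------------------------------------------------------
# splitting and fusion
# ---------------------------------------------------------------------------

def split_indices(labels, seed: int, test_fraction: float = 1.0 / 3.0):
    """Stratified calibration/test split of index positions.

    Per class the test share is rounded up (ceil of n * test_fraction);
    reproducible from the seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    cal_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
        idx = rng.permutation(idx)
        n_test = int(np.ceil(len(idx) * test_fraction))
        test_idx.extend(idx[:n_test])
        cal_idx.extend(idx[n_test:])
    return np.sort(cal_idx), np.sort(test_idx)


def split_dataset(samples, seed: int):
    """Stratified 2/3-1/3 split of labeled samples (objects with ``.label``)."""
    labels = [s.label for s in samples]
    cal_idx, test_idx = split_indices(labels, seed)
    return [samples[i] for i in cal_idx], [samples[i] for i in test_idx]


def fuse_features(img_vector, enose_vector) -> FusedFeatureVector:
    """Concatenate image (46) then e-nose (13) features into 59 values."""
    img = np.asarray(getattr(img_vector, "values", img_vector), dtype=float)
    eno = np.asarray(getattr(enose_vector, "values", enose_vector), dtype=float)
    if img.shape != (46,):
        raise ValueError(f"image block must have 46 entries, got {img.shape}")
    if eno.shape != (13,):
        raise ValueError(f"e-nose block must have 13 entries, got {eno.shape}")
    return FusedFeatureVector(values=np.concatenate([img, eno]))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class PCAModel:
    """Standardize-then-PCA transform frozen on calibration statistics.

    Features are z-scored with calibration means/sds (correlation-structure
    PCA: image areas in pixels and MSR fractions differ by orders of
    magnitude), constant features are dropped with a warning, and the
    leading ``n_components`` loadings are kept.
    """

    def __init__(self, means, sds, keep, components, explained_variance_ratio):
        self.means = means
        self.sds = sds
        self.keep = keep                       # boolean column filter
        self.components = components           # (n_components, n_kept)
        self.explained_variance_ratio = explained_variance_ratio
        self.n_components = components.shape[0]

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X[:, self.keep] - self.means[self.keep]) / self.sds[self.keep]
        return Z @ self.components.T


def fit_pca(X_cal, n_components: int = 4) -> PCAModel:
    """Fit the standardized PCA on calibration features."""
    X = np.asarray(X_cal, dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} samples, got {X.shape[0]}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s) "
                      "before PCA", stacklevel=2)
    sds = np.where(keep, sds, 1.0)
    Z = (X[:, keep] - means[keep]) / sds[keep]
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    return PCAModel(means=means, sds=sds, keep=keep,
                    components=pca.components_,
                    explained_variance_ratio=pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate_classifier(y_true, y_pred):
    """(accuracy %, RMSE on integer class codes)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    accuracy = 100.0 * np.mean(y_true == y_pred)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return float(accuracy), rmse


def evaluate_regressor(y_true, y_pred):
    """(RMSE in target units, R^2 as a percentage)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("target vectors differ in length")
    if y_true.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant truth: R^2 undefined")
    ss_res = np.sum((y_true - y_pred) ** 2)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return rmse, float(100.0 * (1.0 - ss_res / ss_tot))


# ---------------------------------------------------------------------------
# grid searches
# ---------------------------------------------------------------------------

def _make_svc(c, gamma, config):
    return SVC(kernel="poly", degree=config.degree, C=c, gamma=gamma,
               coef0=config.coef0, max_iter=config.max_iter)


def grid_search_svm(X, y, config: SVMConfig | None = None, folds: int = 10,
                    seed: int = 0, X_test=None, y_test=None) -> GridSearchResult:
    """Grid-search a polynomial SVM classifier by 10-fold CV RMSE.

    ``y`` holds integer class codes (e.g. 1 = Talesh, 2 = Langarud,
    3 = Rasht); CV RMSE is computed on those codes.  The winning (c, gamma)
    pair (first in row-major grid order on ties) is refit on all calibration
    data.  Pass ``X_test``/``y_test`` to also produce the test-stage report.
    """
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if np.unique(y).size < 2:
        raise ValueError("classification needs at least 2 classes")

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    candidates = []
    best = None
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for c, g in config.grid:
            pred = np.empty_like(y)
            for tr, va in splits:
                clf = _make_svc(c, g, config).fit(X[tr], y[tr])
                pred[va] = clf.predict(X[va])
            _, rmse = evaluate_classifier(y, pred)
            candidates.append((c, g, rmse))
            if best is None or rmse < best[2]:
                best = (c, g, rmse, pred.copy())
        c, g, cv_rmse, cv_pred = best

        est = _make_svc(c, g, config).fit(X, y)
    cal_acc, cal_rmse = evaluate_classifier(y, est.predict(X))
    val_acc, _ = evaluate_classifier(y, cv_pred)
    reports = {
        "calibration": FitReport("calibration", cal_rmse, accuracy=cal_acc,
                                 c=c, gamma=g),
        "validation": FitReport("validation", cv_rmse, accuracy=val_acc,
                                c=c, gamma=g),
    }
    if X_test is not None:
        t_acc, t_rmse = evaluate_classifier(y_test, est.predict(np.asarray(X_test, dtype=float)))
        reports["test"] = FitReport("test", t_rmse, accuracy=t_acc, c=c, gamma=g)
    return GridSearchResult(estimator=est, best_c=c, best_gamma=g,
                            reports=reports, candidates=candidates)


class _ScaledSVR:
    """SVR fit on a z-scored target; predictions are back-transformed.

    The epsilon-insensitive tube is scale-dependent and the physicochemical
    targets span three orders of magnitude, so the target is standardized
    with training statistics before fitting.
    """

    def __init__(self, c, gamma, config, epsilon=0.05):
        self._svr = SVR(kernel="poly", degree=config.degree, C=c, gamma=gamma,
                        coef0=config.coef0, epsilon=epsilon,
                        max_iter=config.max_iter)

    def fit(self, X, y):
        self._mu = float(np.mean(y))
        self._sd = float(np.std(y)) or 1.0
        self._svr.fit(X, (y - self._mu) / self._sd)
        return self

    def predict(self, X):
        return self._svr.predict(X) * self._sd + self._mu


def grid_search_svr(X, y, config: SVMConfig | None = None, folds: int = 10,
                    seed: int = 0, X_test=None, y_test=None) -> GridSearchResult:
    """Grid-search a polynomial SVR by 10-fold CV RMSE (same protocol)."""
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if not np.all(np.isfinite(y)):
        raise ValueError("target values must be finite")
    if np.ptp(y) == 0:
        raise ValueError("constant target: nothing to regress")

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X))
    candidates = []
    best = None
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for c, g in config.grid:
            pred = np.empty_like(y)
            for tr, va in splits:
                reg = _ScaledSVR(c, g, config).fit(X[tr], y[tr])
                pred[va] = reg.predict(X[va])
            rmse, _ = evaluate_regressor(y, pred)
            candidates.append((c, g, rmse))
            if best is None or rmse < best[2]:
                best = (c, g, rmse, pred.copy())
        c, g, cv_rmse, cv_pred = best

        est = _ScaledSVR(c, g, config).fit(X, y)
    cal_rmse, cal_r2 = evaluate_regressor(y, est.predict(X))
    _, val_r2 = evaluate_regressor(y, cv_pred)
    reports = {
        "calibration": FitReport("calibration", cal_rmse, r_squared=cal_r2,
                                 c=c, gamma=g),
        "validation": FitReport("validation", cv_rmse, r_squared=val_r2,
                                c=c, gamma=g),
    }
    if X_test is not None:
        t_rmse, t_r2 = evaluate_regressor(
            np.asarray(y_test, dtype=float),
            est.predict(np.asarray(X_test, dtype=float)))
        reports["test"] = FitReport("test", t_rmse, r_squared=t_r2, c=c, gamma=g)
    return GridSearchResult(estimator=est, best_c=c, best_gamma=g,
                            reports=reports, candidates=candidates)
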