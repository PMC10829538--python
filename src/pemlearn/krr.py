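"""Kernel ridge regression with a Gaussian kernel.

One separate KRR model is trained per potential-energy surface or per
diabatic matrix element.  With the Gaussian kernel

    k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))

the coefficients have the closed form alpha = (K + lambda I)^-1 y, solved by
Cholesky factorization.  The correction loop retrains on the same kernel
matrix with many different targets, so the factorization is computed once
per (X, sigma, lambda) and reused (a :class:`KernelWorkspace`); leave-one-out
predictions come from the closed-form identity

    y_i - yhat_{-i}(x_i) = alpha_i / [(K + lambda I)^-1]_ii

rather than n refits.

Hyperparameters (sigma, lambda) are selected on a grid by k-fold
cross-validation (default 10-fold); model-selection scores that must not be
optimistically biased use nested (double) cross-validation, where each outer
training fold runs its own inner grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist, pdist


class SingularKernelError(np.linalg.LinAlgError):
    """K + lambda*I is not positive definite (e.g. duplicate rows at lambda=0)."""


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def gaussian_kernel(x1, x2, sigma: float) -> float:
    """exp(-||x1-x2||^2 / (2 sigma^2)); 1 iff x1 == x2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((np.asarray(x1, float) - np.asarray(x2, float)) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def kernel_matrix(X, Y=None, sigma: float = 1.0) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = _as_matrix(X)
    Y = X if Y is None else _as_matrix(Y)
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def median_pairwise_distance(X) -> float:
    """Median Euclidean feature distance; the scale anchor for the sigma grid."""
    d = pdist(_as_matrix(X))
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def default_sigma_grid(X, n: int = 9) -> np.ndarray:
    """Log-spaced over [1e-2, 1e2] x (median pairwise distance)."""
    return median_pairwise_distance(X) * np.logspace(-2, 2, n)


def default_lambda_grid(n: int = 12) -> np.ndarray:
    return np.logspace(-12, -1, n)


class KernelWorkspace:
    """Cached Cholesky factorization of K + lambda*I for one (X, sigma, lambda).

    All per-surface / per-matrix-element models during the correction loop
    share this factorization; only the target vector changes.
    """

    def __init__(self, X, sigma: float, lam: float):
        self.X = _as_matrix(X)
        self.sigma = float(sigma)
        self.lam = float(lam)
        n = self.X.shape[0]
        K = kernel_matrix(self.X, sigma=sigma)
        self.K = K
        try:
            self._cho = cho_factor(K + lam * np.eye(n), lower=True)
        except np.linalg.LinAlgError as exc:
            raise SingularKernelError(self._diagnose_singularity()) from exc
        self._kinv_diag: np.ndarray | None = None

    def _diagnose_singularity(self) -> str:
        d2 = cdist(self.X, self.X, metric="sqeuclidean")
        np.fill_diagonal(d2, np.inf)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        if d2[i, j] < 1e-24:
            return (
                f"kernel system singular: training rows {min(i, j)} and {max(i, j)} "
                f"are duplicates (distance < 1e-12) and lambda = {self.lam}"
            )
        return "kernel system not positive definite"

    def solve(self, y: np.ndarray) -> np.ndarray:
        """alpha = (K + lambda I)^-1 y; y may hold multiple target columns."""
        return cho_solve(self._cho, np.asarray(y, dtype=float))

    @property
    def kinv_diag(self) -> np.ndarray:
        """diag[(K + lambda I)^-1], needed by the closed-form LOO identity."""
        if self._kinv_diag is None:
            n = self.X.shape[0]
            self._kinv_diag = np.diag(cho_solve(self._cho, np.eye(n)))
        return self._kinv_diag

    def loo(self, y: np.ndarray) -> np.ndarray:
        """Leave-one-out predictions for each training point (uncentered).

        Entry i is the prediction of a model fitted without sample i,
        evaluated at x_i.  Columns of a 2-D ``y`` are treated independently.
        """
        y = np.asarray(y, dtype=float)
        alpha = self.solve(y)
        diag = self.kinv_diag
        if y.ndim == 1:
            return y - alpha / diag
        return y - alpha / diag[:, None]

    def cross_kernel(self, Xq) -> np.ndarray:
        return kernel_matrix(_as_matrix(Xq), self.X, sigma=self.sigma)

    def predict(self, Xq, alpha: np.ndarray) -> np.ndarray:
        return self.cross_kernel(Xq) @ alpha


@dataclass
class KRRModel:
    """A fitted kernel ridge regressor for one surface or one PEM element."""

    workspace: KernelWorkspace
    alpha: np.ndarray
    y_mean: float = 0.0
    target_label: str = ""

    @property
    def sigma(self) -> float:
        return self.workspace.sigma

    @property
    def lam(self) -> float:
        return self.workspace.lam

    @property
    def n_train(self) -> int:
        return self.workspace.X.shape[0]


def fit(
    X,
    y,
    sigma: float,
    lam: float,
    *,
    center: bool = True,
    workspace: KernelWorkspace | None = None,
    target_label: str = "",
) -> KRRModel:
    """Closed-form KRR fit, alpha = (K + lambda I)^-1 (y - mean).

    Targets are mean-centered by default (the mean is restored at prediction
    time) so that queries far from all training points revert to the training
    mean instead of zero; ``center=False`` gives the plain uncentered form.
    A ``workspace`` from a previous fit with the same (X, sigma, lambda) is
    reused, skipping the factorization.
    """
    y = np.asarray(y, dtype=float)
    ws = workspace if workspace is not None else KernelWorkspace(X, sigma, lam)
    y_mean = float(np.mean(y)) if center else 0.0
    alpha = ws.solve(y - y_mean)
    return KRRModel(workspace=ws, alpha=alpha, y_mean=y_mean, target_label=target_label)


def predict(model: KRRModel, Xq) -> np.ndarray:
    """Kernel expansion sum_i alpha_i k(x_i, x) (+ restored mean)."""
    Xq = _as_matrix(Xq)
    if Xq.shape[1] != model.workspace.X.shape[1]:
        raise ValueError(
            f"feature length {Xq.shape[1]} != training length {model.workspace.X.shape[1]}"
        )
    return model.workspace.predict(Xq, model.alpha) + model.y_mean


def loo_predictions(X, y, sigma: float, lam: float) -> np.ndarray:
    """Leave-one-out predictions via the closed-form identity (uncentered).

    Equivalent to n refits, each omitting one sample, but computed from a
    single factorization.
    """
    X = _as_matrix(X)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples for leave-one-out")
    return KernelWorkspace(X, sigma, lam).loo(y)


@dataclass(frozen=True)
class CVPlan:
    """Seeded shuffled k-fold partition of n samples."""

    n_samples: int
    n_folds: int = 10
    seed: int = 0

    def folds(self) -> list[np.ndarray]:
        n_folds = min(self.n_folds, self.n_samples)
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(self.n_samples)
        return [np.sort(f) for f in np.array_split(perm, n_folds)]


def _cv_error(X, Y, sigma, lam, folds, center=True) -> np.ndarray:
    """Mean squared CV error per target column."""
    X = _as_matrix(X)
    Y = np.asarray(Y, dtype=float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    n = X.shape[0]
    sse = np.zeros(Y2.shape[1])
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        ws = KernelWorkspace(X[train], sigma, lam)
        mean = Y2[train].mean(axis=0) if center else 0.0
        alpha = ws.solve(Y2[train] - mean)
        pred = ws.predict(X[test], alpha) + mean
        sse += np.sum((pred - Y2[test]) ** 2, axis=0)
    err = sse / n
    return err if Y.ndim > 1 else err[:1]


def grid_search_cv(
    X,
    y,
    sigma_grid=None,
    lambda_grid=None,
    plan: CVPlan | None = None,
    *,
    center: bool = True,
) -> tuple[float, float, float]:
    """Grid search minimizing k-fold CV mean squared error.

    Returns (sigma*, lambda*, cv_error).  Ties are broken toward larger
    lambda, then larger sigma (the smoother model).  Deterministic given
    ``plan.seed``.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    sigma_grid = default_sigma_grid(X) if sigma_grid is None else np.asarray(sigma_grid, float)
    lambda_grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if sigma_grid.size == 0 or lambda_grid.size == 0:
        raise ValueError("empty hyperparameter grid")
    if np.any(sigma_grid <= 0) or np.any(lambda_grid < 0):
        raise ValueError("require sigma > 0 and lambda >= 0")
    if plan is None:
        plan = CVPlan(n_samples=n)
    if plan.n_folds > n:
        import warnings

        warnings.warn(f"fewer samples ({n}) than folds ({plan.n_folds}); reducing fold count")
    folds = CVPlan(n, min(plan.n_folds, n), plan.seed).folds()
    best = None
    # iterate ascending so later (larger) values win ties
    for sigma in np.sort(sigma_grid):
        for lam in np.sort(lambda_grid):
            err = float(np.sum(_cv_error(X, y, sigma, lam, folds, center=center)))
            if best is None or err <= best[2]:
                if best is None or err < best[2] or (lam, sigma) >= (best[1], best[0]):
                    best = (float(sigma), float(lam), err)
    return best


def grid_search_cv_multi(
    X,
    Y,
    sigma_grid=None,
    lambda_grid=None,
    plan: CVPlan | None = None,
    *,
    center: bool = True,
) -> list[tuple[float, float, float]]:
    """Per-column grid search sharing fold factorizations across all targets.

    ``Y`` is (n_samples, n_targets); returns one (sigma*, lambda*, cv_error)
    per column with the same tie-breaking as :func:`grid_search_cv`.  Used by
    the correction loop, where every surface / PEM element lives on the same
    kernel matrix.
    """
    X = _as_matrix(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (n_samples, n_targets)")
    n, m = Y.shape
    sigma_grid = default_sigma_grid(X) if sigma_grid is None else np.asarray(sigma_grid, float)
    lambda_grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if plan is None:
        plan = CVPlan(n_samples=n)
    folds = CVPlan(n, min(plan.n_folds, n), plan.seed).folds()
    best: list[tuple[float, float, float] | None] = [None] * m
    for sigma in np.sort(sigma_grid):
        for lam in np.sort(lambda_grid):
            errs = _cv_error(X, Y, sigma, lam, folds, center=center)
            for c in range(m):
                err = float(errs[c])
                b = best[c]
                if b is None or err < b[2] or (err == b[2] and (lam, sigma) >= (b[1], b[0])):
                    best[c] = (float(sigma), float(lam), err)
    return best  # type: ignore[return-value]


def nested_cv_score(
    X,
    y,
    sigma_grid=None,
    lambda_grid=None,
    plan_outer: CVPlan | None = None,
    plan_inner: CVPlan | None = None,
    *,
    center: bool = True,
) -> float:
    """Mean outer-fold test MSE with hyperparameters tuned per outer fold.

    Each outer training fold runs its own inner grid search, so no sample
    contributes to both hyperparameter tuning and testing — the unbiased
    score used to rank competing state orderings.
    """
    X = _as_matrix(X)
    Y = np.asarray(y, dtype=float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    n = X.shape[0]
    if plan_outer is None:
        plan_outer = CVPlan(n_samples=n, n_folds=5)
    if plan_inner is None:
        plan_inner = CVPlan(n_samples=n, n_folds=10, seed=plan_outer.seed + 1)
    outer_folds = CVPlan(n, min(plan_outer.n_folds, n), plan_outer.seed).folds()
    sse = 0.0
    for test in outer_folds:
        train = np.setdiff1d(np.arange(n), test)
        sigma, lam, _ = grid_search_cv(
            X[train],
            Y2[train] if Y.ndim > 1 else Y2[train, 0],
            sigma_grid,
            lambda_grid,
            CVPlan(len(train), plan_inner.n_folds, plan_inner.seed),
            center=center,
        )
        ws = KernelWorkspace(X[train], sigma, lam)
        mean = Y2[train].mean(axis=0) if center else 0.0
        alpha = ws.solve(Y2[train] - mean)
        pred = ws.predict(X[test], alpha) + mean
        sse += float(np.sum((pred - Y2[test]) ** 2))
    return sse / (n * Y2.shape[1])
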