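"""Prediction models: ordinary least squares and the elastic net.

The elastic net minimizes

    (1/2n) sum_j (y_j - b0 - sum_i b_i x_ji)^2
        + lambda * ( alpha * sum_i |b_i| + (1 - alpha)/2 * sum_i b_i^2 )

with the mixing parameter alpha selected from {0, 0.1, ..., 1} and
lambda from an automatic geometric path, both by inner 10-fold
cross-validation on the training samples. Features are standardized
internally; coefficients are returned on the original scale. A fitting
failure triggers a ridge (alpha = 0) refit, flagged as a fallback.

Ordinary linear regression is reserved for feature sets below the
configured cap (1,000 by default) to avoid wildly underdetermined fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .utils import substream

__all__ = ["ElasticNetSpec", "FitResult", "fit_linear", "fit_elastic_net",
           "predict", "choose_model", "DEFAULT_FEATURE_CAP"]

DEFAULT_FEATURE_CAP = 1000


@dataclass
class ElasticNetSpec:
    """Hyperparameter search space for the elastic net."""

    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
    inner_cv_folds: int = 10
    n_lambda: int = 100
    lambda_decades: float = 2.0
    max_iter: int = 2000

    def lambda_path(self, lam_max: float) -> np.ndarray:
        lam_max = max(lam_max, 1e-12)
        return np.geomspace(lam_max, lam_max * 10 ** (-self.lambda_decades),
                            self.n_lambda)


@dataclass
class FitResult:
    """A fitted prediction model for one (gene, config, fold)."""

    kind: str  # "linear" | "elastic_net" | "ridge_fallback" | "unfittable"
    intercept: float = 0.0
    coef: np.ndarray = field(default_factory=lambda: np.empty(0))
    feature_names: list[str] = field(default_factory=list)
    alpha: Optional[float] = None
    lam: Optional[float] = None
    n: int = 0
    p: int = 0
    status: str = "ok"
    resid_var: float = float("nan")

    @property
    def fallback(self) -> bool:
        return self.kind == "ridge_fallback"


def fit_linear(X: np.ndarray, y: np.ndarray,
               feature_names: Optional[list[str]] = None) -> FitResult:
    """Least-squares fit with intercept.

    Rank-deficient designs are solved by the minimum-norm least-squares
    solution (dependent directions carry no predictive information and a
    warning is emitted). With zero features the model is intercept-only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 1:
        raise ValueError("cannot fit a linear model on <= 1 sample")
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    p = X.shape[1]
    design = np.column_stack([np.ones(n), X])
    beta, _res, rank, _sv = np.linalg.lstsq(design, y, rcond=None)
    if rank < min(design.shape):
        warnings.warn(f"rank-deficient design (rank {rank} < {p + 1}); "
                      "using the minimum-norm solution")
    fitted = design @ beta
    dof = max(n - rank, 1)
    names = list(feature_names) if feature_names is not None \
        else [f"x{i}" for i in range(p)]
    return FitResult("linear", float(beta[0]), beta[1:], names, n=n, p=p,
                     resid_var=float(np.sum((y - fitted) ** 2) / dof))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def _ridge_path_coefs(Xs: np.ndarray, yc: np.ndarray,
                      lambdas: np.ndarray) -> np.ndarray:
    """Ridge solutions of the elastic-net objective at alpha = 0 for every
    lambda: (X'X/n + lam I) b = X'y/n, via one SVD."""
    n = Xs.shape[0]
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    uty = u.T @ yc
    # b(lam) = V diag(s / (s^2 + n lam)) U' y
    denom = s[None, :] ** 2 + n * lambdas[:, None]
    factors = np.where(s[None, :] > 0, s[None, :] / denom, 0.0)
    return (factors * uty[None, :]) @ vt  # n_lambda x p


def _enet_path_coefs(Xs: np.ndarray, yc: np.ndarray, alpha: float,
                     lambdas: np.ndarray, max_iter: int) -> np.ndarray:
    """Coordinate-descent elastic-net path (decreasing lambda, warm starts).

    Delegates to scikit-learn's path solver, whose objective matches the
    one documented in this module with alpha = l1_ratio and lambda =
    its regularization strength.
    """
    from sklearn.linear_model import enet_path

    order = np.argsort(lambdas)[::-1]
    _alphas, coefs, _ = enet_path(Xs, yc, l1_ratio=alpha,
                                  alphas=lambdas[order], max_iter=max_iter)
    out = np.empty((lambdas.size, Xs.shape[1]))
    out[order] = coefs.T
    return out


def _inner_cv_mse(X: np.ndarray, y: np.ndarray, alpha: float,
                  lambdas: np.ndarray, folds: list[np.ndarray],
                  spec: ElasticNetSpec) -> np.ndarray:
    """Mean held-out squared error per lambda for one alpha."""
    n = y.size
    sse = np.zeros(lambdas.size)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        Xs, mean, scale = _standardize(Xtr)
        yc = ytr - ytr.mean()
        if alpha == 0.0:
            coefs = _ridge_path_coefs(Xs, yc, lambdas)
        else:
            coefs = _enet_path_coefs(Xs, yc, alpha, lambdas, spec.max_iter)
        Xte = (X[test_idx] - mean) / scale
        preds = Xte @ coefs.T + ytr.mean()
        sse += np.sum((y[test_idx][:, None] - preds) ** 2, axis=0)
    return sse / n


def fit_elastic_net(X: np.ndarray, y: np.ndarray,
                    spec: Optional[ElasticNetSpec] = None, seed: int = 0,
                    feature_names: Optional[list[str]] = None,
                    force_alpha: Optional[float] = None,
                    force_lambda: Optional[float] = None) -> FitResult:
    """Elastic net with inner-CV selection of (alpha, lambda).

    ``force_alpha`` / ``force_lambda`` pin a hyperparameter (used by
    diagnostics and tests); selection only runs over the free ones.
    """
    spec = spec or ElasticNetSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None \
        else [f"x{i}" for i in range(p)]
    if np.std(y) == 0:
        return FitResult("unfittable", n=n, p=p, status="constant_target")
    if p == 0:
        return FitResult("unfittable", n=n, p=p, status="no_features")

    Xs_full, mean, scale = _standardize(X)
    yc_full = y - y.mean()

    # lambda_max: smallest lambda with an all-zero solution (glmnet
    # convention; alpha floor of 1e-3 keeps the path finite at alpha=0)
    grad0 = np.abs(Xs_full.T @ yc_full) / n
    alphas = (spec.alphas if force_alpha is None
              else (float(force_alpha),))

    rng = substream(seed, "inner-cv")
    k = min(spec.inner_cv_folds, n)
    if k < 2:
        raise ValueError("need at least 2 samples for inner CV")
    perm = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(perm, k)]

    best: Optional[tuple[float, float, float]] = None  # (mse, alpha, lam)
    failures = 0
    for alpha in alphas:
        lam_max = float(grad0.max()) / max(alpha, 1e-3)
        if force_lambda is not None:
            lambdas = np.array([float(force_lambda)])
        else:
            lambdas = spec.lambda_path(lam_max)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mse = _inner_cv_mse(X, y, float(alpha), lambdas, folds, spec)
        except Exception:
            failures += 1
            continue
        j = int(np.argmin(mse))
        if best is None or mse[j] < best[0] - 1e-15:
            best = (float(mse[j]), float(alpha), float(lambdas[j]))

    fallback = False
    if best is None:
        if failures == len(alphas):
            # refit as ridge at a mid-path lambda
            fallback = True
            lam_max = float(grad0.max()) / 1e-3
            best = (np.inf, 0.0, float(np.sqrt(lam_max * lam_max
                                               * 10 ** (-spec.lambda_decades))))
        else:  # pragma: no cover - unreachable
            return FitResult("unfittable", n=n, p=p, status="cv_failed")

    _, alpha_star, lam_star = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alpha_star == 0.0:
            coef_std = _ridge_path_coefs(Xs_full, yc_full,
                                         np.array([lam_star]))[0]
        else:
            coef_std = _enet_path_coefs(Xs_full, yc_full, alpha_star,
                                        np.array([lam_star]),
                                        spec.max_iter)[0]
    coef = coef_std / scale
    intercept = float(y.mean() - mean @ coef)
    kind = "ridge_fallback" if fallback else "elastic_net"
    fitted = X @ coef + intercept
    return FitResult(kind, intercept, coef, names, alpha=alpha_star,
                     lam=lam_star, n=n, p=p,
                     resid_var=float(np.var(y - fitted)))


def predict(fit: FitResult, X_new: np.ndarray,
            feature_names: Optional[list[str]] = None) -> np.ndarray:
    """Linear scoring b0 + X b; refuses feature-name mismatches."""
    if fit.kind == "unfittable":
        raise ValueError("cannot predict from an unfittable result")
    X_new = np.asarray(X_new, dtype=float)
    if feature_names is not None and list(feature_names) != fit.feature_names:
        missing = set(fit.feature_names) - set(feature_names)
        extra = set(feature_names) - set(fit.feature_names)
        raise ValueError("feature mismatch between training and prediction: "
                         f"missing={sorted(missing)[:5]}, "
                         f"extra={sorted(extra)[:5]}")
    if X_new.shape[1] != fit.coef.size:
        raise ValueError(f"expected {fit.coef.size} features, "
                         f"got {X_new.shape[1]}")
    return fit.intercept + X_new @ fit.coef


def choose_model(feature_count: int,
                 cap: int = DEFAULT_FEATURE_CAP) -> str:
    """Model class for a feature count: small sets use plain linear
    regression, sets at or above the cap use the elastic net."""
    if feature_count == 0:
        return "unfittable"
    return "linear" if feature_count < cap else "elastic_net"
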