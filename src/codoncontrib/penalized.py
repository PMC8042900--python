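"""Elastic-net regression by cyclic coordinate descent with cross-validated λ.

Predictors are standardized internally (mean 0, unit variance) and the
response centered; coefficients are reported back on the original scale.
The λ path is geometric from λ_max (the smallest λ with an all-zero
solution at the given mixing parameter) down to ``lambda_min_ratio``·λ_max,
solved with warm starts; λ is chosen by k-fold cross-validation minimizing
mean squared prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ElasticNetResult", "fit_elastic_net", "ConvergenceError", "soft_threshold"]


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to reach tolerance within max_iter sweeps."""


def soft_threshold(z: float, gamma: float) -> float:
    """S(z, γ) = sign(z)·max(|z| − γ, 0)."""
    return np.sign(z) * max(abs(z) - gamma, 0.0)


@dataclass
class ElasticNetResult:
    """Coefficient path, CV curve and the selected model (original scale)."""

    alpha: float
    lambda_path: np.ndarray
    coef_path: np.ndarray  # n_lambda × p, standardized scale
    cv_mse: np.ndarray  # n_lambda mean CV error (NaN when cv_folds == 0)
    lambda_best: float
    coef: np.ndarray  # original scale, selected λ
    intercept: float
    n_iter: int

    def nonzero_features(self, names: list[str] | None = None) -> list:
        idx = np.flatnonzero(self.coef)
        return [names[i] for i in idx] if names is not None else list(idx)


def _cd_solve(
    G: np.ndarray,
    b: np.ndarray,
    lam: float,
    alpha: float,
    beta: np.ndarray,
    tol: float,
    max_iter: int,
    obj_tol: float = 1e-9,
) -> tuple[np.ndarray, int]:
    """Coordinate descent on standardized data via the Gram matrix.

    G = XᵀX/n with unit diagonal, b = Xᵀy/n; update for coordinate j is
    β_j ← S(b_j − Σ_{k≠j} G_jk β_k, αλ) / (1 + λ(1−α)).
    """
    p = len(b)
    l1, l2 = alpha * lam, lam * (1.0 - alpha)
    grad = G @ beta  # maintained as G·β

    def sweep(coords) -> float:
        nonlocal grad
        delta_max = 0.0
        for j in coords:
            old = beta[j]
            z = b[j] - grad[j] + G[j, j] * old
            new = soft_threshold(z, l1) / (G[j, j] + l2)
            if new != old:
                grad += G[:, j] * (new - old)
                beta[j] = new
                delta_max = max(delta_max, abs(new - old))
        return delta_max

    def objective() -> float:
        return (
            0.5 * float(beta @ grad) - float(b @ beta)
            + l1 * float(np.abs(beta).sum()) + 0.5 * l2 * float(beta @ beta)
        )

    # two stopping rules: the coefficient rule for well-conditioned problems,
    # and an objective-decrease rule that ends the flat-direction crawl that
    # exactly collinear (compositional) columns produce at small lambda
    threshold = lambda: tol * max(1.0, float(np.abs(beta).max()))  # noqa: E731
    f_prev = objective()
    it = 0
    while it < max_iter:
        it += 1
        delta = sweep(range(p))  # full sweep (re-screens the active set)
        f = objective()
        if delta <= threshold() or abs(f_prev - f) <= obj_tol * max(1.0, abs(f)):
            return beta, it
        f_prev = f
        # iterate the active set before the next full sweep
        while it < max_iter:
            it += 1
            active = np.flatnonzero(beta)
            if sweep(active) <= threshold():
                break
            f = objective()
            if abs(f_prev - f) <= obj_tol * max(1.0, abs(f)):
                break
            f_prev = f
    raise ConvergenceError(
        f"coordinate descent did not converge at lambda={lam:g} "
        f"(tol {tol:g}, {max_iter} sweeps)"
    )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns stay zero after centering
    return (X - mean) / sd, mean, sd


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 60,
    lambda_min_ratio: float | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 5000,
    obj_tol: float = 1e-9,
) -> ElasticNetResult:
    """Fit the elastic net over a λ path and select λ by k-fold CV.

    ``alpha`` mixes the penalties (1 = lasso, 0 = ridge); ``cv_folds=0``
    skips CV and selects the smallest λ on the path.  Fold assignment is a
    seeded permutation, recorded implicitly by the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    Xs, x_mean, x_sd = _standardize(X)
    y_mean = y.mean()
    yc = y - y_mean

    if lambdas is None:
        lam_max = float(np.abs(Xs.T @ yc).max() / (n * max(alpha, 1e-3)))
        if lam_max <= 0:
            lam_max = 1.0
        if lambda_min_ratio is None:
            lambda_min_ratio = 1e-3 if n > p else 1e-2
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
    else:
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    def path_fit(Xtr: np.ndarray, ytr: np.ndarray) -> tuple[np.ndarray, int]:
        m = len(ytr)
        G = Xtr.T @ Xtr / m
        b = Xtr.T @ ytr / m
        beta = np.zeros(p)
        coefs = np.empty((len(lambdas), p))
        iters = 0
        for i, lam in enumerate(lambdas):
            beta, it = _cd_solve(G, b, lam, alpha, beta.copy(), tol, max_iter, obj_tol)
            coefs[i] = beta
            iters += it
        return coefs, iters

    cv_mse = np.full(len(lambdas), np.nan)
    if cv_folds and cv_folds > 1:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, cv_folds)
        sse = np.zeros(len(lambdas))
        for holdout in folds:
            mask = np.ones(n, dtype=bool)
            mask[holdout] = False
            coefs, _ = path_fit(Xs[mask], yc[mask])
            pred = Xs[holdout] @ coefs.T  # n_hold × n_lambda
            sse += ((yc[holdout][:, None] - pred) ** 2).sum(axis=0)
        cv_mse = sse / n
        best_idx = int(np.argmin(cv_mse))
    else:
        best_idx = len(lambdas) - 1

    coef_path, n_iter = path_fit(Xs, yc)
    beta_std = coef_path[best_idx]
    coef = beta_std / x_sd
    intercept = y_mean - float(x_mean @ coef)
    return ElasticNetResult(
        alpha=alpha,
        lambda_path=lambdas,
        coef_path=coef_path,
        cv_mse=cv_mse,
        lambda_best=float(lambdas[best_idx]),
        coef=coef,
        intercept=intercept,
        n_iter=n_iter,
    )
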