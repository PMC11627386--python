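"""Dense REML machinery for small linear mixed models.

Fits models of the form

    y = X beta + sum_j Z_j u_j + e,    u_j ~ N(0, sigma_j^2 I),  e ~ N(0, sigma_e^2 I)

by maximising the restricted log-likelihood over the variance components on
the log scale. All matrices are dense; intended for single-trial RCBD fits
(tens of plots) and joint variance-component fits (a few thousand plots),
not for genome-scale problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

_LOG2PI = np.log(2.0 * np.pi)
VAR_FLOOR = 1e-10


@dataclass
class MixedModelFit:
    """REML solution of a variance-components mixed model."""

    variances: dict[str, float]
    sigma_e2: float
    beta: np.ndarray
    beta_se: np.ndarray
    blups: dict[str, np.ndarray]
    pev: dict[str, np.ndarray]
    loglik: float
    converged: bool
    boundary_terms: list[str] = field(default_factory=list)
    n_obs: int = 0
    n_fixed: int = 0


def _build_v(n: int, Ms: list[np.ndarray], var: np.ndarray, sigma_e2: float) -> np.ndarray:
    V = sigma_e2 * np.eye(n)
    for M, v in zip(Ms, var):
        V += v * M
    return V


def reml_loglik(y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray],
                variances: np.ndarray, sigma_e2: float) -> float:
    """Restricted log-likelihood (constant included) at fixed variances."""
    n, p = X.shape
    Ms = [Z @ Z.T for Z in Z_list]
    V = _build_v(n, Ms, np.asarray(variances, float), sigma_e2)
    L = np.linalg.cholesky(V)
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * (logdet_v + logdet_x + ypy + (n - p) * _LOG2PI)


def _neg_loglik_and_grad(theta, y, X, Ms):
    """Negative restricted loglik and gradient wrt log-variances.

    theta = log of (var_1..var_q, sigma_e2).
    """
    n, p = X.shape
    var = np.exp(theta)
    V = _build_v(n, Ms, var[:-1], var[-1])
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Vi = np.linalg.inv(V)
    Vi_X = Vi @ X
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vi - Vi_X @ XtViX_inv @ Vi_X.T
    Py = P @ y
    ypy = float(y @ Py)
    ll = -0.5 * (logdet_v + logdet_x + ypy + (n - p) * _LOG2PI)
    grad = np.empty_like(theta)
    for j, M in enumerate(Ms):
        grad[j] = -0.5 * (np.sum(P * M) - Py @ (M @ Py)) * var[j]
    grad[-1] = -0.5 * (np.trace(P) - Py @ Py) * var[-1]
    return -ll, -grad


def _mme_solve(y, X, Z_list, var, sigma_e2):
    """Henderson mixed-model equations: BLUE/BLUP point solutions and PEV.

    Returns beta, beta_se, list of u_j, list of pev_j (diag of the inverse
    coefficient matrix blocks, i.e. prediction error variances).
    """
    p = X.shape[1]
    W = np.hstack([X] + Z_list)
    C = (W.T @ W) / sigma_e2
    offset = p
    for Z, v in zip(Z_list, var):
        q = Z.shape[1]
        idx = np.arange(offset, offset + q)
        C[idx, idx] += 1.0 / max(v, VAR_FLOOR)
        offset += q
    rhs = (W.T @ y) / sigma_e2
    Cinv = np.linalg.pinv(C)
    sol = Cinv @ rhs
    beta = sol[:p]
    beta_se = np.sqrt(np.maximum(np.diag(Cinv)[:p], 0.0))
    us, pevs = [], []
    offset = p
    for Z in Z_list:
        q = Z.shape[1]
        us.append(sol[offset:offset + q])
        pevs.append(np.maximum(np.diag(Cinv)[offset:offset + q], 0.0))
        offset += q
    return beta, beta_se, us, pevs


def fit_mixed(y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray],
              names: list[str], n_starts: int = 3, seed: int = 0,
              tol: float = 1e-10,
              init_variances: np.ndarray | None = None) -> MixedModelFit:
    """REML fit with multistart bounded quasi-Newton on the log-variance scale.

    ``init_variances`` (length q+1: component variances then sigma_e2) adds a
    warm start, e.g. ANOVA moment estimates.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if len(Z_list) != len(names):
        raise ValueError("one name per random term required")
    Ms = [Z @ Z.T for Z in Z_list]
    vy = max(float(np.var(y)), 1e-6)
    rng = np.random.default_rng(seed)
    q = len(Z_list) + 1
    starts = []
    if init_variances is not None:
        starts.append(np.log(np.maximum(np.asarray(init_variances, float), VAR_FLOOR * 100)))
    starts.append(np.full(q, np.log(vy / q)))
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.log(vy) + rng.uniform(-3.0, 1.0, size=q))
    best = None
    bounds = [(np.log(VAR_FLOOR), np.log(vy * 1e4) + 1.0)] * q
    for theta0 in starts:
        res = optimize.minimize(
            _neg_loglik_and_grad, theta0, args=(y, X, Ms), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": tol, "gtol": 1e-9})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    var = np.exp(best.x)
    comp, sigma_e2 = var[:-1], var[-1]
    boundary = [nm for nm, v in zip(names, comp) if v <= VAR_FLOOR * 10]
    beta, beta_se, us, pevs = _mme_solve(y, X, Z_list, comp, sigma_e2)
    return MixedModelFit(
        variances=dict(zip(names, comp.tolist())),
        sigma_e2=float(sigma_e2),
        beta=beta, beta_se=beta_se,
        blups=dict(zip(names, us)),
        pev=dict(zip(names, pevs)),
        loglik=-float(best.fun),
        converged=bool(best.success),
        boundary_terms=boundary,
        n_obs=n, n_fixed=p)


def indicator(labels) -> tuple[np.ndarray, list]:
    """0/1 incidence matrix for a label vector plus the level order."""
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    Z = np.zeros((labels.shape[0], len(levels)))
    lut = {lv: j for j, lv in enumerate(levels)}
    for i, lab in enumerate(labels):
        Z[i, lut[lab]] = 1.0
    return Z, levels
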