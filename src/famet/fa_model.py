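"""Stage-2 joint factor-analytic mixed model across environments.

The genotype x environment table of stage-1 adjusted means is modelled as

    mean_il = tau_l + u_il + e_il,

where tau_l is an environment intercept (fixed), the rows u_i of the m x s
matrix of genetic effects are iid N(0, Sigma) with the FA(k) structure
Sigma = Lambda Lambda' + diag(Psi) (s x k loadings, diagonal specific
variances), and e_il ~ N(0, d_l) is optional stage-2 residual noise per
environment. Estimation is by REML: the restricted likelihood factorises
over genotypes given the environment intercepts, so each evaluation costs a
set of small per-missingness-pattern Cholesky factorisations. Lambda carries
an upper-triangle-zero identifiability constraint during optimisation;
interpretation happens after varimax rotation (see :mod:`famet.stability`).

With one adjusted mean per cell a *free* diagonal d is confounded with Psi
(only Psi + d enters the likelihood), so d is either zero ("absorb", the
default: stage-2 noise is absorbed into Psi) or fixed from the stage-1
standard errors ("fixed": d_l = mean of se^2 in environment l, which makes
G_hat = Lambda Lambda' + diag(Psi) an unbiased genetic covariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .single_trial import TrialFit

_LOG2PI = np.log(2.0 * np.pi)
_PSI_FLOOR = 1e-8


@dataclass
class MeansTable:
    """Genotype x environment adjusted means with optional cell SEs."""

    values: pd.DataFrame            # genotypes x environments, NaN = untested
    se: pd.DataFrame | None = None  # same shape, stage-1 standard errors

    def __post_init__(self):
        if self.values.shape[1] < 2:
            raise ValueError("need >= 2 environments")
        counts = self.values.notna().sum(axis=0)
        if (counts < 3).any():
            bad = counts.index[counts < 3][0]
            raise ValueError(f"environment {bad!r} has < 3 genotypes")
        empty = self.values.notna().sum(axis=1) == 0
        if empty.any():
            self.values = self.values.loc[~empty]
            if self.se is not None:
                self.se = self.se.loc[~empty]
        comp = _incidence_components(self.values.notna().to_numpy())
        if len(comp) > 1:
            raise ValueError(
                f"environment incidence is disconnected; components: "
                f"{[sorted(self.values.columns[list(c)]) for c in comp]}")

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def environments(self) -> list[str]:
        return list(self.values.columns.astype(str))


@dataclass
class FAFit:
    """A fitted FA(k) model of the genetic covariance across environments."""

    k: int
    Lambda: np.ndarray              # s x k, upper-triangle-zero gauge
    Psi: np.ndarray                 # s specific variances
    scores: np.ndarray              # m x k genotype factor scores (BLUPs)
    env_intercepts: pd.Series       # s fixed environment means
    stage2_resid: np.ndarray        # s fixed stage-2 residual variances d
    G_hat: np.ndarray               # s x s = Lambda Lambda' + diag(Psi)
    logREML: float
    n_params: int
    AIC: float
    u_hat: pd.DataFrame             # m x s predicted genetic effects, all cells
    tested: pd.DataFrame            # m x s bool mask of observed cells
    converged: bool
    genotypes: list[str] = field(default_factory=list)
    environments: list[str] = field(default_factory=list)
    n_obs: int = 0

    @property
    def s(self) -> int:
        return self.Lambda.shape[0]

    def to_json(self, path) -> None:
        import json
        payload = {
            "k": self.k, "Lambda": self.Lambda.tolist(),
            "Psi": self.Psi.tolist(), "scores": self.scores.tolist(),
            "env_intercepts": self.env_intercepts.tolist(),
            "stage2_resid": self.stage2_resid.tolist(),
            "logREML": self.logREML, "n_params": self.n_params,
            "AIC": self.AIC, "u_hat": self.u_hat.to_numpy().tolist(),
            "tested": self.tested.to_numpy().tolist(),
            "converged": self.converged, "genotypes": self.genotypes,
            "environments": self.environments, "n_obs": self.n_obs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FAFit":
        import json
        with open(path) as fh:
            d = json.load(fh)
        Lambda = np.asarray(d["Lambda"], float)
        Psi = np.asarray(d["Psi"], float)
        gen, env = d["genotypes"], d["environments"]
        return cls(
            k=d["k"], Lambda=Lambda, Psi=Psi,
            scores=np.asarray(d["scores"], float),
            env_intercepts=pd.Series(d["env_intercepts"], index=env),
            stage2_resid=np.asarray(d["stage2_resid"], float),
            G_hat=Lambda @ Lambda.T + np.diag(Psi),
            logREML=d["logREML"], n_params=d["n_params"], AIC=d["AIC"],
            u_hat=pd.DataFrame(d["u_hat"], index=gen, columns=env),
            tested=pd.DataFrame(np.asarray(d["tested"], bool), index=gen, columns=env),
            converged=d["converged"], genotypes=gen, environments=env,
            n_obs=d["n_obs"])


def _incidence_components(mask: np.ndarray) -> list[set[int]]:
    """Connected components of the environment-sharing graph of a bool mask."""
    s = mask.shape[1]
    adj = (mask.T.astype(int) @ mask.astype(int)) >= 1
    seen, comps = np.zeros(s, bool), []
    for start in range(s):
        if seen[start]:
            continue
        stack, comp = [start], {start}
        seen[start] = True
        while stack:
            a = stack.pop()
            for b in np.nonzero(adj[a])[0]:
                if not seen[b]:
                    seen[b] = True
                    comp.add(b)
                    stack.append(b)
        comps.append(comp)
    return comps


def build_means_table(trial_fits: list[TrialFit]) -> MeansTable:
    """Assemble the stage-2 means table from per-trial fits (BLUEs + SEs)."""
    if len(trial_fits) < 2:
        raise ValueError("need >= 2 trial fits")
    vals = pd.DataFrame({f.trial_id: f.blues for f in trial_fits})
    ses = pd.DataFrame({f.trial_id: f.blue_se_contrast for f in trial_fits})
    return MeansTable(values=vals, se=ses)


def n_params(s: int, k: int, include_stage2_resid: bool = False) -> int:
    """Variance-parameter count of FA(k): s*k - k(k-1)/2 loadings + s psi."""
    if k > s:
        raise ValueError(f"k={k} exceeds s={s}")
    base = s * k - k * (k - 1) // 2 + s if k >= 1 else s
    return base + (s if include_stage2_resid else 0)


# ---------------------------------------------------------------------------
# likelihood machinery

def _lam_mask(s: int, k: int) -> np.ndarray:
    """Free-entry mask for Lambda: zeros above the diagonal (lam[l,j]=0, j>l)."""
    mask = np.zeros((s, k), bool)
    for l in range(s):
        mask[l, :min(l + 1, k)] = True
    return mask


def _pack(Lambda, log_psi, mask):
    return np.concatenate([Lambda[mask], log_psi])


def _unpack(theta, mask):
    s, k = mask.shape
    nl = int(mask.sum())
    Lambda = np.zeros((s, k))
    Lambda[mask] = theta[:nl]
    return Lambda, np.exp(theta[nl:])


class _PatternStats:
    """Per-missingness-pattern sufficient statistics of a means table."""

    def __init__(self, Y: np.ndarray):
        self.m, self.s = Y.shape
        self.mask = ~np.isnan(Y)
        self.patterns = []
        seen: dict[tuple, list[int]] = {}
        for i in range(self.m):
            seen.setdefault(tuple(self.mask[i]), []).append(i)
        for key, rows in seen.items():
            idx = np.nonzero(np.array(key))[0]
            if idx.size == 0:
                continue
            block = Y[np.ix_(rows, idx)]
            self.patterns.append({
                "idx": idx, "rows": np.array(rows), "n": len(rows),
                "sum_y": block.sum(axis=0),
                "S": block.T @ block,
                "Y": block,
            })
        self.n_cells = int(self.mask.sum())


def _reml_from_sigma(stats: _PatternStats, Sigma_tot: np.ndarray):
    """Restricted loglik + GLS intercepts given the total cell covariance.

    Returns (logREML, tau_hat, per-pattern Cholesky inverses) or
    (-inf, None, None) when a pattern covariance is not PD.
    """
    s = Sigma_tot.shape[0]
    A = np.zeros((s, s))
    b = np.zeros(s)
    logdets = 0.0
    quad = 0.0
    cinvs = []
    for p in stats.patterns:
        idx = p["idx"]
        C = Sigma_tot[np.ix_(idx, idx)]
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        Cinv = np.linalg.inv(C)
        cinvs.append(Cinv)
        logdets += p["n"] * 2.0 * np.sum(np.log(np.diag(L)))
        A[np.ix_(idx, idx)] += p["n"] * Cinv
        b[idx] += Cinv @ p["sum_y"]
        quad += float(np.sum(Cinv * p["S"]))
    sign, logdet_x = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf, None, None
    tau = np.linalg.solve(A, b)
    ypy = quad - float(b @ tau)
    ll = -0.5 * (logdets + logdet_x + ypy + (stats.n_cells - s) * _LOG2PI)
    return ll, tau, cinvs


def fa_reml_loglik(means: MeansTable, Lambda: np.ndarray, Psi: np.ndarray,
                   stage2_resid: np.ndarray | None = None) -> float:
    """Restricted log-likelihood of the FA model at fixed (Lambda, Psi, d).

    Environment intercepts are profiled out by GLS; the constant term is
    included so the value is comparable with a dense whole-vector evaluation.
    """
    Y = means.values.to_numpy(float)
    stats = _PatternStats(Y)
    d = np.zeros(Y.shape[1]) if stage2_resid is None else np.asarray(stage2_resid, float)
    Sigma_tot = Lambda @ Lambda.T + np.diag(np.asarray(Psi, float) + d)
    ll, _, _ = _reml_from_sigma(stats, Sigma_tot)
    return float(ll)


def _reml_grad_sigma(stats: _PatternStats, Sigma_tot: np.ndarray):
    """Restricted loglik and its gradient with respect to Sigma.

    Uses the REML identity dl/dtheta = -1/2 [tr(P dV) - y'P dV P y] written
    per missingness pattern: with W_p = C_p^{-1} and A the GLS information
    of the environment intercepts, the Sigma-gradient is
    -1/2 (M - Q), M = sum_p n_p (W_p - W_p Ainv_pp W_p),
    Q = sum_p W_p R_p W_p, R_p the residual cross-product of the pattern.
    """
    s = Sigma_tot.shape[0]
    A = np.zeros((s, s))
    b = np.zeros(s)
    logdets = 0.0
    quad = 0.0
    Ws = []
    for p in stats.patterns:
        idx = p["idx"]
        C = Sigma_tot[np.ix_(idx, idx)]
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return -np.inf, None
        W = np.linalg.inv(C)
        Ws.append(W)
        logdets += p["n"] * 2.0 * np.sum(np.log(np.diag(L)))
        A[np.ix_(idx, idx)] += p["n"] * W
        b[idx] += W @ p["sum_y"]
        quad += float(np.sum(W * p["S"]))
    sign, logdet_x = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf, None
    Ainv = np.linalg.inv(A)
    tau = Ainv @ b
    ypy = quad - float(b @ tau)
    ll = -0.5 * (logdets + logdet_x + ypy + (stats.n_cells - s) * _LOG2PI)
    Gmat = np.zeros((s, s))
    for p, W in zip(stats.patterns, Ws):
        idx = p["idx"]
        n_p = p["n"]
        t = tau[idx]
        sy = p["sum_y"]
        R = p["S"] - np.outer(sy, t) - np.outer(t, sy) + n_p * np.outer(t, t)
        M_p = n_p * (W - W @ Ainv[np.ix_(idx, idx)] @ W)
        Q_p = W @ R @ W
        Gmat[np.ix_(idx, idx)] += -0.5 * (M_p - Q_p)
    return ll, Gmat


def _canonical_lambda(Lambda: np.ndarray) -> np.ndarray:
    """Rotate Lambda into the upper-triangle-zero gauge with nonneg diagonal."""
    s, k = Lambda.shape
    A = Lambda[:k, :]
    Q, _ = np.linalg.qr(A.T)
    L = Lambda @ Q
    for j in range(k):
        if L[j, j] < 0:
            L[:, j] = -L[:, j]
    L[np.triu_indices_from(L[:k, :], 1)] = 0.0  # zero numerical dust
    return L


def fit_fa(means: MeansTable, k: int, stage2_resid: str = "absorb",
           n_starts: int = 5, seed: int = 0, maxiter: int = 1000,
           tol: float = 1e-9,
           init: tuple[np.ndarray, np.ndarray] | None = None) -> FAFit:
    """REML fit of the FA(k) model to a genotype x environment means table.

    Parameters
    ----------
    means : MeansTable
    k : number of latent factors, 1 <= k <= s-1.
    stage2_resid : "absorb" (d = 0, stage-2 noise absorbed into Psi) or
        "fixed" (d_l set to the mean squared stage-1 SE per environment;
        requires ``means.se``).
    n_starts : multistarts around the eigen-decomposition initial value.
    init : optional extra (Lambda0, Psi0) start, e.g. the padded solution of
        the FA(k-1) fit, which guarantees monotone nesting of logREML.
    """
    Y = means.values.to_numpy(float)
    m, s = Y.shape
    if not (1 <= k <= s - 1):
        raise ValueError(f"require 1 <= k <= s-1, got k={k}, s={s}")
    if stage2_resid == "fixed":
        if means.se is None:
            raise ValueError("stage2_resid='fixed' requires cell SEs in the means table")
        d = np.nanmean(means.se.to_numpy(float) ** 2, axis=0)
    elif stage2_resid == "absorb":
        d = np.zeros(s)
    else:
        raise ValueError(f"unknown stage2_resid mode {stage2_resid!r}")

    stats = _PatternStats(Y)
    mask = _lam_mask(s, k)

    def neg_ll(theta):
        Lambda, Psi = _unpack(theta, mask)
        Sigma_tot = Lambda @ Lambda.T + np.diag(Psi + d)
        ll, Gmat = _reml_grad_sigma(stats, Sigma_tot)
        if not np.isfinite(ll):
            return 1e10, np.zeros_like(theta)
        # chain rule: dl/dLambda = 2 G Lambda (free entries only);
        # dl/dlog psi_l = G_ll * psi_l
        grad_lam = (2.0 * Gmat @ Lambda)[mask]
        grad_psi = np.diag(Gmat) * Psi
        return -ll, -np.concatenate([grad_lam, grad_psi])

    # eigen-decomposition start from the (pairwise-complete) sample covariance
    S = pd.DataFrame(Y).cov(min_periods=2).to_numpy()
    S = np.where(np.isfinite(S), S, 0.0)
    S = (S + S.T) / 2
    S_g = S - np.diag(d)
    w, V = np.linalg.eigh(S_g)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    Lam0 = V[:, :k] * np.sqrt(np.maximum(w[:k], 1e-4))[None, :]
    Lam0 = _canonical_lambda(Lam0)
    psi0 = np.maximum(np.diag(S_g) - (Lam0 ** 2).sum(axis=1), 0.05 * np.maximum(np.diag(S), 1e-3))

    rng = np.random.default_rng(seed)
    starts = [(Lam0, psi0)]
    if init is not None:
        starts.append((_canonical_lambda(np.asarray(init[0], float)),
                       np.maximum(np.asarray(init[1], float), _PSI_FLOOR)))
    while len(starts) < n_starts + (init is not None):
        jitter = 1.0 + 0.3 * rng.standard_normal(Lam0.shape)
        scale = np.exp(rng.uniform(-0.7, 0.7))
        starts.append((_canonical_lambda(Lam0 * jitter), psi0 * scale + 1e-3))

    nl = int(mask.sum())
    bounds = [(None, None)] * nl + [(np.log(_PSI_FLOOR), np.log(1e4 * max(np.max(np.diag(S)), 1.0)))] * s
    best, best_res = None, None
    for Lam_s, psi_s in starts:
        theta0 = _pack(Lam_s, np.log(np.maximum(psi_s, _PSI_FLOOR)), mask)
        res = optimize.minimize(neg_ll, theta0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": maxiter, "ftol": tol,
                                         "maxfun": 200000})
        if best is None or res.fun < best - 1e-10:
            best, best_res = res.fun, res

    Lambda, Psi = _unpack(best_res.x, mask)
    Sigma_tot = Lambda @ Lambda.T + np.diag(Psi + d)
    ll, tau, cinvs = _reml_from_sigma(stats, Sigma_tot)
    G_hat = Lambda @ Lambda.T + np.diag(Psi)

    # BLUPs of scores and genetic effects, cell predictions for all cells
    scores = np.zeros((m, k))
    u_hat = np.zeros((m, s))
    for p, Cinv in zip(stats.patterns, cinvs):
        idx, rows = p["idx"], p["rows"]
        resid = p["Y"] - tau[idx][None, :]
        H = Cinv @ resid.T                       # s_p x n_p
        scores[rows] = (Lambda[idx].T @ H).T
        u_hat[rows] = (G_hat[:, idx] @ H).T

    np_ = n_params(s, k, include_stage2_resid=False)
    aic = -2.0 * ll + 2.0 * np_
    gen = means.genotypes
    env = means.environments
    return FAFit(
        k=k, Lambda=Lambda, Psi=Psi, scores=scores,
        env_intercepts=pd.Series(tau, index=env),
        stage2_resid=d, G_hat=G_hat,
        logREML=float(ll), n_params=np_, AIC=float(aic),
        u_hat=pd.DataFrame(u_hat, index=gen, columns=env),
        tested=pd.DataFrame(stats.mask, index=gen, columns=env),
        converged=bool(best_res.success),
        genotypes=gen, environments=env, n_obs=stats.n_cells)


@dataclass
class ModelSearch:
    """AIC comparison of FA(1)..FA(kmax) fits."""

    table: pd.DataFrame    # Model, NP, AIC, logREML, fit_r
    fits: dict[int, FAFit]
    best_k: int

    @property
    def best(self) -> FAFit:
        return self.fits[self.best_k]


def model_search(means: MeansTable, k_range=None, stage2_resid: str = "absorb",
                 n_starts: int = 5, seed: int = 0) -> ModelSearch:
    """Fit FA(k) over a range of orders and select the minimum-AIC model.

    Each fit of order k receives the order-(k-1) solution (padded with a zero
    column) as an extra start, so logREML is non-decreasing in k.
    """
    s = len(means.environments)
    if k_range is None:
        k_range = range(1, min(6, s - 1) + 1)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > s - 1:
        raise ValueError(f"k_range must lie within [1, {s - 1}]")
    fits: dict[int, FAFit] = {}
    rows = []
    prev: FAFit | None = None
    for k in ks:
        init = None
        if prev is not None and prev.k == k - 1:
            init = (np.hstack([prev.Lambda, np.zeros((s, 1))]), prev.Psi.copy())
        fit = fit_fa(means, k, stage2_resid=stage2_resid, n_starts=n_starts,
                     seed=seed, init=init)
        fits[k] = fit
        rows.append({"Model": f"FA{k}", "NP": fit.n_params, "AIC": fit.AIC,
                     "logREML": fit.logREML, "fit_r": fit_accuracy(fit, means)})
        prev = fit
    if not any(f.converged for f in fits.values()):
        raise RuntimeError("no FA fit converged over the requested orders")
    table = pd.DataFrame(rows)
    best_k = ks[int(np.argmin(table["AIC"].to_numpy()))]
    return ModelSearch(table=table, fits=fits, best_k=best_k)


# ---------------------------------------------------------------------------
# derived quantities

def variance_explained(fit: FAFit) -> tuple[float, np.ndarray]:
    """Percent genetic variance captured by the common factors.

    Overall = 100 tr(Lambda Lambda') / tr(Lambda Lambda' + diag(Psi));
    per-factor shares use the same denominator and sum to the overall value.
    """
    common = (fit.Lambda ** 2).sum(axis=0)          # per-factor traces
    denom = float(common.sum() + fit.Psi.sum())
    if denom <= 0:
        raise ValueError("total genetic variance is zero")
    per_factor = 100.0 * common / denom
    return float(per_factor.sum()), per_factor


def genetic_correlation_matrix(fit: FAFit) -> pd.DataFrame:
    """Between-environment genetic correlations implied by G_hat.

    rho_ll' = G_ll' / sqrt(G_ll G_l'l'); environments with (numerically)
    zero genetic variance get NaN rows/columns.
    """
    g = np.diag(fit.G_hat).copy()
    ok = g > 1e-12
    denom = np.sqrt(np.where(ok, g, np.nan))
    rho = fit.G_hat / denom[:, None] / denom[None, :]
    rho[np.arange(fit.s), np.arange(fit.s)] = np.where(ok, 1.0, np.nan)
    return pd.DataFrame(rho, index=fit.environments, columns=fit.environments)


def predict_genotype_env(fit: FAFit) -> pd.DataFrame:
    """Predicted genotype values in every environment, tested or not.

    value = env_intercept_l + u_hat_il; for untested cells u_hat reduces to
    lambda_l' f_i (no specific-effect information). Long-format output with a
    ``tested`` flag.
    """
    pred = fit.u_hat.add(fit.env_intercepts, axis=1)
    long = pred.stack().rename("predicted").reset_index()
    long.columns = ["genotype", "environment", "predicted"]
    flags = fit.tested.stack().reset_index(drop=True)
    long["tested"] = flags.to_numpy()
    return long


def fit_accuracy(fit: FAFit, means: MeansTable) -> float:
    """Pearson correlation of observed cell means with fitted values."""
    Y = means.values.to_numpy(float)
    mask = ~np.isnan(Y)
    if mask.sum() < 3:
        raise ValueError("need >= 3 observed cells")
    fitted = fit.u_hat.to_numpy() + fit.env_intercepts.to_numpy()[None, :]
    obs, fv = Y[mask], fitted[mask]
    return float(np.corrcoef(obs, fv)[0, 1])
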