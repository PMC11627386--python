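"""Stage-1 per-trial linear mixed model.

Each trial (environment) is analysed separately with the RCBD model

    y = mu + replicate + genotype + e,

replicate and genotype random, intercept fixed, all variance components by
REML. The genotype-random fit yields the variance components, BLUPs with
prediction error variances (PEV), Cullis heritability, experimental accuracy
and CV%; a companion genotype-fixed fit yields the BLUEs (adjusted means)
that feed the stage-2 joint analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._reml import VAR_FLOOR, _mme_solve, fit_mixed, indicator, reml_loglik
from .data_model import MetDataset


@dataclass
class TrialFit:
    """REML results for one trial."""

    trial_id: str
    mu: float
    sigma_g2: float
    sigma_r2: float
    sigma_e2: float
    genotypes: list[str]
    blups: pd.Series          # genotype -> predicted genetic effect
    pev: pd.Series            # genotype -> prediction error variance
    blues: pd.Series          # genotype -> adjusted mean (genotype-fixed fit)
    blue_se: pd.Series        # GLS standard error of the adjusted mean
    blue_se_contrast: pd.Series  # within-trial contrast SE, sqrt(sigma_e2/r_i)
    logREML: float
    residuals: pd.DataFrame   # plot-level standardized conditional residuals
    converged: bool
    boundary: bool            # a variance hit the lower floor
    n_obs: int


def fit_trial(records: pd.DataFrame, trial_id: str | None = None,
              n_starts: int = 3, seed: int = 0) -> TrialFit:
    """Fit the RCBD mixed model to the plot records of a single trial.

    ``records`` must hold one trial only, with columns genotype, replicate,
    value. Requires >= 2 genotypes and >= 2 replicates sharing at least one
    genotype. Missing plot values are dropped from the fit (they remain
    explicit in the dataset).
    """
    rec = records.dropna(subset=["value"])
    if trial_id is None:
        trial_id = str(rec["environment"].iloc[0]) if "environment" in rec else "trial"
    genos = sorted(rec["genotype"].astype(str).unique())
    reps = sorted(rec["replicate"].unique())
    if len(genos) < 2:
        raise ValueError(f"{trial_id}: need >= 2 genotypes, got {len(genos)}")
    if len(reps) < 2:
        raise ValueError(f"{trial_id}: need >= 2 replicates, got {len(reps)}")
    y = rec["value"].to_numpy(float)
    n = len(y)
    X = np.ones((n, 1))
    Zg, glev = indicator(rec["genotype"].astype(str))
    Zr, rlev = indicator(rec["replicate"])
    m, r = len(glev), len(rlev)

    # ANOVA moment estimators; on a complete balanced RCBD with interior
    # estimates these coincide with REML, giving a closed-form fast path.
    balanced = (n == m * r) and (Zg.T @ Zr == 1).all()
    anova = None
    if balanced:
        grand = y.mean()
        gm = (Zg.T @ y) / r
        rm = (Zr.T @ y) / m
        ss_g = r * np.sum((gm - grand) ** 2)
        ss_r = m * np.sum((rm - grand) ** 2)
        ss_e = np.sum((y - grand) ** 2) - ss_g - ss_r
        ms_g = ss_g / (m - 1)
        ms_r = ss_r / (r - 1)
        ms_e = ss_e / ((m - 1) * (r - 1))
        anova = np.array([(ms_g - ms_e) / r, (ms_r - ms_e) / m, ms_e])
    if anova is not None and (anova > VAR_FLOOR * 100).all():
        sigma_g2, sigma_r2, sigma_e2 = (float(v) for v in anova)
        mu = float(y.mean())
        loglik = reml_loglik(y, X, [Zg, Zr], anova[:2], sigma_e2)
        _, _, us, pevs = _mme_solve(y, X, [Zg, Zr], anova[:2], sigma_e2)
        blups = pd.Series(us[0], index=glev)
        pev = pd.Series(pevs[0], index=glev)
        rep_blup = us[1]
        beta_f, se_f, _, _ = _mme_solve(y, Zg, [Zr], anova[1:2], sigma_e2)
        blues = pd.Series(beta_f, index=glev)
        blue_se = pd.Series(se_f, index=glev)
        converged, boundary = True, False
    else:
        init = None if anova is None else np.maximum(anova, VAR_FLOOR * 100)
        fit = fit_mixed(y, X, [Zg, Zr], ["genotype", "replicate"],
                        n_starts=n_starts, seed=seed, init_variances=init)
        sigma_g2 = fit.variances["genotype"]
        sigma_r2 = fit.variances["replicate"]
        sigma_e2 = fit.sigma_e2
        mu = float(fit.beta[0])
        loglik = fit.loglik
        blups = pd.Series(fit.blups["genotype"], index=glev)
        pev = pd.Series(fit.pev["genotype"], index=glev)
        rep_blup = fit.blups["replicate"]
        fixed = fit_mixed(y, Zg, [Zr], ["replicate"], n_starts=n_starts,
                          seed=seed, init_variances=np.array([sigma_r2, sigma_e2]))
        blues = pd.Series(fixed.beta, index=glev)
        blue_se = pd.Series(fixed.beta_se, index=glev)
        converged = fit.converged
        boundary = bool(fit.boundary_terms)

    fitted = mu + Zg @ blups.to_numpy() + Zr @ rep_blup
    resid = (y - fitted) / np.sqrt(max(sigma_e2, VAR_FLOOR))
    residuals = rec[["genotype", "replicate"]].copy()
    residuals["std_resid"] = resid
    # replicate-effect uncertainty is common to all genotypes of a trial and
    # is absorbed by the trial intercept downstream; the contrast SE carries
    # only the residual part
    rep_counts = Zg.sum(axis=0)
    se_contrast = pd.Series(np.sqrt(sigma_e2 / rep_counts), index=glev)

    return TrialFit(
        trial_id=trial_id, mu=mu,
        sigma_g2=sigma_g2, sigma_r2=sigma_r2, sigma_e2=sigma_e2,
        genotypes=glev, blups=blups, pev=pev, blues=blues, blue_se=blue_se,
        blue_se_contrast=se_contrast,
        logREML=loglik, residuals=residuals,
        converged=converged, boundary=boundary, n_obs=n)


def fit_all_trials(data: MetDataset, n_starts: int = 3, seed: int = 0) -> list[TrialFit]:
    """Fit every trial in a MET dataset, in environment order."""
    return [fit_trial(data.subset_environment(env), trial_id=env,
                      n_starts=n_starts, seed=seed)
            for env in data.environments]


def heritability_cullis(fit: TrialFit) -> float:
    """Cullis broad-sense heritability H2 = 1 - mean(PEV) / (2 sigma_g2).

    Clipped to [0, 1]; returns 0.0 when the genotypic variance is at the
    boundary (undefined case).
    """
    if fit.sigma_g2 <= VAR_FLOOR * 10:
        return 0.0
    h2 = 1.0 - fit.pev.mean() / (2.0 * fit.sigma_g2)
    return float(np.clip(h2, 0.0, 1.0))


def accuracy(fit: TrialFit, as_printed: bool = False) -> float:
    """Experimental (selective) accuracy from mean PEV.

    Default is the square-root form sqrt(1 - mean(PEV)/sigma_g2); with
    ``as_printed=True`` the non-root form 1 - mean(PEV)/sigma_g2 is returned
    instead. Clamped to [0, 1].
    """
    if fit.sigma_g2 <= VAR_FLOOR * 10:
        return 0.0
    ratio = fit.pev.mean() / fit.sigma_g2
    base = np.clip(1.0 - ratio, 0.0, 1.0)
    return float(base if as_printed else np.sqrt(base))


def cv_percent(fit: TrialFit, mu: float | None = None) -> float:
    """Residual coefficient of variation, 100 * sigma_e / mu."""
    mu = fit.mu if mu is None else mu
    if mu <= 0:
        raise ValueError(f"mean must be positive, got {mu}")
    return float(100.0 * np.sqrt(fit.sigma_e2) / mu)


def adjusted_means(records: pd.DataFrame, trial_id: str | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Genotype adjusted means (BLUEs) with standard errors for one trial."""
    fit = fit_trial(records, trial_id=trial_id, seed=seed)
    return pd.DataFrame({"genotype": fit.blues.index,
                         "blue": fit.blues.values,
                         "se": fit.blue_se.values})


def residual_diagnostics(fit: TrialFit, threshold: float = 3.5) -> pd.DataFrame:
    """Standardized conditional residuals with advisory outlier flags.

    Flags |r| > threshold; flagged plots are never removed automatically.
    """
    out = fit.residuals.copy()
    out["outlier"] = out["std_resid"].abs() > threshold
    return out


def trial_summary(fits: list[TrialFit], accuracy_as_printed: bool = False) -> pd.DataFrame:
    """Per-trial genetic-parameter table (sigma_g2, sigma_e2, H2, Ac, CV%)."""
    rows = []
    for f in fits:
        rows.append({
            "trial": f.trial_id, "n_obs": f.n_obs, "mu": f.mu,
            "sigma_g2": f.sigma_g2, "sigma_r2": f.sigma_r2,
            "sigma_e2": f.sigma_e2,
            "H2": heritability_cullis(f),
            "Ac": accuracy(f, as_printed=accuracy_as_printed),
            "CV_pct": cv_percent(f),
            "converged": f.converged, "boundary": f.boundary,
        })
    return pd.DataFrame(rows)
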