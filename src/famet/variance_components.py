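"""Joint across-environment variance components and covariate correlations.

The compound joint model treats environments as fixed and genotype,
genotype x environment and residual as random:

    y = env + genotype + genotype:env + e.

REML components feed the standard derived genetic parameters of a MET:
phenotypic variance sigma_p^2 = sigma_g^2 + sigma_gxe^2/E + sigma_e^2/(E R),
genotypic and residual coefficients of variation, the genotype-environment
correlation r_ge, the G x E determination coefficient r_i^2, entry-mean
heritability and the phenotypic-minus-genotypic CV gap. Random terms are
tested by likelihood-ratio tests with the boundary-corrected 50:50 mixture
of chi2(0) and chi2(1). Pearson correlations between environment covariates
and rotated factor loadings quantify which weather/site variables drive each
latent environmental gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._reml import fit_mixed, indicator
from .data_model import CovariateTable, MetDataset
from .stability import RotatedFA


@dataclass
class JointVC:
    """Joint variance components and derived genetic parameters."""

    sigma_g2: float
    sigma_gxe2: float
    sigma_e2: float
    E: float              # (harmonic-mean) number of environments
    R: float              # (harmonic-mean) number of replicates
    mean: float
    sigma_p2: float
    CVg: float
    CVr: float
    CVp: float
    CV_ratio: float
    r_ge: float
    r_i2: float
    H2_entry_mean: float
    P_minus_G: float
    logREML: float
    converged: bool

    def to_dict(self) -> dict:
        return {k: float(v) if isinstance(v, (int, float, np.floating)) else v
                for k, v in self.__dict__.items()}


def _harmonic_mean(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    x = x[x > 0]
    return float(len(x) / np.sum(1.0 / x))


def _design(data: MetDataset):
    rec = data.records.dropna(subset=["value"])
    y = rec["value"].to_numpy(float)
    env = rec["environment"].astype(str)
    gen = rec["genotype"].astype(str)
    gxe = gen.str.cat(env, sep="::")
    X, env_levels = indicator(env)
    Zg, _ = indicator(gen)
    Zge, _ = indicator(gxe)
    return rec, y, X, Zg, Zge


def fit_joint_vc(data: MetDataset, n_starts: int = 2, seed: int = 0) -> JointVC:
    """REML fit of the compound joint model with derived genetic parameters.

    E and R enter sigma_p^2 as harmonic means of the per-genotype environment
    counts and per-cell replicate counts, which reduce to the plain counts on
    balanced data.
    """
    if len(data.environments) < 2:
        raise ValueError("need >= 2 environments for a joint analysis")
    rec, y, X, Zg, Zge = _design(data)
    fit = fit_mixed(y, X, [Zg, Zge], ["genotype", "gxe"],
                    n_starts=n_starts, seed=seed)
    sg2 = fit.variances["genotype"]
    sge2 = fit.variances["gxe"]
    se2 = fit.sigma_e2
    inc = data.incidence
    E = _harmonic_mean(inc.sum(axis=1).to_numpy())
    reps = rec.groupby(["genotype", "environment"]).size().to_numpy()
    R = _harmonic_mean(reps)
    mean = float(np.mean(y))
    sp2 = sg2 + sge2 / E + se2 / (E * R)
    cvg = 100.0 * np.sqrt(sg2) / mean
    cvr = 100.0 * np.sqrt(se2) / mean
    cvp = 100.0 * np.sqrt(sp2) / mean
    denom_ge = sg2 + sge2
    r_ge = sg2 / denom_ge if denom_ge > 0 else np.nan
    tot = sg2 + sge2 + se2
    r_i2 = sge2 / tot if tot > 0 else np.nan
    return JointVC(
        sigma_g2=sg2, sigma_gxe2=sge2, sigma_e2=se2, E=E, R=R, mean=mean,
        sigma_p2=sp2, CVg=cvg, CVr=cvr, CVp=cvp,
        CV_ratio=cvg / cvr if cvr > 0 else np.nan,
        r_ge=float(r_ge), r_i2=float(r_i2),
        H2_entry_mean=sg2 / sp2 if sp2 > 0 else np.nan,
        P_minus_G=cvp - cvg,
        logREML=fit.loglik, converged=fit.converged)


def derived_parameters(sigma_g2: float, sigma_gxe2: float, sigma_e2: float,
                       E: float, R: float, mean: float) -> dict:
    """Derived genetic parameters from given components (no fitting)."""
    sp2 = sigma_g2 + sigma_gxe2 / E + sigma_e2 / (E * R)
    cvg = 100.0 * np.sqrt(sigma_g2) / mean
    cvr = 100.0 * np.sqrt(sigma_e2) / mean
    cvp = 100.0 * np.sqrt(sp2) / mean
    return {
        "sigma_p2": sp2,
        "CVg": cvg, "CVr": cvr, "CVp": cvp,
        "CV_ratio": cvg / cvr if cvr > 0 else np.nan,
        "r_ge": sigma_g2 / (sigma_g2 + sigma_gxe2),
        "r_i2": sigma_gxe2 / (sigma_g2 + sigma_gxe2 + sigma_e2),
        "H2_entry_mean": sigma_g2 / sp2,
        "P_minus_G": cvp - cvg,
    }


def _p_mixture(stat: float) -> float:
    """Boundary-corrected LRT p: 50:50 mixture of chi2(0) and chi2(1)."""
    if stat <= 0:
        return 1.0
    return float(0.5 * sps.chi2.sf(stat, 1))


def lrt_effects(data: MetDataset, n_starts: int = 2, seed: int = 0) -> pd.DataFrame:
    """Likelihood-ratio tests for the genotype and G x E random terms.

    Each term is dropped in turn from the full model; the statistic is
    2 (logREML_full - logREML_reduced), valid because the fixed-effect
    structure is identical across the nested fits.
    """
    rec, y, X, Zg, Zge = _design(data)
    full = fit_mixed(y, X, [Zg, Zge], ["genotype", "gxe"],
                     n_starts=n_starts, seed=seed)
    rows = []
    for term, keep in (("genotype", [Zge]), ("gxe", [Zg])):
        names = ["gxe"] if term == "genotype" else ["genotype"]
        try:
            red = fit_mixed(y, X, keep, names, n_starts=n_starts, seed=seed)
            stat = max(0.0, 2.0 * (full.loglik - red.loglik))
            rows.append({"term": term, "LRT": stat, "p": _p_mixture(stat),
                         "testable": True})
        except Exception:
            rows.append({"term": term, "LRT": np.nan, "p": np.nan,
                         "testable": False})
    return pd.DataFrame(rows)


STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, code in STAR_LEVELS:
        if p < level:
            return code
    return ""


@dataclass
class LoadingCovariateReport:
    """Factor x covariate Pearson correlations with p-values and stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.r.round(2).astype(str) + self.stars
        out.index.name = "covariate"
        return out


def loading_covariate_correlations(rot: RotatedFA, cov: CovariateTable,
                                   min_n: int = 4,
                                   bh_adjust: bool = False) -> LoadingCovariateReport:
    """Pearson correlations between rotated loadings and covariates.

    For each (factor, covariate) pair, r is computed over environments
    present in both tables with a finite covariate value; two-sided p-values
    come from t = r sqrt((n-2)/(1-r^2)). Raw p-values are starred at
    0.05/0.01/0.001; ``bh_adjust`` applies Benjamini-Hochberg across the
    grid instead.
    """
    envs = [e for e in rot.environments if e in set(cov.environments)]
    if len(envs) < min_n:
        raise ValueError(f"only {len(envs)} environments shared; need >= {min_n}")
    L = pd.DataFrame(rot.Lambda_rot, index=rot.environments)
    L = L.loc[envs]
    C = cov.table.loc[envs]
    k = L.shape[1]
    factors = [f"FA{j + 1}" for j in range(k)]
    r = pd.DataFrame(np.nan, index=C.columns, columns=factors)
    p = pd.DataFrame(np.nan, index=C.columns, columns=factors)
    nmat = pd.DataFrame(0, index=C.columns, columns=factors)
    for cname in C.columns:
        x = C[cname].to_numpy(float)
        ok = np.isfinite(x)
        for j, fname in enumerate(factors):
            yv = L.iloc[:, j].to_numpy(float)
            n = int(ok.sum())
            nmat.loc[cname, fname] = n
            if n < min_n or np.std(x[ok]) == 0 or np.std(yv[ok]) == 0:
                continue
            rr, pp = sps.pearsonr(x[ok], yv[ok])
            r.loc[cname, fname] = rr
            p.loc[cname, fname] = pp
    if bh_adjust:
        flat = p.to_numpy().ravel()
        ok = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if ok.sum():
            pv = flat[ok]
            order = np.argsort(pv)
            ranked = pv[order] * len(pv) / (np.arange(len(pv)) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            out = np.empty_like(ranked)
            out[order] = np.minimum(ranked, 1.0)
            adj[ok] = out
        p = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    stars = p.map(lambda v: _stars(v) if np.isfinite(v) else "")
    return LoadingCovariateReport(r=r, p=p, stars=stars, n=nmat)
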