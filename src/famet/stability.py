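"""Varimax rotation and latent-regression stability analysis.

The unrotated FA(k) loadings carry an arbitrary orthogonal gauge; varimax
rotation maximises the variance of squared loadings to obtain interpretable
simple structure. Genotype scores are co-rotated so the fitted genetic
effects Lambda scores' are unchanged, as are G_hat, the overall variance
explained and all genetic correlations.

The latent regression reads the rotated model genotype-wise: for factor r,
a genotype's predicted values across environments fall on the line

    value(x) = mean_BLUP_i + f_ir * x,

where x is the environment loading on factor r and the slope beta1 = f_ir is
the rotated genotype score. Slopes near zero mean stability (insensitivity
to the environmental gradient the factor captures); large positive slopes
mean responsiveness to environments loading high on that factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .fa_model import FAFit

LABELS = ("stable", "responsive", "negatively-responsive", "intermediate")


@dataclass
class RotatedFA:
    """Varimax-rotated loadings and co-rotated scores of an FA fit."""

    Lambda_rot: np.ndarray     # s x k
    scores_rot: np.ndarray     # m x k
    rotation: np.ndarray       # k x k orthonormal, Lambda_rot = Lambda @ rotation
    varimax_criterion: float
    explained_per_factor: np.ndarray   # percent, descending
    converged: bool = True
    environments: list[str] = field(default_factory=list)
    genotypes: list[str] = field(default_factory=list)


@dataclass
class StabilityTable:
    """Per-genotype-per-factor latent-regression slopes and plot data."""

    table: pd.DataFrame    # genotype, factor, slope, mean_blup[, label]
    points: pd.DataFrame   # factor, genotype, environment, loading, predicted, tested
    explained_per_factor: np.ndarray


def varimax_criterion(Lambda: np.ndarray) -> float:
    """Raw varimax objective: sum over factors of var of squared loadings."""
    L2 = np.asarray(Lambda, float) ** 2
    s = L2.shape[0]
    return float(np.sum(L2 ** 2) / s - np.sum((L2.sum(axis=0) / s) ** 2))


def varimax_rotate(fit: FAFit, kaiser_normalize: bool = False,
                   tol: float = 1e-10, max_iter: int = 1000) -> RotatedFA:
    """Varimax rotation of the FA loadings with score co-rotation.

    Factors are reordered by explained variance (descending) and column
    signs fixed so each column's largest-magnitude loading is positive.
    ``kaiser_normalize`` rescales rows to unit communality before rotating
    (raw varimax is the default).
    """
    Lambda = fit.Lambda.copy()
    s, k = Lambda.shape
    if k == 1:
        R = np.eye(1)
        L = Lambda.copy()
        converged = True
    else:
        work = Lambda.copy()
        comm = None
        if kaiser_normalize:
            comm = np.sqrt((work ** 2).sum(axis=1))
            comm[comm == 0] = 1.0
            work = work / comm[:, None]
        try:
            L, R = rotate_factors(work, "varimax", tol=tol, max_tries=max_iter)
            converged = True
        except Exception:
            L, R = work, np.eye(k)
            converged = False
        if kaiser_normalize:
            L = L * comm[:, None]
    # reorder by explained variance (sum of squared loadings), descending
    ss = (L ** 2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    R = R[:, order]
    # sign convention: largest-magnitude loading in each column positive
    for j in range(k):
        peak = np.argmax(np.abs(L[:, j]))
        if L[peak, j] < 0:
            L[:, j] = -L[:, j]
            R[:, j] = -R[:, j]
    scores_rot = fit.scores @ R
    denom = float((L ** 2).sum() + fit.Psi.sum())
    explained = 100.0 * (L ** 2).sum(axis=0) / denom
    return RotatedFA(Lambda_rot=L, scores_rot=scores_rot, rotation=R,
                     varimax_criterion=varimax_criterion(L),
                     explained_per_factor=explained, converged=converged,
                     environments=fit.environments, genotypes=fit.genotypes)


def latent_regression(rot: RotatedFA, fit: FAFit) -> StabilityTable:
    """Latent-regression table: slope beta1 per (genotype, factor) + plot data.

    The slope is the rotated genotype score; the intercept is the genotype's
    average predicted genetic value over all environments. The point cloud
    pairs each environment's rotated loading (x) with the genotype's
    predicted value there (y), flagged tested/untested.
    """
    genotypes, environments = fit.genotypes, fit.environments
    m, k = rot.scores_rot.shape
    mean_blup = fit.u_hat.mean(axis=1)
    rows = []
    for r in range(k):
        for i, g in enumerate(genotypes):
            rows.append({"genotype": g, "factor": r + 1,
                         "slope": float(rot.scores_rot[i, r]),
                         "mean_blup": float(mean_blup.iloc[i])})
    table = pd.DataFrame(rows)
    pts = []
    pred = fit.u_hat.to_numpy()
    tested = fit.tested.to_numpy()
    for r in range(k):
        x = rot.Lambda_rot[:, r]
        for i, g in enumerate(genotypes):
            for l, env in enumerate(environments):
                pts.append((r + 1, g, env, float(x[l]), float(pred[i, l]),
                            bool(tested[i, l])))
    points = pd.DataFrame(pts, columns=["factor", "genotype", "environment",
                                        "loading", "predicted", "tested"])
    return StabilityTable(table=table, points=points,
                          explained_per_factor=rot.explained_per_factor)


def classify_stability(table: StabilityTable, stable_band: float = 0.5,
                       responsive_threshold: float = 1.0) -> StabilityTable:
    """Label slopes: |b1| <= band -> stable; b1 >= thr -> responsive;
    b1 <= -thr -> negatively-responsive; else intermediate."""
    if stable_band <= 0 or responsive_threshold <= 0:
        raise ValueError("thresholds must be positive")
    b = table.table["slope"].to_numpy()
    labels = np.where(np.abs(b) <= stable_band, "stable",
                      np.where(b >= responsive_threshold, "responsive",
                               np.where(b <= -responsive_threshold,
                                        "negatively-responsive", "intermediate")))
    out = table.table.copy()
    out["label"] = labels
    return StabilityTable(table=out, points=table.points,
                          explained_per_factor=table.explained_per_factor)
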