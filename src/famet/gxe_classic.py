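"""AMMI and GGE decompositions of a genotype x environment means table.

AMMI (additive main effects and multiplicative interaction) removes the
grand mean and genotype/environment main effects by double-centering, then
decomposes the interaction residual by SVD; term n contributes singular
value lambda_n with orthonormal genotype scores xi_n and environment scores
eta_n, and is tested with the Gollob F statistic. GGE centers by environment
only (keeping genotype main effect + G x E) and plots the first two
symmetrically scaled principal components. Missing cells are imputed first
with an EM alternation of additive fill and low-rank SVD reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fa_model import _incidence_components


@dataclass
class TwoWayTable:
    """m x s genotype x environment means, with optional error information."""

    values: pd.DataFrame
    n_reps: int = 1
    resid_var: float | None = None   # pooled plot-level residual variance
    imputed: pd.DataFrame | None = None  # bool mask of EM-imputed cells

    def __post_init__(self):
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need >= 2 genotypes and >= 2 environments")

    @property
    def complete(self) -> bool:
        return not self.values.isna().any().any()


@dataclass
class AMMIResult:
    grand_mean: float
    genotype_effects: pd.Series
    env_effects: pd.Series
    singular_values: np.ndarray
    genotype_scores: pd.DataFrame   # m x n_terms (orthonormal columns)
    env_scores: pd.DataFrame        # s x n_terms
    ss_terms: np.ndarray            # lambda_n^2 per term (interaction SS share)
    ss_interaction: float
    anova: pd.DataFrame             # term, SS, pct_gxe, df, F, p
    n_significant: int | None


@dataclass
class GGEResult:
    genotype_coords: pd.DataFrame   # m x n_pcs, symmetric scaling
    env_coords: pd.DataFrame        # s x n_pcs
    proportions: np.ndarray         # per-PC share of G+GxE variance
    cumulative_12: float            # PC1+PC2 share
    degenerate: bool = False


def impute_two_way(table: TwoWayTable, rank: int = 1, tol: float = 1e-6,
                   max_iter: int = 20000) -> TwoWayTable:
    """EM imputation: alternate additive main-effect fill and rank-r SVD.

    Missing cells are initialised from the additive model (grand + row + col
    effects on observed cells) and refined by reconstructing the interaction
    residual at the requested rank until the largest imputed-cell change is
    below ``tol``. The missing pattern must keep the table connected and no
    row/column may be entirely missing.
    """
    Y = table.values.to_numpy(float).copy()
    mask = np.isnan(Y)
    if not mask.any():
        return table
    if mask.all(axis=1).any() or mask.all(axis=0).any():
        raise ValueError("a fully-missing row or column cannot be imputed")
    comps = _incidence_components(~mask)
    if len(comps) > 1:
        raise ValueError("missing pattern disconnects the table")
    obs = ~mask
    grand = np.nanmean(Y)
    row = np.where(obs.any(axis=1), np.nanmean(Y, axis=1), grand) - grand
    col = np.where(obs.any(axis=0), np.nanmean(Y, axis=0), grand) - grand
    Y[mask] = (grand + row[:, None] + col[None, :])[mask]
    for it in range(max_iter):
        gm = Y.mean()
        r = Y.mean(axis=1) - gm
        c = Y.mean(axis=0) - gm
        additive = gm + r[:, None] + c[None, :]
        resid = Y - additive
        U, sv, Vt = np.linalg.svd(resid, full_matrices=False)
        low = (U[:, :rank] * sv[:rank]) @ Vt[:rank]
        new = additive + low
        delta = np.max(np.abs(new[mask] - Y[mask])) if mask.any() else 0.0
        Y[mask] = new[mask]
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"EM imputation did not converge in {max_iter} iterations "
            f"(last change {delta:.3g})")
    vals = pd.DataFrame(Y, index=table.values.index, columns=table.values.columns)
    return TwoWayTable(values=vals, n_reps=table.n_reps,
                       resid_var=table.resid_var,
                       imputed=pd.DataFrame(mask, index=vals.index,
                                            columns=vals.columns))


def fit_ammi(table: TwoWayTable, n_terms: int | None = None,
             alpha: float = 0.05) -> AMMIResult:
    """AMMI decomposition of a complete two-way table.

    Both genotype and environment main effects are removed before the SVD
    (standard AMMI; the genotype effect belongs in the additive part even
    when a formula omits it). Gollob df_n = m + s - 1 - 2n; when a pooled
    residual variance and replicate count are available the F statistic is
    (lambda_n^2 / df_n) / (resid_var / n_reps) on the means scale.
    """
    if not table.complete:
        raise ValueError("AMMI requires a complete table; impute first")
    Y = table.values.to_numpy(float)
    m, s = Y.shape
    max_terms = min(m, s) - 1
    if n_terms is None:
        n_terms = max_terms
    if n_terms > max_terms:
        raise ValueError(f"n_terms={n_terms} exceeds min(m,s)-1={max_terms}")
    grand = Y.mean()
    a = Y.mean(axis=1) - grand
    b = Y.mean(axis=0) - grand
    inter = Y - grand - a[:, None] - b[None, :]
    ss_int = float(np.sum(inter ** 2))
    U, sv, Vt = np.linalg.svd(inter, full_matrices=False)
    sv = sv[:max_terms]
    U, Vt = U[:, :max_terms], Vt[:max_terms]
    ss_terms = sv ** 2
    dfs = np.array([m + s - 1 - 2 * (n + 1) for n in range(max_terms)], float)
    rows = []
    n_sig = None
    if table.resid_var is not None:
        err = table.resid_var / max(table.n_reps, 1)
        n_sig = 0
        counting = True
    for n in range(max_terms):
        F = p = np.nan
        if table.resid_var is not None and dfs[n] > 0:
            F = (ss_terms[n] / dfs[n]) / err
            # large-sample denominator df for the pooled error
            p = float(sps.f.sf(F, dfs[n], 1e6))
            if counting and p < alpha:
                n_sig += 1
            else:
                counting = False
        rows.append({"term": f"IPCA{n + 1}", "SS": ss_terms[n],
                     "pct_gxe": 100.0 * ss_terms[n] / ss_int if ss_int > 0 else 0.0,
                     "df": dfs[n], "F": F, "p": p})
    anova = pd.DataFrame(rows)
    gidx, eidx = table.values.index, table.values.columns
    return AMMIResult(
        grand_mean=float(grand),
        genotype_effects=pd.Series(a, index=gidx),
        env_effects=pd.Series(b, index=eidx),
        singular_values=sv[:n_terms],
        genotype_scores=pd.DataFrame(U[:, :n_terms], index=gidx,
                                     columns=[f"IPCA{j + 1}" for j in range(n_terms)]),
        env_scores=pd.DataFrame(Vt[:n_terms].T, index=eidx,
                                columns=[f"IPCA{j + 1}" for j in range(n_terms)]),
        ss_terms=ss_terms, ss_interaction=ss_int,
        anova=anova, n_significant=n_sig)


def ammi_stability_ranking(res: AMMIResult) -> pd.DataFrame:
    """Genotypes ranked by |IPCA1| ascending (most stable first).

    Ties are broken by genotype main effect, descending (higher-yielding
    genotype ranks first among equally stable ones).
    """
    if res.genotype_scores.shape[1] < 1:
        raise ValueError("no fitted multiplicative term")
    ip1 = res.genotype_scores.iloc[:, 0] * res.singular_values[0]
    df = pd.DataFrame({
        "genotype": res.genotype_scores.index,
        "IPCA1": ip1.values,
        "abs_IPCA1": np.abs(ip1.values),
        "main_effect": res.genotype_effects.values,
    })
    df = df.sort_values(["abs_IPCA1", "main_effect"],
                        ascending=[True, False], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def fit_gge(table: TwoWayTable, n_pcs: int = 2) -> GGEResult:
    """GGE decomposition: environment-centered SVD with symmetric scaling.

    Centering subtracts environment means, so the decomposed matrix carries
    genotype main effects plus G x E. Coordinates assign sqrt(lambda_n) to
    both sides; PC proportions are lambda_n^2 / sum lambda^2.
    """
    if not table.complete:
        raise ValueError("GGE requires a complete table; impute first")
    Y = table.values.to_numpy(float)
    m, s = Y.shape
    if n_pcs > min(m, s):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(m,s)={min(m, s)}")
    centered = Y - Y.mean(axis=0)[None, :]
    U, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(sv ** 2))
    if total <= 1e-12:
        return GGEResult(
            genotype_coords=pd.DataFrame(np.zeros((m, n_pcs)),
                                         index=table.values.index,
                                         columns=[f"PC{j + 1}" for j in range(n_pcs)]),
            env_coords=pd.DataFrame(np.zeros((s, n_pcs)),
                                    index=table.values.columns,
                                    columns=[f"PC{j + 1}" for j in range(n_pcs)]),
            proportions=np.zeros(n_pcs), cumulative_12=0.0, degenerate=True)
    props = sv ** 2 / total
    root = np.sqrt(sv[:n_pcs])
    cols = [f"PC{j + 1}" for j in range(n_pcs)]
    gen = pd.DataFrame(U[:, :n_pcs] * root[None, :], index=table.values.index,
                       columns=cols)
    env = pd.DataFrame(Vt[:n_pcs].T * root[None, :], index=table.values.columns,
                       columns=cols)
    cum12 = float(props[:min(2, len(props))].sum())
    return GGEResult(genotype_coords=gen, env_coords=env,
                     proportions=props[:n_pcs], cumulative_12=cum12)
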