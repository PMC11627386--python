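"""Synthetic MET generator with factor-analytic genetic structure.

Generates plot-level multi-environment trial datasets under exactly the
generative model the downstream joint analysis assumes: genotype effects
across s environments drawn from N(0, G) with G = Lambda Lambda' + diag(Psi)
(k latent factors, diagonal specific variances), heterogeneous
environment-specific residual variances, RCBD replicates within trials, and
optional MCAR cell-level unbalance constrained to keep the design connected.
Environment covariates can be engineered to a target correlation with the
first-factor loadings.

Defaults emulate a cassava variety-trial programme: 22 genotypes, 20
environments (year x location), 3 replicates, yields on the t/ha scale with
a grand mean of 24 t/ha, and single-trial heritabilities mostly in the
0.5-0.8 band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import CovariateTable, MetDataset, RECORD_COLUMNS


@dataclass
class SimConfig:
    """Generating parameters of a synthetic MET study.

    Units follow the fresh-root-yield convention (t/ha). ``loading_sd``
    controls the spread of factor loadings, hence the genetic covariance
    scale; ``psi_range`` bounds the environment-specific genetic variances;
    ``resid_sd_range`` bounds plot-level residual SDs per environment.
    """

    m: int = 22                    # genotypes
    s: int = 20                    # environments (= trials)
    k_true: int = 2                # latent factors
    reps: int = 3                  # RCBD replicates per trial
    mu: float = 24.0               # grand mean, t/ha
    env_effects_sd: float = 6.0    # spread of environment main effects
    loading_sd: float = 1.5
    loading_mean_f1: float = 1.5   # positive shift of first-factor loadings
    psi_range: tuple[float, float] = (0.5, 2.0)
    resid_sd_range: tuple[float, float] = (1.8, 3.6)
    rep_sd: float = 0.8
    missing_cell_rate: float = 0.0
    min_env_coverage: float = 0.5
    covariate_target_r: float = 0.58
    trait: str = "FRY"
    seed: int = 0

    def __post_init__(self):
        if not self.m > self.k_true >= 1:
            raise ValueError(f"require m > k_true >= 1, got m={self.m}, k_true={self.k_true}")
        if self.s < self.k_true:
            raise ValueError(f"require s >= k_true, got s={self.s}, k_true={self.k_true}")
        if min(self.psi_range) <= 0 or min(self.resid_sd_range) <= 0:
            raise ValueError("psi_range and resid_sd_range must be positive")
        if not (0.0 <= self.missing_cell_rate < 1.0):
            raise ValueError("missing_cell_rate must lie in [0, 1)")
        if not (0.0 < self.min_env_coverage <= 1.0):
            raise ValueError("min_env_coverage must lie in (0, 1]")
        if not (-1.0 < self.covariate_target_r < 1.0):
            raise ValueError("covariate_target_r must lie strictly in (-1, 1)")


@dataclass
class SimTruth:
    """Ground-truth parameters of one simulation run (for recovery checks)."""

    Lambda_true: np.ndarray   # s x k loadings
    Psi_true: np.ndarray      # s specific variances
    scores_true: np.ndarray   # m x k genotype factor scores
    G_true: np.ndarray        # s x s = Lambda Lambda' + diag(Psi)
    env_means: np.ndarray     # s environment main effects
    resid_sd: np.ndarray      # s plot-level residual SDs
    genetic_effects: np.ndarray  # m x s genotype-in-environment effects
    genotypes: list[str] = field(default_factory=list)
    environments: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _env_names(s: int) -> list[str]:
    # canonical "<year>.<location-code>" keys in the trial-label style
    locs = ["NH", "SA", "UFV", "RA1", "AL", "ALC", "NR", "GM", "PP", "ITAM",
            "UFRB", "SV", "RIOS", "GA", "RA2", "WX", "DOU", "ER", "FL", "LJ"]
    names = []
    for j in range(s):
        year = 2013 + (j % 9)
        loc = locs[j % len(locs)]
        suffix = "" if j < len(locs) else str(j // len(locs) + 1)
        names.append(f"{year}.ERU.{loc}{suffix}")
    return names


def simulate_met(config: SimConfig) -> tuple[MetDataset, SimTruth]:
    """Draw one plot-level MET dataset from the FA generative model.

    Plot value = mu + env_mean_l + rep_effect(l, r) + u_il + eps, where the
    m x s matrix u has rows with covariance G = Lambda Lambda' + diag(Psi)
    (u = scores Lambda' + specific deviations) and eps ~ N(0, resid_sd_l^2).
    Fully reproducible from ``config.seed``; unbalance is applied afterwards
    when ``missing_cell_rate`` > 0.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m, s, k = cfg.m, cfg.s, cfg.k_true
    Lambda = rng.normal(0.0, cfg.loading_sd, size=(s, k))
    # a dominant first factor with mostly-positive loadings gives the positive
    # between-environment genetic correlations typical of real METs (and a
    # nonzero genotype main effect in the compound joint model)
    Lambda[:, 0] += cfg.loading_mean_f1
    Psi = rng.uniform(*cfg.psi_range, size=s)
    scores = rng.standard_normal((m, k))
    specific = rng.standard_normal((m, s)) * np.sqrt(Psi)[None, :]
    u = scores @ Lambda.T + specific
    G = Lambda @ Lambda.T + np.diag(Psi)
    env_means = rng.normal(0.0, cfg.env_effects_sd, size=s)
    resid_sd = rng.uniform(*cfg.resid_sd_range, size=s)
    rep_eff = rng.normal(0.0, cfg.rep_sd, size=(s, cfg.reps))

    genotypes = [f"G{i + 1:03d}" for i in range(m)]
    environments = _env_names(s)
    years = [int(e.split(".")[0]) for e in environments]
    locs = [e.split(".", 1)[1] for e in environments]

    n = m * s * cfg.reps
    eps = rng.standard_normal((m, s, cfg.reps)) * resid_sd[None, :, None]
    vals = (cfg.mu + env_means[None, :, None] + rep_eff[None, :, :]
            + u[:, :, None] + eps)
    gi, li, ri = np.meshgrid(np.arange(m), np.arange(s), np.arange(cfg.reps),
                             indexing="ij")
    df = pd.DataFrame({
        "environment": np.array(environments)[li.ravel()],
        "year": np.array(years)[li.ravel()],
        "location": np.array(locs)[li.ravel()],
        "genotype": np.array(genotypes)[gi.ravel()],
        "replicate": ri.ravel() + 1,
        "block": "",
        "trait": cfg.trait,
        "value": vals.ravel(),
    })[RECORD_COLUMNS]
    data = MetDataset(records=df, trait=cfg.trait)
    truth = SimTruth(Lambda_true=Lambda, Psi_true=Psi, scores_true=scores,
                     G_true=G, env_means=env_means, resid_sd=resid_sd,
                     genetic_effects=u, genotypes=genotypes,
                     environments=environments)
    if cfg.missing_cell_rate > 0:
        data = apply_unbalance(data, cfg)
    return data, truth


def _env_graph_connected(inc: np.ndarray) -> bool:
    """Connectivity of the environment-sharing graph given an m x s 0/1 incidence."""
    s = inc.shape[1]
    adj = (inc.T @ inc) >= 1
    seen = np.zeros(s, bool)
    stack = [0]
    seen[0] = True
    while stack:
        a = stack.pop()
        for b in np.nonzero(adj[a])[0]:
            if not seen[b]:
                seen[b] = True
                stack.append(b)
    return bool(seen.all())


def apply_unbalance(data: MetDataset, config: SimConfig) -> MetDataset:
    """Remove whole genotype x environment cells completely at random.

    Removal respects two constraints: every genotype keeps at least
    ``min_env_coverage`` of the environments, and the environment-sharing
    graph stays connected. Raises if the requested rate is infeasible,
    reporting the maximum feasible rate found.
    """
    cfg = config
    if cfg.missing_cell_rate >= 1.0:
        raise ValueError("missing_cell_rate must be < 1")
    if cfg.missing_cell_rate == 0.0:
        return data
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    genotypes = data.genotypes
    environments = data.environments
    m, s = len(genotypes), len(environments)
    inc = data.incidence.reindex(index=genotypes, columns=environments).to_numpy(int)
    min_envs = int(np.ceil(cfg.min_env_coverage * s))
    target = int(np.floor(cfg.missing_cell_rate * m * s))
    cells = [(i, l) for i in range(m) for l in range(s) if inc[i, l]]
    rng.shuffle(cells)
    removed = []
    for (i, l) in cells:
        if len(removed) >= target:
            break
        if inc[i].sum() - 1 < min_envs:
            continue
        if inc[:, l].sum() - 1 < 3:   # keep every environment analysable (>= 3 genotypes)
            continue
        inc[i, l] = 0
        if _env_graph_connected(inc):
            removed.append((i, l))
        else:
            inc[i, l] = 1
    if len(removed) < target:
        feasible = len(removed) / (m * s)
        raise ValueError(
            f"cannot remove {target} cells at rate {cfg.missing_cell_rate} under "
            f"coverage>={cfg.min_env_coverage} and connectivity; max feasible "
            f"rate ~ {feasible:.3f}")
    drop = {(genotypes[i], environments[l]) for (i, l) in removed}
    rec = data.records
    keys = list(zip(rec["genotype"], rec["environment"]))
    keep = np.array([kv not in drop for kv in keys])
    return MetDataset(records=rec[keep].reset_index(drop=True), trait=data.trait)


def simulate_covariates(truth: SimTruth, target_r: float, seed: int) -> CovariateTable:
    """Environment covariates with one engineered predictor of the first factor.

    The engineered covariate (``Rain``) is the analytic mixture
    c = r z(Lambda_1) + sqrt(1 - r^2) z(noise) on standardized vectors, so its
    *population* correlation with the first-column loadings is ``target_r``;
    the remaining covariates are independent nuisance variables on realistic
    weather-station scales.
    """
    s = truth.Lambda_true.shape[0]
    if s < 3:
        raise ValueError("need at least 3 environments for correlations")
    if not (-1.0 < target_r < 1.0):
        raise ValueError(f"target_r must lie strictly in (-1, 1), got {target_r}")
    rng = np.random.default_rng(seed)

    def z(x):
        sd = x.std()
        if sd == 0:
            raise ValueError("degenerate (constant) loading column")
        return (x - x.mean()) / sd

    lam1 = z(truth.Lambda_true[:, 0])
    noise = z(rng.standard_normal(s))
    c = target_r * lam1 + np.sqrt(1.0 - target_r ** 2) * noise
    tmax = rng.normal(30.0, 2.0, s)
    tmin = rng.normal(20.0, 2.0, s)
    tab = pd.DataFrame({
        "Tmax": tmax,
        "Tmin": tmin,
        "Tav": (tmax + tmin) / 2 + rng.normal(0.0, 0.5, s),
        "Rain": 1100.0 + 350.0 * c,
        "Rh": rng.normal(75.0, 4.0, s),
        "Wspeed": np.abs(rng.normal(2.0, 1.0, s)) + 0.1,
        "Solrad": rng.normal(18.0, 2.0, s),
        "Altitude": rng.uniform(10.0, 900.0, s),
    }, index=pd.Index(truth.environments or [f"E{j}" for j in range(s)],
                      name="environment"))
    return CovariateTable(table=tab)
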