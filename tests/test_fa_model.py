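import numpy as np
import pandas as pd
import pytest
from scipy.linalg import block_diag

from famet import (FAFit, MeansTable, SimConfig, build_means_table,
                   fa_reml_loglik, fit_accuracy, fit_all_trials, fit_fa,
                   genetic_correlation_matrix, model_search, n_params,
                   predict_genotype_env, simulate_met, variance_explained)

_LOG2PI = np.log(2.0 * np.pi)


def dense_reml_oracle(Y, Sigma_tot):
    """Brute-force restricted loglik: one dense covariance over all cells."""
    m, s = Y.shape
    yv, Xs, blocks = [], [], []
    for i in range(m):
        idx = np.nonzero(~np.isnan(Y[i]))[0]
        if idx.size == 0:
            continue
        yv.append(Y[i, idx])
        E = np.zeros((idx.size, s))
        E[np.arange(idx.size), idx] = 1.0
        Xs.append(E)
        blocks.append(Sigma_tot[np.ix_(idx, idx)])
    y = np.concatenate(yv)
    X = np.vstack(Xs)
    V = block_diag(*blocks)
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1]
                   + r @ Vi @ r + (n - p) * _LOG2PI)


def _manual_fit(Lambda, Psi, scores, envs=None, genos=None):
    """Construct an FAFit directly from parameters (no estimation)."""
    s, k = Lambda.shape
    m = scores.shape[0]
    envs = envs or [f"E{j}" for j in range(s)]
    genos = genos or [f"G{i}" for i in range(m)]
    u = scores @ Lambda.T
    return FAFit(k=k, Lambda=Lambda, Psi=Psi, scores=scores,
                 env_intercepts=pd.Series(np.zeros(s), index=envs),
                 stage2_resid=np.zeros(s),
                 G_hat=Lambda @ Lambda.T + np.diag(Psi),
                 logREML=0.0, n_params=n_params(s, k), AIC=0.0,
                 u_hat=pd.DataFrame(u, index=genos, columns=envs),
                 tested=pd.DataFrame(True, index=genos, columns=envs),
                 converged=True, genotypes=genos, environments=envs,
                 n_obs=m * s)


class TestLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, s, k = 20, 5, 2
        Y = rng.normal(20, 3, (m, s))
        # unbalanced pattern, keeping >= 3 genotypes per environment
        drop = rng.random((m, s)) < 0.2
        for l in range(s):
            if (~drop[:, l]).sum() < 3:
                drop[:3, l] = False
        Y[drop] = np.nan
        Y[np.isnan(Y).all(axis=1)] = 20.0
        means = MeansTable(values=pd.DataFrame(Y))
        Lambda = rng.normal(0, 1, (s, k))
        Psi = rng.uniform(0.5, 2, s)
        d = rng.uniform(0.1, 0.4, s)
        ours = fa_reml_loglik(means, Lambda, Psi, d)
        oracle = dense_reml_oracle(means.values.to_numpy(),
                                   Lambda @ Lambda.T + np.diag(Psi + d))
        assert ours == pytest.approx(oracle, rel=1e-8)

    def test_optimal_vs_generating_values(self, small_fit):
        means, fit, truth = small_fit
        perm = [truth.environments.index(e) for e in means.environments]
        ll_truth = fa_reml_loglik(means, truth.Lambda_true[perm],
                                  truth.Psi_true[perm], fit.stage2_resid)
        assert fit.logREML >= ll_truth - 1e-6


class TestNParams:
    @pytest.mark.parametrize("s,k,expected", [(10, 2, 29), (10, 1, 20), (10, 0, 10)])
    def test_counting(self, s, k, expected):
        assert n_params(s, k) == expected

    def test_stage2_resid_adds_s(self):
        assert n_params(10, 2, include_stage2_resid=True) == 39

    def test_k_exceeds_s(self):
        with pytest.raises(ValueError):
            n_params(3, 4)


class TestBuildMeansTable:
    def test_complete_trials(self, small_study):
        _, data, _ = small_study
        fits = fit_all_trials(data, seed=11)
        means = build_means_table(fits)
        assert means.values.shape == (40, 6)
        assert means.se is not None

    def test_missing_cell_where_absent(self, small_study):
        _, data, _ = small_study
        fits = fit_all_trials(data, seed=11)
        means = build_means_table(fits)
        inc = data.incidence.reindex(index=means.genotypes,
                                     columns=means.environments)
        assert (means.values.notna().to_numpy() == inc.to_numpy()).all()

    def test_disconnected_rejected(self):
        Y = np.full((6, 4), np.nan)
        Y[:3, :2] = 1.0
        Y[3:, 2:] = 2.0
        with pytest.raises(ValueError, match="disconnected"):
            MeansTable(values=pd.DataFrame(Y))


class TestFitFA:
    def test_rank_one_limit(self):
        # k_true=1, psi ~ 0: all fitted genetic correlations near +-1
        cfg = SimConfig(m=400, s=5, k_true=1, reps=2, seed=13,
                        psi_range=(1e-6, 2e-6), resid_sd_range=(0.3, 0.5))
        data, _ = simulate_met(cfg)
        fits = fit_all_trials(data, seed=13)
        means = build_means_table(fits)
        fit = fit_fa(means, 1, stage2_resid="fixed", seed=13)
        rho = genetic_correlation_matrix(fit).to_numpy()
        assert (np.abs(rho) > 0.95).all()

    def test_saturated_limit_reproduces_sample_cov(self):
        rng = np.random.default_rng(21)
        m, s = 150, 4
        A = rng.normal(0, 1, (s, s))
        Sigma = A @ A.T + 0.5 * np.eye(s)
        Y = rng.multivariate_normal(np.zeros(s), Sigma, size=m) + 20.0
        means = MeansTable(values=pd.DataFrame(Y))
        fit = fit_fa(means, s - 1, seed=21)
        S = np.cov(Y.T, ddof=1)
        Sigma_fit = fit.G_hat  # absorb mode: G_hat is the full cell covariance
        assert np.linalg.norm(Sigma_fit - S, "fro") / np.linalg.norm(S, "fro") < 0.02

    def test_k_out_of_range(self, small_fit):
        means, _, _ = small_fit
        with pytest.raises(ValueError):
            fit_fa(means, 0)
        with pytest.raises(ValueError):
            fit_fa(means, len(means.environments))

    def test_diag_identity(self, small_fit):
        _, fit, _ = small_fit
        assert np.allclose(np.diag(fit.G_hat),
                           (fit.Lambda ** 2).sum(axis=1) + fit.Psi)
        assert np.allclose(fit.G_hat, fit.G_hat.T)

    def test_upper_triangle_gauge(self, small_fit):
        _, fit, _ = small_fit
        k = fit.k
        assert np.allclose(np.triu(fit.Lambda[:k, :], 1), 0.0)

    def test_json_roundtrip(self, small_fit, tmp_path):
        _, fit, _ = small_fit
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FAFit.from_json(path)
        assert np.allclose(back.Lambda, fit.Lambda)
        assert np.allclose(back.u_hat.to_numpy(), fit.u_hat.to_numpy())
        assert back.environments == fit.environments


class TestModelSearch:
    def test_monotone_nesting_and_table(self, small_fit):
        means, _, _ = small_fit
        search = model_search(means, k_range=[1, 2, 3], stage2_resid="fixed",
                              seed=11)
        ll = search.table["logREML"].to_numpy()
        assert (np.diff(ll) >= -1e-6).all()
        assert list(search.table["Model"]) == ["FA1", "FA2", "FA3"]
        assert search.best_k in (1, 2, 3)

    def test_aic_formula(self, small_fit):
        means, _, _ = small_fit
        search = model_search(means, k_range=[1, 2], stage2_resid="fixed", seed=11)
        row = search.table.iloc[0]
        assert row["AIC"] == pytest.approx(-2 * row["logREML"] + 2 * row["NP"])

    def test_single_order(self, small_fit):
        means, _, _ = small_fit
        search = model_search(means, k_range=[1], stage2_resid="fixed", seed=11)
        assert search.best_k == 1

    def test_selects_true_order_strong_signal(self):
        hits = 0
        for seed in range(3):
            cfg = SimConfig(m=150, s=8, k_true=2, reps=2, seed=seed + 200)
            data, _ = simulate_met(cfg)
            means = build_means_table(fit_all_trials(data, seed=seed))
            search = model_search(means, k_range=[1, 2, 3],
                                  stage2_resid="fixed", seed=seed)
            hits += search.best_k == 2
        assert hits >= 2


class TestDerivedQuantities:
    def test_variance_explained_examples(self):
        lam = np.zeros((3, 1))
        lam[:, 0] = np.sqrt([3.0, 3.0, 3.0])     # tr LL' = 9
        psi = np.array([0.4, 0.3, 0.3])          # tr psi = 1
        fit = _manual_fit(lam, psi, np.zeros((4, 1)))
        overall, per = variance_explained(fit)
        assert overall == pytest.approx(90.0)
        fit0 = _manual_fit(lam, np.zeros(3), np.zeros((4, 1)))
        assert variance_explained(fit0)[0] == pytest.approx(100.0)

    def test_variance_explained_additive(self):
        lam = np.zeros((4, 2))
        lam[:, 0] = np.sqrt(6.0 / 4.0)
        lam[:, 1] = [np.sqrt(3.0), 0, 0, 0]
        psi = np.full(4, 0.25)
        overall, per = variance_explained(_manual_fit(lam, psi, np.zeros((4, 2))))
        assert per[0] == pytest.approx(60.0)
        assert per[1] == pytest.approx(30.0)
        assert overall == pytest.approx(90.0)
        assert overall == pytest.approx(per.sum())

    def test_correlation_rank_one(self):
        lam = np.array([[1.0], [2.0], [-1.5]])
        fit = _manual_fit(lam, np.zeros(3), np.zeros((4, 1)))
        rho = genetic_correlation_matrix(fit).to_numpy()
        assert np.allclose(np.abs(rho), 1.0)
        assert rho[0, 2] == pytest.approx(-1.0)

    def test_correlation_zero_loading_row(self):
        lam = np.array([[1.0], [0.0], [2.0]])
        fit = _manual_fit(lam, np.array([0.0, 1.0, 0.0]), np.zeros((4, 1)))
        rho = genetic_correlation_matrix(fit).to_numpy()
        assert rho[1, 0] == pytest.approx(0.0)
        assert rho[1, 2] == pytest.approx(0.0)

    def test_correlation_psd_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            s, k = rng.integers(3, 9), rng.integers(1, 4)
            lam = rng.normal(0, 1, (s, k))
            psi = rng.uniform(0.05, 2, s)
            fit = _manual_fit(lam, psi, np.zeros((4, k)))
            w = np.linalg.eigvalsh(genetic_correlation_matrix(fit).to_numpy())
            assert w.min() >= -1e-10

    def test_rotational_invariance_of_G(self, small_fit):
        _, fit, _ = small_fit
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(0, 1, (fit.k, fit.k)))
        G_rot = (fit.Lambda @ Q) @ (fit.Lambda @ Q).T + np.diag(fit.Psi)
        assert np.allclose(G_rot, fit.G_hat, atol=1e-8)


class TestPrediction:
    def test_observed_cells_track_means(self, small_fit):
        means, fit, _ = small_fit
        assert fit_accuracy(fit, means) > 0.9

    def test_every_cell_filled_with_flags(self, small_fit):
        means, fit, _ = small_fit
        pred = predict_genotype_env(fit)
        assert len(pred) == len(fit.genotypes) * len(fit.environments)
        assert pred["predicted"].notna().all()
        assert pred["tested"].sum() == int(means.values.notna().sum().sum())

    def test_untested_beats_column_mean(self):
        # hold out cells; FA predictions should beat the env-mean baseline
        cfg = SimConfig(m=80, s=6, k_true=2, reps=2, seed=33,
                        missing_cell_rate=0.2)
        data, truth = simulate_met(cfg)
        means = build_means_table(fit_all_trials(data, seed=33))
        fit = fit_fa(means, 2, stage2_resid="fixed", seed=33)
        perm = [truth.environments.index(e) for e in means.environments]
        u_true = truth.genetic_effects[:, perm]
        gidx = [truth.genotypes.index(g) for g in means.genotypes]
        u_true = u_true[gidx]
        mask = means.values.notna().to_numpy()
        untested = ~mask
        pred_err = np.abs(fit.u_hat.to_numpy()[untested] - u_true[untested])
        base_err = np.abs(0.0 - u_true[untested])  # env mean = zero genetic effect
        assert pred_err.mean() < base_err.mean()

    def test_zero_scores_predict_intercept(self):
        lam = np.array([[1.0], [2.0]])
        fit = _manual_fit(lam, np.zeros(2), np.zeros((3, 1)))
        pred = predict_genotype_env(fit)
        assert np.allclose(pred["predicted"], 0.0)  # intercepts are zero

    def test_perfect_fit_accuracy(self):
        lam = np.array([[1.0], [2.0]])
        scores = np.array([[1.0], [-1.0], [0.5]])
        fit = _manual_fit(lam, np.zeros(2), scores)
        means = MeansTable(values=fit.u_hat.copy())
        assert fit_accuracy(fit, means) == pytest.approx(1.0)
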