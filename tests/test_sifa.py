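"""EM estimation, identifiability gauge, rank selection, sparsification."""

import warnings

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from simfa.data_model import CovariateDesign, FeatureBlock, MultiModalDataset
from simfa.sifa import (
    SIFAError,
    SIFAFit,
    SIFAModel,
    SIFARanks,
    apply_identifiability,
    em_fit,
    observed_loglik,
    posterior_scores,
    select_ranks_lcv,
    sparsify_loadings,
    validate_identifiability,
    variance_explained,
)
from simfa.synthetic import SimulationConfig, simulate_sifa_dataset


def _single_block_ds(X, modality="volume"):
    n = X.shape[0]
    ids = [f"s{i}" for i in range(n)]
    blk = FeatureBlock(modality, X, [f"f{j}" for j in range(X.shape[1])], ids,
                       standardized=True)
    cov = CovariateDesign(np.empty((n, 0)), [], np.array(["HC"] * n, object),
                          ids)
    return MultiModalDataset([blk], cov)


def _quiet_fit(ds, ranks, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return em_fit(ds, ranks, **kw)


class TestObservedLoglik:
    def test_no_factor_limit_is_diagonal_gaussian(self, small_sim):
        _, ds, _ = small_sim
        p = ds.block_dims
        model = SIFAModel(
            B0=np.empty((ds.covariates.n_covariates, 0)),
            Bk=[np.empty((ds.covariates.n_covariates, 0)) for _ in p],
            V0k=[np.empty((pk, 0)) for pk in p],
            Vk=[np.empty((pk, 0)) for pk in p],
            tau0=np.empty(0),
            tauk=[np.empty(0) for _ in p],
            sigma2=np.array([1.3, 0.7]),
        )
        ll = observed_loglik(model, ds)
        X = ds.concatenated()
        d = np.concatenate([np.full(p[0], 1.3), np.full(p[1], 0.7)])
        expected = (
            -0.5 * X.shape[0] * (len(d) * np.log(2 * np.pi) + np.log(d).sum())
            - 0.5 * (X**2 / d).sum()
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_woodbury_matches_dense_covariance(self, small_sim, small_fit):
        _, ds, _ = small_sim
        m = small_fit.model
        # dense evaluation: concatenated mean and covariance, p <= 30
        p = sum(m.p)
        W = np.zeros((p, m.ranks.total))
        row = 0
        col_j = m.ranks.r0
        for k, pk in enumerate(m.p):
            W[row : row + pk, : m.ranks.r0] = m.V0k[k]
            W[row : row + pk, col_j : col_j + m.ranks.r[k]] = m.Vk[k]
            col_j += m.ranks.r[k]
            row += pk
        T = np.concatenate([m.tau0] + list(m.tauk))
        D = np.concatenate([np.full(pk, m.sigma2[k]) for k, pk in enumerate(m.p)])
        Sigma = W @ np.diag(T) @ W.T + np.diag(D)
        B_all = np.concatenate([m.B0] + list(m.Bk), axis=1)
        mean = ds.covariates.Y @ B_all @ W.T
        X = ds.concatenated()
        dense = sum(
            multivariate_normal.logpdf(X[i], mean=mean[i], cov=Sigma)
            for i in range(X.shape[0])
        )
        assert observed_loglik(m, ds) == pytest.approx(dense, abs=1e-8)

    def test_truth_beats_perturbed_truth_on_average(self):
        diffs = []
        for seed in range(10):
            cfg = SimulationConfig(n=150, p=(15, 12), r0=1, r=(1, 1),
                                   seed=seed, snr=3.0)
            ds, truth = simulate_sifa_dataset(cfg)
            rng = np.random.default_rng(seed)
            pert = truth.model.copy()
            pert.V0k = [V + 0.3 * rng.standard_normal(V.shape)
                        for V in pert.V0k]
            diffs.append(
                observed_loglik(truth.model, ds)
                - observed_loglik(pert, ds)
            )
        assert np.mean(diffs) > 0

    def test_nonpositive_variance_rejected(self, small_sim, small_fit):
        _, ds, _ = small_sim
        bad = small_fit.model.copy()
        bad.sigma2 = np.array([1.0, -0.1])
        with pytest.raises(SIFAError):
            observed_loglik(bad, ds)


class TestEMFit:
    def test_noiseless_rank1_recovers_loading_direction(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((200, 1))
        v = rng.standard_normal((10, 1))
        X = u @ v.T + 1e-9 * rng.standard_normal((200, 10))
        ds = _single_block_ds(X)
        fit = _quiet_fit(ds, SIFARanks(0, (1,)), tol=1e-12, max_iter=2000)
        vhat = fit.model.Vk[0][:, 0]
        cos = abs(vhat @ v[:, 0]) / (np.linalg.norm(vhat) * np.linalg.norm(v))
        assert np.arccos(min(cos, 1.0)) < 1e-6

    def test_reduces_to_probabilistic_pca(self):
        rng = np.random.default_rng(1)
        n, p, r = 400, 14, 2
        W = rng.standard_normal((p, r)) * 1.5
        X = rng.standard_normal((n, r)) @ W.T + 0.8 * rng.standard_normal((n, p))
        X = X - X.mean(axis=0)
        ds = _single_block_ds(X)
        fit = _quiet_fit(ds, SIFARanks(0, (r,)), tol=1e-12, max_iter=5000)
        ev = np.sort(np.linalg.eigvalsh(X.T @ X / n))[::-1]
        assert fit.model.sigma2[0] == pytest.approx(ev[r:].mean(), abs=1e-4)
        # loading span equals the top-r eigenvector span
        evec = np.linalg.eigh(X.T @ X / n)[1][:, ::-1][:, :r]
        Q, _ = np.linalg.qr(fit.model.Vk[0])
        s = np.linalg.svd(evec.T @ Q, compute_uv=False)
        assert np.max(np.arccos(np.clip(s, 0, 1))) < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_trace_monotone(self, seed):
        cfg = SimulationConfig(n=80, p=(10, 8), r0=1, r=(1, 1), seed=seed,
                               snr=1.5)
        ds, _ = simulate_sifa_dataset(cfg)
        fit = _quiet_fit(ds, SIFARanks(1, (1, 1)), seed=seed, jitter=0.05,
                         max_iter=150)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_nonconvergence_warns_not_silent(self, small_sim):
        _, ds, _ = small_sim
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = em_fit(ds, SIFARanks(1, (1, 1)), max_iter=3)
        assert not fit.converged

    def test_invalid_ranks_rejected(self, small_sim):
        _, ds, _ = small_sim
        with pytest.raises(SIFAError, match="rank"):
            em_fit(ds, SIFARanks(10, (5, 5)))

    def test_all_zero_ranks_fit_isotropic_noise(self, small_sim):
        _, ds, _ = small_sim
        fit = _quiet_fit(ds, SIFARanks(0, (0, 0)), max_iter=10)
        for k, blk in enumerate(ds.blocks):
            assert fit.model.sigma2[k] == pytest.approx(
                np.mean(blk.values**2), rel=1e-6
            )


class TestIdentifiability:
    def test_idempotent_on_canonical_model(self, small_fit):
        m = small_fit.model
        again = apply_identifiability(m)
        for a, b in zip(m.V0k + m.Vk, again.V0k + again.Vk):
            np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(m.B0, again.B0, atol=1e-12)

    def test_likelihood_invariance(self, small_sim, small_fit):
        _, ds, _ = small_sim
        rng = np.random.default_rng(0)
        messy = small_fit.model.copy()
        # scramble the gauge: arbitrary positive score variances
        messy.tau0 = rng.uniform(0.5, 2.0, messy.ranks.r0)
        messy.V0k = [V / np.sqrt(messy.tau0) for V in messy.V0k]
        messy.B0 = messy.B0 * np.sqrt(messy.tau0)
        ll_before = observed_loglik(messy, ds)
        ll_after = observed_loglik(apply_identifiability(messy), ds)
        assert ll_after == pytest.approx(ll_before, abs=1e-8)

    def test_random_mixing_round_trip(self):
        cfg = SimulationConfig(n=100, p=(20, 16), r0=2, r=(2, 1), seed=6,
                               snr=3.0)
        _, truth = simulate_sifa_dataset(cfg)
        canon = truth.model
        rng = np.random.default_rng(7)
        mixed = canon.copy()
        # mix joint factors by a random invertible matrix, compensating the
        # score distribution: u' = A^{-1} u has covariance A^{-1} A^{-T},
        # so absorb by scaling only (diagonal mix keeps tau diagonal)
        scales = rng.uniform(0.3, 3.0, canon.ranks.r0)
        mixed.V0k = [V * scales for V in mixed.V0k]
        mixed.tau0 = canon.tau0 / scales**2
        mixed.B0 = canon.B0 / scales
        back = apply_identifiability(mixed)
        for Va, Vb in zip(back.V0k, canon.V0k):
            np.testing.assert_allclose(Va, Vb, atol=1e-6)
        np.testing.assert_allclose(back.B0, canon.B0, atol=1e-6)
        np.testing.assert_allclose(back.tau0, 1.0, atol=1e-12)

    def test_rank_deficient_column_rejected(self, small_fit):
        bad = small_fit.model.copy()
        bad.V0k = [V * 0.0 for V in bad.V0k]
        with pytest.raises(SIFAError, match="rank-deficient"):
            apply_identifiability(bad)

    def test_validator_flags_wrong_order(self, small_sim):
        cfg = SimulationConfig(n=100, p=(15, 12), r0=2, r=(0, 0), seed=3,
                               snr=3.0)
        _, truth = simulate_sifa_dataset(cfg)
        m = truth.model
        m.V0k = [V[:, ::-1].copy() for V in m.V0k]  # break decreasing order
        with pytest.raises(SIFAError, match="order"):
            validate_identifiability(m)


class TestRecovery:
    def test_joint_subspace_and_coefficients_near_oracle(self):
        """At the study's reduced shape the fit tracks the information
        limit: subspace error modest, coefficient error close to the
        oracle regression of the *true* scores on the covariates."""
        from simfa.inference import align_factors, apply_alignment

        angles, fit_rmse, oracle_rmse = [], [], []
        for seed in range(20):
            cfg = SimulationConfig(n=150, p=(40, 20, 20, 60), r0=2,
                                   r=(1, 1, 1, 1), seed=seed, snr=2.0)
            ds, truth = simulate_sifa_dataset(cfg)
            fit = _quiet_fit(ds, SIFARanks(2, (1, 1, 1, 1)), seed=seed)
            Vt, Vf = np.vstack(truth.model.V0k), np.vstack(fit.model.V0k)
            Qt, _ = np.linalg.qr(Vt)
            Qf, _ = np.linalg.qr(Vf)
            s = np.linalg.svd(Qt.T @ Qf, compute_uv=False)
            angles.append(np.degrees(np.arccos(np.clip(s, 0, 1))).max())
            al = align_factors(truth.model, fit.model)
            aligned = apply_alignment(fit.model, al)
            grp = [i for i, c in enumerate(truth.covariates.column_names)
                   if c.startswith("group_")]
            fit_rmse.append(np.sqrt(np.mean(
                (aligned.B0[grp] - truth.model.B0[grp]) ** 2)))
            Bhat, *_ = np.linalg.lstsq(truth.covariates.Y, truth.U0,
                                       rcond=None)
            for j in range(Bhat.shape[1]):  # oracle knows only up to sign
                if np.sum((Bhat[grp, j] - truth.model.B0[grp, j]) ** 2) > \
                   np.sum((Bhat[grp, j] + truth.model.B0[grp, j]) ** 2):
                    Bhat[:, j] = -Bhat[:, j]
            oracle_rmse.append(np.sqrt(np.mean(
                (Bhat[grp] - truth.model.B0[grp]) ** 2)))
        assert np.median(angles) < 8.0
        assert np.median(fit_rmse) < 1.6 * np.median(oracle_rmse)


class TestRankSelection:
    def test_leave_one_out_boundary_runs(self):
        cfg = SimulationConfig(n=24, p=(8, 6), r0=1, r=(0, 0), seed=0,
                               snr=4.0)
        ds, _ = simulate_sifa_dataset(cfg)
        best, table = select_ranks_lcv(
            ds, r0_grid=(0, 1), rk_grid=(0,), n_folds=ds.n_subjects, seed=0,
            em_kwargs={"max_iter": 50},
        )
        assert best.r0 in (0, 1)
        assert len(table) >= 1

    def test_inadmissible_candidates_skipped(self):
        cfg = SimulationConfig(n=30, p=(6, 5), r0=1, r=(1, 1), seed=1,
                               snr=4.0)
        ds, _ = simulate_sifa_dataset(cfg)
        best, table = select_ranks_lcv(
            ds, r0_grid=(0, 1, 8), rk_grid=(0, 1), n_folds=3, seed=0,
            em_kwargs={"max_iter": 50},
        )
        assert 8 not in table["r0"].values

    def test_greedy_search_used_for_large_grids(self):
        cfg = SimulationConfig(n=60, p=(10, 8), r0=1, r=(1, 1), seed=2,
                               snr=4.0)
        ds, _ = simulate_sifa_dataset(cfg)
        best, table = select_ranks_lcv(
            ds, r0_grid=(0, 1, 2), rk_grid=(0, 1, 2), n_folds=3, seed=0,
            max_grid=5, em_kwargs={"max_iter": 50},
        )
        # greedy visits far fewer combinations than the 3*3*3 full grid
        assert len(table) < 27
        assert best.r0 >= 0


class TestSparsify:
    def test_zero_penalty_is_identity(self, small_sim, small_fit):
        _, ds, _ = small_sim
        out = sparsify_loadings(small_fit, ds, penalty=0.0)
        for a, b in zip(out.model.V0k + out.model.Vk,
                        small_fit.model.V0k + small_fit.model.Vk):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_huge_penalty_kills_all_loadings_with_warning(self, small_sim,
                                                          small_fit):
        _, ds, _ = small_sim
        lam = 10.0 * max(
            np.max(np.abs(np.hstack([small_fit.U0_hat] + small_fit.Uk_hat).T
                          @ blk.values))
            for blk in ds.blocks
        )
        with pytest.warns(RuntimeWarning, match="zeroed factor"):
            out = sparsify_loadings(small_fit, ds, penalty=lam)
        for V in out.model.V0k + out.model.Vk:
            np.testing.assert_array_equal(V, 0.0)

    def test_soft_threshold_closed_form_with_orthonormal_scores(self):
        """With a single factor the lasso solution per feature is the
        soft-thresholded least-squares coefficient."""
        rng = np.random.default_rng(5)
        n, p = 80, 6
        u = rng.standard_normal((n, 1))
        V = rng.standard_normal((p, 1))
        X = u @ V.T + 0.1 * rng.standard_normal((n, p))
        ds = _single_block_ds(X)
        fit = _quiet_fit(ds, SIFARanks(0, (1,)), tol=1e-10, max_iter=2000)
        lam = 0.4 * float(np.max(np.abs(fit.Uk_hat[0].T @ X)))
        out = sparsify_loadings(fit, ds, penalty=lam)
        uh = fit.Uk_hat[0][:, 0]
        denom = uh @ uh + n * fit.posterior_cov[0, 0]
        c = X.T @ uh
        expected = np.sign(c) * np.maximum(np.abs(c) - lam, 0.0) / denom
        np.testing.assert_allclose(out.model.Vk[0][:, 0], expected, atol=1e-8)

    def test_support_recovery_on_sparse_truth(self):
        from simfa.inference import align_factors, apply_alignment

        f1s = []
        for seed in range(10):
            cfg = SimulationConfig(n=150, p=(30, 24), r0=1, r=(1, 1),
                                   seed=seed, snr=4.0, loading_sparsity=0.6)
            ds, truth = simulate_sifa_dataset(cfg)
            fit = _quiet_fit(ds, SIFARanks(1, (1, 1)), seed=seed)
            al = align_factors(truth.model, fit.model)
            sp = sparsify_loadings(fit, ds, penalty="cv", seed=seed)
            spal = apply_alignment(sp.model, al)
            tp = fp = fn = 0
            for Vt, Vf in zip(truth.model.V0k + truth.model.Vk,
                              spal.V0k + spal.Vk):
                st, sf = Vt != 0, Vf != 0
                tp += (st & sf).sum()
                fp += (~st & sf).sum()
                fn += (st & ~sf).sum()
            f1s.append(2 * tp / (2 * tp + fp + fn))
        assert np.median(f1s) >= 0.7


class TestPosteriorScores:
    def test_training_subjects_reproduce_stored_scores(self, small_sim,
                                                       small_fit):
        _, ds, _ = small_sim
        U0, Uk = posterior_scores(small_fit.model, ds)
        np.testing.assert_allclose(U0, small_fit.U0_hat, atol=1e-8)
        for a, b in zip(Uk, small_fit.Uk_hat):
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_zero_noise_limit_is_least_squares_projection(self):
        rng = np.random.default_rng(8)
        n, p, r = 50, 10, 2
        V = np.linalg.qr(rng.standard_normal((p, r)))[0] * [3.0, 2.0]
        U = rng.standard_normal((n, r))
        X = U @ V.T
        ds = _single_block_ds(X)
        model = SIFAModel(
            B0=np.empty((0, 0)), Bk=[np.empty((0, r))],
            V0k=[np.empty((p, 0))], Vk=[V],
            tau0=np.empty(0), tauk=[np.ones(r)], sigma2=np.array([1e-10]),
        )
        _, Uk = posterior_scores(model, ds)
        lsq, *_ = np.linalg.lstsq(V, X.T, rcond=None)
        np.testing.assert_allclose(Uk[0], lsq.T, atol=1e-4)

    def test_infinite_noise_limit_shrinks_to_prior_mean(self, small_sim):
        _, ds, _ = small_sim
        cfg = SimulationConfig(n=120, p=(15, 12), r0=1, r=(1, 1), seed=11,
                               snr=3.0)
        _, truth = simulate_sifa_dataset(cfg)
        m = truth.model.copy()
        m.sigma2 = np.array([1e12, 1e12])
        U0, _ = posterior_scores(m, ds)
        prior = ds.covariates.Y @ m.B0
        np.testing.assert_allclose(U0, prior, atol=1e-4)

    def test_dimension_mismatch_rejected(self, small_fit):
        rng = np.random.default_rng(0)
        ds_bad = _single_block_ds(rng.standard_normal((5, 7)))
        with pytest.raises(SIFAError):
            posterior_scores(small_fit.model, ds_bad)


class TestVarianceExplained:
    @staticmethod
    def _truth_fit(cfg):
        ds, truth = simulate_sifa_dataset(cfg)
        fit = SIFAFit(
            model=truth.model, U0_hat=truth.U0, Uk_hat=truth.Uk,
            loglik_trace=np.array([0.0]), converged=True, n_iter=0,
        )
        return ds, truth, fit

    def test_noiseless_data_fully_explained(self):
        cfg = SimulationConfig(n=80, p=(12, 10), r0=1, r=(1, 1), seed=4,
                               resid_sd=0.0, snr=2.0)
        ds, truth, fit = self._truth_fit(cfg)
        # score the raw (pre-canonicalization) truth: reconstruct exactly
        raw = truth.model
        tab = variance_explained(
            SIFAFit(model=raw, U0_hat=truth.U0, Uk_hat=truth.Uk,
                    loglik_trace=np.array([0.0]), converged=True, n_iter=0),
            ds,
        )
        np.testing.assert_allclose(tab["all_latent_pct"], 100.0, atol=1e-6)

    def test_disjoint_shares_below_union(self):
        cfg = SimulationConfig(n=80, p=(12, 10), r0=1, r=(1, 1), seed=4,
                               snr=2.0)
        ds, _, fit = self._truth_fit(cfg)
        tab = variance_explained(fit, ds)
        assert (tab["common_pct"] <= tab["all_latent_pct"] + 1e-9).all()
        assert (tab["individual_pct"] <= tab["all_latent_pct"] + 1e-9).all()

    def test_matches_bruteforce_reconstruction(self, small_sim, small_fit):
        _, ds, _ = small_sim
        tab = variance_explained(small_fit, ds)
        X0 = ds.blocks[0].values
        J = small_fit.U0_hat @ small_fit.model.V0k[0].T
        expected = 100.0 * (J**2).sum() / (X0**2).sum()
        assert tab["common_pct"].iloc[0] == pytest.approx(expected, rel=1e-12)
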