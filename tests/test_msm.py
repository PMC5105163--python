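import numpy as np
import pytest
from scipy.optimize import minimize

from msmex import msm, synth
from msmex.constants import R_KJ_PER_MOL_K


def oracle_reversible_mle(C):
    """Independent numerically-constrained maximizer of the reversible
    likelihood: log-parameterized symmetric edge weights, quasi-Newton."""
    C = np.asarray(C, float)
    n = C.shape[0]
    iu = np.triu_indices(n)
    mask = (C + C.T)[iu] > 0
    rows, cols = iu[0][mask], iu[1][mask]

    def unpack(logx):
        X = np.zeros((n, n))
        X[rows, cols] = np.exp(logx)
        X[cols, rows] = X[rows, cols]
        return X

    def negll(logx):
        X = unpack(logx)
        T = X / X.sum(1)[:, None]
        return -np.where(C > 0, C * np.log(np.where(T > 0, T, 1.0)), 0.0).sum()

    x0 = np.log(((C + C.T) / 2)[rows, cols] + 0.1)
    res = minimize(negll, x0, method="L-BFGS-B",
                   options=dict(maxiter=20000, ftol=1e-17, gtol=1e-14))
    X = unpack(res.x)
    return X / X.sum(1)[:, None], -res.fun


def detailed_balance_residual(model):
    flux = model.stationary[:, None] * model.transition_matrix
    return np.abs(flux - flux.T).max()


class TestKmeansDiscretize:
    def test_separated_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 0.5, (2000, 2))
        b = rng.normal([10, 10], 0.5, (2000, 2))
        disc = msm.kmeans_discretize({"c": [np.vstack([a, b])]}, k=2, seed=0)
        centers = disc.centers[np.argsort(disc.centers[:, 0])]
        assert np.linalg.norm(centers[0] - [0, 0]) < 0.05
        assert np.linalg.norm(centers[1] - [10, 10]) < 0.05

    def test_k1_is_global_mean(self):
        x = np.random.default_rng(1).normal(3.0, 1.0, (500, 2))
        disc = msm.kmeans_discretize({"c": [x]}, k=1, seed=0)
        np.testing.assert_allclose(disc.centers[0], x.mean(axis=0), atol=1e-8)

    def test_seed_reproducible(self):
        x = np.random.default_rng(2).normal(0, 1, (1000, 3))
        d1 = msm.kmeans_discretize({"c": [x]}, k=5, seed=3)
        d2 = msm.kmeans_discretize({"c": [x]}, k=5, seed=3)
        np.testing.assert_array_equal(d1.dtrajs["c"][0], d2.dtrajs["c"][0])

    def test_shared_centers_across_conditions(self):
        rng = np.random.default_rng(3)
        d = msm.kmeans_discretize(
            {"a": [rng.normal(0, 1, (500, 2))],
             "b": [rng.normal(0, 1, (500, 2))]}, k=4, seed=0)
        assert set(d.dtrajs) == {"a", "b"}
        assert d.centers.shape == (4, 2)


class TestCountTransitions:
    def test_enumerated_examples(self):
        C = msm.count_transitions([np.array([0, 0, 1, 1, 2])], 3, 1)
        np.testing.assert_array_equal(C, [[1, 1, 0], [0, 1, 1], [0, 0, 0]])
        C2 = msm.count_transitions([np.array([0, 1, 0, 1])], 2, 2)
        np.testing.assert_array_equal(C2, [[1, 0], [0, 1]])

    def test_no_cross_boundary_pairs(self):
        split = msm.count_transitions([np.array([0, 0]), np.array([1, 1])], 2, 1)
        cat = msm.count_transitions([np.array([0, 0, 1, 1])], 2, 1)
        assert split[0, 1] == 0
        assert cat[0, 1] == 1

    def test_all_short_trajectories_raise(self):
        with pytest.raises(ValueError, match="lag"):
            msm.count_transitions([np.array([0, 1])], 2, 5)


class TestLargestConnectedSet:
    def test_fully_connected(self):
        assert set(msm.largest_connected_set(np.array([[1, 1], [1, 1]]))) == {0, 1}

    def test_count_tiebreak(self):
        lcs = msm.largest_connected_set(np.array([[5.0, 0.0], [0.0, 3.0]]))
        np.testing.assert_array_equal(lcs, [0])

    def test_directed_chain_gives_singletons(self):
        C = np.array([[0, 2, 0], [0, 0, 7], [0, 0, 0.0]])
        # each state is its own strong component; the largest by counts wins
        lcs = msm.largest_connected_set(C)
        assert len(lcs) == 1


class TestReversibleEstimator:
    def test_symmetric_counts(self):
        m = msm.estimate_reversible_msm(np.array([[8.0, 2.0], [2.0, 8.0]]))
        np.testing.assert_allclose(m.transition_matrix,
                                   [[0.8, 0.2], [0.2, 0.8]], atol=1e-12)
        np.testing.assert_allclose(m.stationary, [0.5, 0.5], atol=1e-12)

    def test_two_state_closed_form(self):
        # for 2 states the reversible MLE is the row-normalized counts
        m = msm.estimate_reversible_msm(np.array([[0.0, 2.0], [3.0, 5.0]]))
        np.testing.assert_allclose(m.transition_matrix,
                                   [[0.0, 1.0], [0.375, 0.625]], atol=1e-10)
        np.testing.assert_allclose(m.stationary, [3 / 11, 8 / 11], atol=1e-10)
        np.testing.assert_allclose(m.stationary @ m.transition_matrix,
                                   m.stationary, atol=1e-10)

    def test_matches_independent_maximizer(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(3, 6))
            C = rng.integers(1, 60, size=(n, n)).astype(float)
            m = msm.estimate_reversible_msm(C)
            T_opt, ll_opt = oracle_reversible_mle(C)
            assert np.abs(m.transition_matrix - T_opt).max() < 1e-6
            assert detailed_balance_residual(m) < 1e-10

    def test_rows_sum_to_one(self):
        C = np.random.default_rng(5).integers(1, 20, (4, 4)).astype(float)
        m = msm.estimate_reversible_msm(C)
        np.testing.assert_allclose(m.transition_matrix.sum(1), 1.0, atol=1e-12)


class TestImpliedTimescales:
    def test_closed_form_from_eigenvalues(self):
        # reversible T with spectrum (1, 0.9, 0.5)
        pi = np.ones(3) / 3
        Q = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))[0]
        # build a symmetric stochastic-like matrix with known spectrum
        lam = np.diag([1.0, 0.9, 0.5])
        u = np.ones(3) / np.sqrt(3)
        B = np.eye(3) - np.outer(u, u)
        V = np.linalg.qr(B @ np.random.default_rng(1).normal(size=(3, 3)))[0][:, :2]
        S = np.outer(u, u) + V @ np.diag([0.9, 0.5]) @ V.T
        T = S  # symmetric doubly-stochastic, pi uniform
        model = msm.MarkovModel(1, 1.0, np.ones((3, 3)), np.arange(3), T, pi)
        ts = model.timescales_frames(2)
        assert ts[0] == pytest.approx(-1 / np.log(0.9), abs=1e-6)
        assert ts[1] == pytest.approx(-1 / np.log(0.5), abs=1e-6)

    def test_recovers_latent_relaxation_time(self):
        spec = synth.chain_from_populations(np.array([0.7, 0.25, 0.05]), 50.0)
        rng = np.random.default_rng(2)
        dtrajs = [synth.sample_latent_path(spec, 50_000, seed=int(s))
                  for s in rng.integers(0, 2**31 - 1, size=10)]
        its = msm.implied_timescales(dtrajs, 3, [1, 5, 10])
        truth = spec.relaxation_timescales_frames()[0]
        for lag in (1, 5, 10):
            assert abs(its[lag][0] - truth) / truth < 0.15

    def test_unit_eigenvalue_reports_inf(self):
        T = np.eye(2) * 0.999 + 0.001 * np.array([[0, 1], [1, 0.0]])
        pi = np.array([0.5, 0.5])
        model = msm.MarkovModel(1, 1.0, np.ones((2, 2)), np.arange(2), T, pi)
        # eigenvalue 0.998 -> finite; a strictly unit eigenvalue would be inf
        assert np.isfinite(model.timescales_frames(1)[0])


class TestPCCA:
    def _block_chain(self, eps):
        T = np.array([
            [0.5 - eps, 0.5, eps, 0.0],
            [0.5, 0.5 - eps, 0.0, eps],
            [eps, 0.0, 0.5 - eps, 0.5],
            [0.0, eps, 0.5, 0.5 - eps],
        ])
        return T / T.sum(1)[:, None]

    def test_two_uncoupled_blocks(self):
        T = self._block_chain(1e-4)
        C = T * 10000
        model = msm.estimate_reversible_msm(C)
        decomp = msm.pcca(model, 2)
        crisp = decomp.crisp[model.active_set]
        assert crisp[0] == crisp[1]
        assert crisp[2] == crisp[3]
        assert crisp[0] != crisp[2]
        np.testing.assert_allclose(decomp.memberships.sum(1), 1.0, atol=1e-9)

    def test_three_blocks_slow_coupling(self):
        rng = np.random.default_rng(0)
        n_per = 3
        blocks = []
        intra = 0.2
        inter = 0.002
        n = 3 * n_per
        T = np.full((n, n), 0.0)
        for b in range(3):
            s = slice(b * n_per, (b + 1) * n_per)
            T[s, s] = intra
        T += inter
        np.fill_diagonal(T, 0)
        T = T + np.diag(1 - T.sum(1))
        C = T * 100000
        model = msm.estimate_reversible_msm(C)
        decomp = msm.pcca(model, 3)
        crisp = decomp.crisp[model.active_set]
        for b in range(3):
            members = crisp[b * n_per:(b + 1) * n_per]
            assert len(set(members)) == 1
        diag_membership = np.array([
            decomp.memberships[i, crisp[i]] for i in range(n)])
        assert np.all(diag_membership >= 0.95)

    def test_coarse_populations_sum_to_one(self):
        T = self._block_chain(0.01)
        model = msm.estimate_reversible_msm(T * 5000)
        decomp = msm.pcca(model, 2)
        assert decomp.populations.sum() == pytest.approx(1.0, abs=1e-12)


class TestThermodynamics:
    def test_equal_populations_zero(self):
        np.testing.assert_allclose(msm.free_energies([0.5, 0.5], 310.0), 0.0)

    def test_rare_state_free_energy(self):
        dg = msm.free_energies([0.776, 0.208, 0.016], 310.0)
        assert dg[0] == 0.0
        assert dg[2] == pytest.approx(
            R_KJ_PER_MOL_K * 310.0 * np.log(0.776 / 0.016), abs=1e-9)
        assert dg[2] == pytest.approx(10.0, abs=0.02)

    def test_e_fold_population_ratio_is_rt(self):
        dg = msm.free_energies([1.0, np.exp(-1.0)] / (1 + np.exp(-1.0)), 310.0)
        assert dg[1] == pytest.approx(R_KJ_PER_MOL_K * 310.0, abs=1e-9)
        assert dg[1] == pytest.approx(2.5775, abs=1e-3)

    def test_monotone_in_population(self):
        pops = np.array([0.5, 0.3, 0.15, 0.05])
        dg = msm.free_energies(pops, 310.0)
        assert np.all(np.diff(dg) > 0)


class TestCoarseRates:
    def test_two_state_mfpt(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = synth.stationary_distribution(T)
        model = msm.MarkovModel(1, 1.0, T * 100, np.arange(2), T, pi)
        assert msm.mfpt_frames(model, np.array([0]), np.array([1])) == \
            pytest.approx(10.0, rel=1e-12)
        decomp = msm.MetastableDecomposition(
            n_meta=2, memberships=np.eye(2), crisp=np.array([0, 1]),
            populations=pi, active_set=np.arange(2))
        rates = msm.coarse_rates(model, decomp, frame_interval_ns=1.0)
        assert rates[0, 1] == pytest.approx(0.1 * 1000.0, rel=1e-12)  # 1/us

    def test_detailed_balance_of_rates(self):
        # two metastable blocks with fast intra- and slow inter-block mixing:
        # in this timescale-separated regime the 1/MFPT rates obey flux
        # balance Pi_a rate(a->b) = Pi_b rate(b->a)
        intra, inter = 0.3, 0.002
        T = np.array([
            [0.0, intra, inter, inter * 0.5],
            [intra, 0.0, inter * 0.5, inter],
            [3 * inter, 1.5 * inter, 0.0, intra],
            [1.5 * inter, 3 * inter, intra, 0.0],
        ])
        T = T + np.diag(1 - T.sum(1))
        pi = synth.stationary_distribution(T)
        model = msm.MarkovModel(1, 1.0, T * 1e6, np.arange(4), T, pi)
        crisp = np.array([0, 0, 1, 1])
        pops = np.array([pi[:2].sum(), pi[2:].sum()])
        decomp = msm.MetastableDecomposition(
            n_meta=2, memberships=np.eye(2)[crisp], crisp=crisp,
            populations=pops, active_set=np.arange(4))
        rates = msm.coarse_rates(model, decomp)
        fa = pops[0] * rates[0, 1]
        fb = pops[1] * rates[1, 0]
        assert fa == pytest.approx(fb, rel=0.1)


class TestBootstrap:
    def _decomp_for(self, model, n_meta):
        return msm.pcca(model, n_meta)

    def test_degenerate_resampling_zero_width(self):
        d = np.array([0, 0, 1, 1, 0, 1, 0, 0, 1, 1] * 30)
        dtrajs = [d.copy() for _ in range(10)]
        C = msm.count_transitions(dtrajs, 2, 1)
        model = msm.estimate_reversible_msm(C)
        decomp = msm.MetastableDecomposition(
            n_meta=2, memberships=np.eye(2), crisp=np.array([0, 1]),
            populations=model.stationary, active_set=np.arange(2))
        boot = msm.bootstrap_msm(dtrajs, 2, 1, decomp, n_boot=20, seed=0,
                                 compute_rates=False)
        lo, hi = boot.percentile_band(boot.population_samples)
        np.testing.assert_allclose(lo, hi, atol=1e-12)

    def test_interval_reproducible_for_seed(self):
        rng = np.random.default_rng(1)
        spec = synth.chain_from_populations(np.array([0.8, 0.2]), 10.0)
        dtrajs = [synth.sample_latent_path(spec, 2000, seed=int(s))
                  for s in rng.integers(0, 2**31 - 1, 8)]
        C = msm.count_transitions(dtrajs, 2, 1)
        model = msm.estimate_reversible_msm(C)
        decomp = msm.MetastableDecomposition(
            n_meta=2, memberships=np.eye(2), crisp=np.array([0, 1]),
            populations=model.stationary, active_set=np.arange(2))
        b1 = msm.bootstrap_msm(dtrajs, 2, 1, decomp, n_boot=25, seed=9,
                               compute_rates=False)
        b2 = msm.bootstrap_msm(dtrajs, 2, 1, decomp, n_boot=25, seed=9,
                               compute_rates=False)
        np.testing.assert_array_equal(b1.population_samples,
                                      b2.population_samples)

    def test_coverage_of_true_population(self):
        # 1-sigma interval should cover truth in roughly 68% of repeats;
        # a cheap proxy: truth within 3 sigma for a single realization
        spec = synth.chain_from_populations(np.array([0.7, 0.3]), 10.0)
        rng = np.random.default_rng(4)
        dtrajs = [synth.sample_latent_path(spec, 3000, seed=int(s))
                  for s in rng.integers(0, 2**31 - 1, 20)]
        C = msm.count_transitions(dtrajs, 2, 1)
        model = msm.estimate_reversible_msm(C)
        decomp = msm.MetastableDecomposition(
            n_meta=2, memberships=np.eye(2), crisp=np.array([0, 1]),
            populations=model.stationary, active_set=np.arange(2))
        boot = msm.bootstrap_msm(dtrajs, 2, 1, decomp, n_boot=50, seed=0,
                                 compute_rates=False)
        sd = boot.population_samples.std(axis=0)
        assert abs(decomp.populations[1] - 0.3) < 3 * max(sd[1], 1e-3)


class TestCompareConditions:
    def _decomp(self, pops, crisp):
        n = len(pops)
        return msm.MetastableDecomposition(
            n_meta=n, memberships=np.eye(n), crisp=np.asarray(crisp),
            populations=np.asarray(pops, float), active_set=np.arange(len(crisp)))

    def test_fold_28_gives_ddg_9(self):
        p_rare = 0.016
        a = self._decomp([1.0 - p_rare / 28, p_rare / 28], [0, 0, 1, 1])
        b = self._decomp([1.0 - p_rare, p_rare], [0, 0, 1, 1])
        res = msm.compare_conditions(a, b, 310.0)
        rare = [r for r in res if r["state_A"] == 1][0]
        assert rare["fold"] == pytest.approx(28.0, rel=1e-9)
        assert rare["ddg_kj"] == pytest.approx(8.59, abs=0.005)
        assert round(rare["ddg_kj"]) == 9

    def test_fold_200_gives_ddg_14(self):
        ddg = msm.delta_delta_g(200.0, 310.0)
        assert ddg == pytest.approx(13.66, abs=0.005)
        assert round(ddg) == 14

    def test_identical_conditions_zero(self):
        a = self._decomp([0.8, 0.2], [0, 0, 1, 1])
        b = self._decomp([0.8, 0.2], [0, 0, 1, 1])
        res = msm.compare_conditions(a, b, 310.0)
        for row in res:
            assert row["matched"]
            assert row["fold"] == pytest.approx(1.0)
            assert row["ddg_kj"] == pytest.approx(0.0, abs=1e-12)

    def test_unmatched_state_flagged(self):
        a = self._decomp([0.8, 0.2], [0, 0, 1, 1])
        b = self._decomp([0.8, 0.2], [1, 1, 0, 0])
        res = msm.compare_conditions(a, b, 310.0)
        # states map to the swapped partner, overlap 0 with the same index
        assert all(r["matched"] for r in res)
        assert res[0]["state_B"] == 1


class TestSeedConformations:
    def _model(self, n_states, seed=0):
        rng = np.random.default_rng(seed)
        C = rng.integers(1, 30, (n_states, n_states)).astype(float)
        return msm.estimate_reversible_msm(C)

    def test_uniform_split_across_clusters(self):
        model = self._model(12)
        rng = np.random.default_rng(1)
        dtrajs = [rng.integers(0, 12, 500) for _ in range(4)]
        picks = msm.sample_seed_conformations(model, dtrajs, n_out=12,
                                              k_clusters=6, seed=0)
        assert len(picks) == 12

    def test_default_k_is_sqrt_of_active_set(self):
        model = self._model(36, seed=2)
        assert model.n_active == 36
        rng = np.random.default_rng(3)
        dtrajs = [rng.integers(0, 36, 2000) for _ in range(3)]
        picks = msm.sample_seed_conformations(model, dtrajs, n_out=6, seed=0)
        assert len(picks) == 6  # k = round(sqrt(36)) = 6, one per cluster

    def test_reproducible(self):
        model = self._model(10, seed=4)
        rng = np.random.default_rng(5)
        dtrajs = [rng.integers(0, 10, 500) for _ in range(2)]
        a = msm.sample_seed_conformations(model, dtrajs, n_out=8, seed=11)
        b = msm.sample_seed_conformations(model, dtrajs, n_out=8, seed=11)
        assert a == b
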