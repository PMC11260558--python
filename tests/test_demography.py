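import numpy as np
import pytest
from scipy import stats

from sanderpop import demography as dm
from sanderpop.demography import (
    DemographicFit,
    JointSFS,
    block_bootstrap,
    effective_length,
    expected_joint_sfs,
    fit_model,
    fold_sfs,
    joint_sfs,
    lrt,
    project_sfs,
    read_sfs,
    scale_to_real,
    write_sfs,
)

from conftest import make_gm


class TestJointSfs:
    def test_single_site_lands_in_right_cell(self):
        # 4 diploids (8 chromosomes) per pop; alt counts (1, 0)
        gt = np.zeros((8, 1), dtype=np.int8)
        gt[0, 0] = 1
        gm = make_gm(gt)
        pops = np.array(["p1"] * 4 + ["p2"] * 4)
        sfs = joint_sfs(gm, pops, "p1", "p2", fold=False)
        assert sfs.data[1, 0] == 1
        assert sfs.total() == 1

    def test_folding_merges_complementary_cells(self):
        # n1 = n2 = 4; cells (3, 4) and (1, 0) are complements
        d = np.zeros((5, 5))
        d[3, 4] = 2
        d[1, 0] = 3
        folded = fold_sfs(JointSFS(d))
        assert folded.data[1, 0] == 5
        assert folded.mask[3, 4]

    def test_fold_preserves_mass(self):
        rng = np.random.default_rng(1)
        d = rng.poisson(5, size=(7, 9)).astype(float)
        raw = JointSFS(d)
        folded = fold_sfs(raw)
        assert folded.unmasked().sum() == pytest.approx(
            d.sum() - d[0, 0] - d[6, 8], rel=1e-12
        )

    def test_matches_brute_force_tabulation(self):
        rng = np.random.default_rng(2)
        gt = rng.choice([0, 1, 2], size=(10, 100), p=[0.6, 0.3, 0.1]).astype(np.int8)
        gm = make_gm(gt)
        pops = np.array(["p1"] * 5 + ["p2"] * 5)
        sfs = joint_sfs(gm, pops, "p1", "p2", fold=False)
        expected = np.zeros((11, 11))
        for j in range(100):
            expected[gt[:5, j].sum(), gt[5:, j].sum()] += 1
        np.testing.assert_allclose(sfs.data, expected)

    def test_projection_absorbs_missing_data(self):
        gt = np.zeros((6, 2), dtype=np.int8)
        gt[0, 0] = 1
        gt[5, 1] = -1  # missing in p2 -> usable only via projection
        gm = make_gm(gt)
        pops = np.array(["p1"] * 3 + ["p2"] * 3)
        full = joint_sfs(gm, pops, "p1", "p2", fold=False)
        assert full.total() == 1  # site 2 dropped without projection
        proj = joint_sfs(gm, pops, "p1", "p2", fold=False, project=(4, 4))
        assert proj.total() == pytest.approx(2 - proj.data[0, 0] - proj.data[4, 4])


class TestProjection:
    def test_identity_projection(self):
        rng = np.random.default_rng(3)
        sfs = JointSFS(rng.poisson(4, size=(5, 5)).astype(float))
        out = project_sfs(sfs, (4, 4))
        keep = ~sfs.mask
        np.testing.assert_allclose(out.data[keep], sfs.data[keep])

    def test_hypergeometric_by_hand(self):
        # single entry at frequency 2/4 projected to n=2:
        # P(0)=C(2,0)C(2,2)/C(4,2)=1/6, P(1)=4/6, P(2)=1/6
        d = np.zeros((5, 2))
        d[2, 1] = 1.0
        sfs = JointSFS(d, mask=np.zeros((5, 2), dtype=bool))
        out = project_sfs(sfs, (2, 1))
        np.testing.assert_allclose(out.data[:, 1], [1 / 6, 4 / 6, 1 / 6])

    def test_mass_conserved_before_corner_masking(self):
        rng = np.random.default_rng(4)
        d = rng.poisson(10, size=(9, 9)).astype(float)
        sfs = JointSFS(d, mask=np.zeros((9, 9), dtype=bool))
        out = project_sfs(sfs, (4, 4))
        assert out.data.sum() == pytest.approx(d.sum())

    def test_upward_projection_rejected(self):
        sfs = JointSFS(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            project_sfs(sfs, (6, 4))


class TestSerialization:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        sfs = fold_sfs(JointSFS(rng.poisson(3, size=(6, 8)).astype(float)))
        path = tmp_path / "spec.fs"
        write_sfs(sfs, path)
        back = read_sfs(path)
        np.testing.assert_allclose(back.data, sfs.data)
        np.testing.assert_array_equal(back.mask, sfs.mask)
        assert back.folded == sfs.folded


class TestExpectedSfs:
    def test_t_zero_spectrum_has_no_divergence(self):
        E = expected_joint_sfs(
            "split_nomig", dict(nu1=0.5, nu2=0.5, T=0.0), (8, 8),
            grid_diploids=40, fold=False,
        )
        d = E.data
        # expected F_ST of the spectrum ~ 0: compute RP F_ST treating cells
        # as site counts
        num = den = 0.0
        for i in range(9):
            for j in range(9):
                if E.mask[i, j] or d[i, j] == 0:
                    continue
                h1 = i * (8 - i) / (8 * 7)
                h2 = j * (8 - j) / (8 * 7)
                N = (i / 8 - j / 8) ** 2 - h1 / 8 - h2 / 8
                num += d[i, j] * N
                den += d[i, j] * (N + h1 + h2)
        assert num / den == pytest.approx(0.0, abs=0.02)

    def test_swapping_sizes_transposes_spectrum(self):
        a = expected_joint_sfs("split_nomig", dict(nu1=0.3, nu2=0.6, T=0.08),
                               (6, 6), grid_diploids=40, fold=False)
        b = expected_joint_sfs("split_nomig", dict(nu1=0.6, nu2=0.3, T=0.08),
                               (6, 6), grid_diploids=40, fold=False)
        np.testing.assert_allclose(a.data, b.data.T, atol=1e-12)

    def test_equilibrium_marginal_is_theta_over_k(self):
        """At T=0 the combined-sample spectrum follows theta/k."""
        E = expected_joint_sfs("split_nomig", dict(nu1=0.5, nu2=0.5, T=0.0),
                               (10, 10), grid_diploids=60, fold=False)
        comb = np.zeros(21)
        for i in range(11):
            for j in range(11):
                comb[i + j] += E.data[i, j]
        for k in range(2, 10):
            assert comb[k] * k == pytest.approx(1.0, rel=0.02)

    def test_migration_zero_equals_isolation_model(self):
        En = expected_joint_sfs("split_nomig", dict(nu1=0.5, nu2=0.5, T=0.1),
                                (8, 8), grid_diploids=30, fold=False)
        Em = expected_joint_sfs("split_mig",
                                dict(nu1=0.5, nu2=0.5, T=0.1, M12=0, M21=0),
                                (8, 8), grid_diploids=30, fold=False)
        np.testing.assert_allclose(Em.data, En.data, atol=1e-10)

    def test_migration_reduces_divergence(self):
        def spectrum_fst(E):
            num = den = 0.0
            n = E.n1
            for i in range(n + 1):
                for j in range(n + 1):
                    if E.mask[i, j]:
                        continue
                    h1 = i * (n - i) / (n * (n - 1))
                    h2 = j * (n - j) / (n * (n - 1))
                    N = (i / n - j / n) ** 2 - h1 / n - h2 / n
                    num += E.data[i, j] * N
                    den += E.data[i, j] * (N + h1 + h2)
            return num / den

        iso = expected_joint_sfs("split_nomig", dict(nu1=0.5, nu2=0.5, T=0.15),
                                 (8, 8), grid_diploids=30, fold=False)
        mig = expected_joint_sfs("split_mig",
                                 dict(nu1=0.5, nu2=0.5, T=0.15, M12=3, M21=3),
                                 (8, 8), grid_diploids=30, fold=False)
        assert spectrum_fst(mig) < spectrum_fst(iso)

    def test_sample_size_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            expected_joint_sfs("split_nomig", dict(nu1=0.1, nu2=0.5, T=0.1),
                               (30, 10), grid_diploids=20)


class TestFitting:
    def test_profiled_theta_is_optimal(self):
        truth = dict(nu1=0.5, nu2=0.4, T=0.08)
        E = expected_joint_sfs("split_nomig", truth, (10, 10), grid_diploids=40)
        obs = JointSFS(E.data * 500, folded=True, mask=E.mask.copy())
        ll, theta = dm._poisson_loglik(obs, E)
        for bump in (0.99, 1.01):
            m = np.clip(E.data[~obs.mask], 1e-300, None)
            o = obs.unmasked()
            mu = theta * bump * m
            ll_bump = np.sum(o * np.log(mu) - mu)
            assert ll_bump < ll

    def test_empty_observation_rejected(self):
        obs = JointSFS(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="empty"):
            fit_model(obs, "split_nomig", n_restarts=1)

    def test_self_consistency_quick(self):
        """Fitting the model to its own expected spectrum recovers the
        generating parameters (scaled-down version of the full check)."""
        truth = dict(nu1=0.5, nu2=0.3, T=0.1)
        E = expected_joint_sfs("split_nomig", truth, (10, 10), grid_diploids=40)
        obs = JointSFS(E.data * 1000, folded=True, mask=E.mask.copy())
        fit = fit_model(obs, "split_nomig", n_restarts=2, seed=1,
                        grid_diploids=40)
        for k, v in truth.items():
            assert fit.params[k] == pytest.approx(v, rel=0.02)


class TestLrt:
    def _fit(self, ll, model="split_nomig"):
        return DemographicFit(model=model, params={}, theta=1.0, loglik=ll,
                              converged=True, n_restarts=1)

    def test_equal_logliks_not_supported(self):
        D, p, sup = lrt(self._fit(-100.0), self._fit(-100.0))
        assert D == 0
        assert p == pytest.approx(1.0)
        assert not sup

    def test_chi_square_tail_value(self):
        # D = 10, df = 2 -> p = exp(-5) ~ 0.0067
        D, p, sup = lrt(self._fit(-105.0), self._fit(-100.0), df=2)
        assert D == pytest.approx(10.0)
        assert p == pytest.approx(np.exp(-5), rel=1e-6)
        assert sup

    def test_negative_statistic_flags_optimizer_failure(self):
        with pytest.raises(RuntimeError, match="local optimum"):
            lrt(self._fit(-100.0), self._fit(-102.0))

    def test_sub_tolerance_negative_clamped_to_zero(self):
        D, p, sup = lrt(self._fit(-100.0), self._fit(-100.1))
        assert D == 0 and p == pytest.approx(1.0) and not sup


class TestScaling:
    def test_effective_length_arithmetic(self):
        assert effective_length(1000, 100, 25) == pytest.approx(250)
        assert effective_length(1000, 100, 100) == pytest.approx(1000)
        with pytest.raises(ValueError):
            effective_length(1000, 0, 0)
        with pytest.raises(ValueError):
            effective_length(1000, 10, 20)

    def test_effective_length_from_filtered_genotypes(self):
        from sanderpop.vcfio import filter_loci

        rng = np.random.default_rng(8)
        gt = rng.choice([-1, 0, 1, 2], size=(30, 200), p=[0.2, 0.5, 0.2, 0.1])
        gm = make_gm(gt)
        post = filter_loci(gm, maf_min=0.05, max_locus_missing=0.3)
        L = effective_length(10_000, gm.n_loci, post.n_loci)
        assert L == pytest.approx(10_000 * post.n_loci / 200)

    def test_nref_identity(self):
        fit = DemographicFit(model="split_nomig", params=dict(T=0.1),
                             theta=4.0, loglik=0.0, converged=True, n_restarts=1)
        s = scale_to_real(fit, mu=1e-8, L=1e8)["mu"]
        assert s.N_ref == pytest.approx(1.0)

    def test_generation_to_year_conversion(self):
        # 17.5 generations at 3 years/generation = 52.5 years
        fit = DemographicFit(model="split_nomig", params=dict(T=0.5),
                             theta=1.0, loglik=0.0, converged=True, n_restarts=1)
        mu, L = 2.5e-9, 1e7
        s = scale_to_real(fit, mu=mu, L=L, generation_time=3.0)["mu"]
        n_ref = 1.0 / (4 * mu * L)
        assert s.T_generations == pytest.approx(0.5 * 2 * n_ref)
        assert s.T_years == pytest.approx(s.T_generations * 3)

    def test_doubling_mu_halves_nref_and_years(self):
        fit = DemographicFit(model="split_nomig", params=dict(T=0.2),
                             theta=2.0, loglik=0.0, converged=True, n_restarts=1)
        a = scale_to_real(fit, mu=1e-8, L=1e6)["mu"]
        b = scale_to_real(fit, mu=2e-8, L=1e6)["mu"]
        assert b.N_ref == pytest.approx(a.N_ref / 2)
        assert b.T_years == pytest.approx(a.T_years / 2)


class TestBlockBootstrap:
    def _gm(self, n_blocks=10, loci_per_block=20):
        rng = np.random.default_rng(9)
        L = n_blocks * loci_per_block
        pos = np.concatenate(
            [b * 1_000_000 + np.sort(rng.choice(999_999, loci_per_block, False)) + 1
             for b in range(n_blocks)]
        )
        gt = rng.choice([0, 1, 2], size=(8, L), p=[0.5, 0.3, 0.2]).astype(np.int8)
        return make_gm(gt, pos=pos)

    def test_block_larger_than_genome_degenerate(self, caplog):
        gm = self._gm(n_blocks=1)
        pops = np.array(["a"] * 4 + ["b"] * 4)
        with caplog.at_level("WARNING"):
            reps = block_bootstrap(gm, pops, "a", "b", block_size=10**9, B=3, seed=1)
        assert "single block" in caplog.text
        for r in reps:
            np.testing.assert_allclose(r.data, reps[0].data)

    def test_replicate_mean_total_matches_original(self):
        gm = self._gm()
        pops = np.array(["a"] * 4 + ["b"] * 4)
        reps = block_bootstrap(gm, pops, "a", "b", B=400, seed=2)
        totals = np.array([r.total() for r in reps])
        original = dm.joint_sfs(gm, pops, "a", "b").total()
        assert totals.mean() == pytest.approx(original, rel=0.05)

    def test_fixed_seed_reproducible(self):
        gm = self._gm(n_blocks=4)
        pops = np.array(["a"] * 4 + ["b"] * 4)
        a = block_bootstrap(gm, pops, "a", "b", B=5, seed=3)
        b = block_bootstrap(gm, pops, "a", "b", B=5, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)
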