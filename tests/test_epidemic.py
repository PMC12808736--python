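import numpy as np
import pytest

from stratmix.epidemic import (
    EpidemicParams,
    NGM,
    attack_rates,
    build_ngm,
    calibrate_beta,
    child_reduced_sigma,
    control_strategy_report,
    eigen_ratio,
    elasticity_contributions,
    simulate_sir,
    standard_partitions,
    type_reproduction,
)
from stratmix.expansion import (
    ExpandedMatrix,
    collapse_dimension,
    homogeneous_expansion,
)
from stratmix.groups import GROUP_KEYS, N_GROUPS, PopulationTable


@pytest.fixture(scope="module")
def uniform_world():
    """All strata identical: contact rate 10 spread proportionally."""
    pop = PopulationTable(np.full(N_GROUPS, 1e5))
    shares = pop.counts / pop.total
    hat = ExpandedMatrix(10.0 * np.tile(shares, (N_GROUPS, 1)), pop)
    return pop, hat


class TestNGM:
    def test_single_type_reproduction_number(self, uniform_world):
        _, hat = uniform_world
        params = EpidemicParams(beta=0.05, gamma=1 / 3)
        K = build_ngm(hat, params)
        # beta * c / gamma with c = 10 contacts/day
        assert K.spectral_radius() == pytest.approx(1.5, rel=1e-12)

    def test_zero_susceptibility_kills_transmission(self, uniform_world):
        _, hat = uniform_world
        K = build_ngm(hat, EpidemicParams(beta=0.05, gamma=1 / 3, sigma=0.0))
        assert K.spectral_radius() == 0.0

    def test_transpose_has_same_spectrum(self, truth):
        params = EpidemicParams(beta=0.03, gamma=1 / 3, sigma=child_reduced_sigma())
        K = build_ngm(truth, params)
        rho_t = float(np.abs(np.linalg.eigvals(K.values.T)).max())
        assert K.spectral_radius() == pytest.approx(rho_t, rel=1e-12)

    def test_two_group_within_between_rates(self):
        """rho = (beta/gamma)(w + b) for two equal groups, by hand."""
        w, b, beta, gamma = 4.0, 1.5, 0.02, 0.25
        K = (beta / gamma) * np.array([[w, b], [b, w]])
        rho = float(np.abs(np.linalg.eigvals(K)).max())
        assert rho == pytest.approx((beta / gamma) * (w + b), rel=1e-12)


class TestCalibration:
    def test_single_group_closed_form(self, uniform_world):
        _, hat = uniform_world
        beta = calibrate_beta(hat, 1.0, 1 / 3, 1.5)
        assert beta == pytest.approx(1.5 / (3 * 10), rel=1e-10)

    def test_doubling_matrix_halves_beta(self, truth):
        beta1 = calibrate_beta(truth, 1.0, 1 / 3, 1.5)
        doubled = ExpandedMatrix(2 * truth.values, truth.population)
        assert calibrate_beta(doubled, 1.0, 1 / 3, 1.5) == pytest.approx(
            beta1 / 2, rel=1e-12
        )

    def test_child_scenario_recalibration_exact(self, truth):
        sigma = child_reduced_sigma(0.5)
        beta = calibrate_beta(truth, sigma, 1 / 3, 1.5)
        K = build_ngm(truth, EpidemicParams(beta, 1 / 3, sigma))
        assert K.spectral_radius() == pytest.approx(1.5, rel=1e-10)


class TestEigenRatio:
    def test_identity(self, truth):
        assert eigen_ratio(truth, truth) == pytest.approx(1.0, rel=1e-12)

    def test_ensemble_members_never_below_homogeneous(self, small_ensemble, hom):
        mats, _ = small_ensemble
        for hat in mats[::20]:
            assert eigen_ratio(hat, hom) >= 1 - 1e-9

    def test_one_dimensional_collapses_bracketed(self, truth, hom):
        """SEP-only and education-only expansions raise the dominant
        eigenvalue above the homogeneous baseline but below the full
        two-dimensional matrix."""
        full = eigen_ratio(truth, hom)
        for collapsed_dim in ("sep", "edu"):
            ratio = eigen_ratio(collapse_dimension(truth, collapsed_dim), hom)
            assert 1 - 1e-9 <= ratio <= full + 1e-9


class TestElasticities:
    def test_symmetric_equal_groups_contribute_equally(self, uniform_world):
        _, hat = uniform_world
        K = build_ngm(hat, EpidemicParams(0.05, 1 / 3))
        _, contrib = elasticity_contributions(K)
        np.testing.assert_allclose(contrib, np.full(N_GROUPS, 1 / N_GROUPS), rtol=1e-9)

    def test_contributions_sum_to_one(self, truth):
        K = build_ngm(truth, EpidemicParams(0.04, 1 / 3, child_reduced_sigma()))
        _, contrib = elasticity_contributions(K)
        assert contrib.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_finite_difference_of_log_rho(self):
        K = np.array([[1.2, 0.3], [0.3, 0.6]])
        e, _ = elasticity_contributions(K)
        h = 1e-6
        for s in range(2):
            for t in range(2):
                Kp, Km = K.copy(), K.copy()
                Kp[s, t] *= 1 + h
                Km[s, t] *= 1 - h
                rp = float(np.abs(np.linalg.eigvals(Kp)).max())
                rm = float(np.abs(np.linalg.eigvals(Km)).max())
                fd = (np.log(rp) - np.log(rm)) / (np.log(1 + h) - np.log(1 - h))
                assert e[s, t] == pytest.approx(fd, abs=1e-5)

    def test_permutation_invariance(self, truth):
        params = EpidemicParams(0.04, 1 / 3)
        K = build_ngm(truth, params)
        _, contrib = elasticity_contributions(K)
        perm = np.random.default_rng(3).permutation(N_GROUPS)
        Kp = NGM(K.values[np.ix_(perm, perm)])
        _, contrib_p = elasticity_contributions(Kp)
        np.testing.assert_allclose(contrib_p, contrib[perm], rtol=1e-8)


class TestSIR:
    def test_subcritical_outbreak_stays_small(self, uniform_world):
        pop, hat = uniform_world
        beta = calibrate_beta(hat, 1.0, 1 / 3, 0.8)
        traj = simulate_sir(hat, EpidemicParams(beta, 1 / 3), initial_infected=1.0)
        final = traj.R[-1].sum()
        assert final < 100 * N_GROUPS  # a few times the seed, not an epidemic

    def test_conservation(self, truth):
        pop = truth.population
        beta = calibrate_beta(truth, 1.0, 1 / 3, 1.5)
        traj = simulate_sir(truth, EpidemicParams(beta, 1 / 3), 1e-6 * pop.counts)
        total = (traj.S + traj.I + traj.R).sum(axis=1)
        assert np.abs(total - pop.total).max() < 1e-6 * pop.total

    def test_homogeneous_final_size_equation(self, uniform_world):
        """Single effective group at R0=1.5: z = 1 - exp(-1.5 z)."""
        pop, hat = uniform_world
        beta = calibrate_beta(hat, 1.0, 1 / 3, 1.5)
        traj = simulate_sir(
            hat, EpidemicParams(beta, 1 / 3), initial_infected=1e-6 * pop.counts
        )
        z_ode = traj.R[-1].sum() / pop.total
        z = 0.5
        for _ in range(200):
            z = 1 - np.exp(-1.5 * z)
        assert z_ode == pytest.approx(z, abs=1e-4)


class TestAttackRates:
    def test_subcritical_zero_branch(self, uniform_world):
        _, hat = uniform_world
        beta = calibrate_beta(hat, 1.0, 1 / 3, 0.8)
        z = attack_rates(hat, EpidemicParams(beta, 1 / 3))
        assert np.abs(z).max() <= 1e-6

    @pytest.mark.parametrize("scenario", ["homogeneous", "child_reduced"])
    def test_fixed_point_matches_ode(self, truth, scenario):
        sigma = 1.0 if scenario == "homogeneous" else child_reduced_sigma()
        beta = calibrate_beta(truth, sigma, 1 / 3, 1.5)
        params = EpidemicParams(beta, 1 / 3, sigma)
        z_fp = attack_rates(truth, params)
        traj = simulate_sir(
            truth, params, initial_infected=1e-7 * truth.population.counts
        )
        z_ode = traj.final_attack_rates()
        assert np.abs(z_fp - z_ode).max() < 1e-4


class TestTypeReproduction:
    def test_all_groups_equals_r0(self, truth):
        beta = calibrate_beta(truth, 1.0, 1 / 3, 1.5)
        K = build_ngm(truth, EpidemicParams(beta, 1 / 3))
        res = type_reproduction(K, GROUP_KEYS, truth.population)
        assert res.t_g == pytest.approx(1.5, rel=1e-9)
        assert res.critical_fraction == pytest.approx(1 / 3, rel=1e-9)
        assert res.overall_effort == pytest.approx(1 / 3, rel=1e-9)

    def test_infeasible_when_rest_self_sustaining(self):
        res = type_reproduction(np.array([[2.0, 1.0], [1.0, 2.0]]), [0])
        assert not res.feasible

    def test_two_group_matrix_formula(self):
        res = type_reproduction(
            np.array([[1.2, 0.3], [0.3, 0.6]]), [0], np.array([100.0, 100.0])
        )
        assert res.feasible
        assert res.t_g == pytest.approx(1.425, abs=1e-9)
        assert res.critical_fraction == pytest.approx(1 - 1 / 1.425, abs=1e-9)

    def test_branching_process_extinction_threshold(self):
        """Immunizing more/less than 1 - 1/T_g of the target group puts a
        multitype Poisson branching process below/above criticality."""
        K = np.array([[1.2, 0.3], [0.3, 0.6]])
        res = type_reproduction(K, [0])
        f_star = res.critical_fraction

        def outbreak_fraction(f, n_chains=300, cap=3000, seed=0):
            rng = np.random.default_rng(seed)
            thinned = K.copy()
            thinned[0, :] *= 1 - f  # infections into group 0 blocked by immunity
            big = 0
            for _ in range(n_chains):
                gen = np.array([1, 1])
                total = 2
                while gen.sum() > 0 and total < cap:
                    gen = rng.poisson(thinned @ gen)
                    total += gen.sum()
                big += total >= cap
            return big / n_chains

        assert outbreak_fraction(max(f_star - 0.15, 0.0)) > 0.10
        assert outbreak_fraction(min(f_star + 0.15, 1.0)) < 0.02

    def test_t_g_at_least_r0_for_partial_targets(self, truth):
        sigma = child_reduced_sigma()
        beta = calibrate_beta(truth, sigma, 1 / 3, 1.5)
        K = build_ngm(truth, EpidemicParams(beta, 1 / 3, sigma))
        for targets in standard_partitions()["sep"].values():
            res = type_reproduction(K, targets, truth.population)
            if res.feasible:
                assert res.t_g >= 1.5 - 1e-9

    def test_critical_immunity_prevents_outbreak(self, truth):
        """Seeding an epidemic with the critical fraction of the target
        group immune produces no outbreak growth."""
        pop = truth.population
        sigma = child_reduced_sigma()
        beta = calibrate_beta(truth, sigma, 1 / 3, 1.5)
        params = EpidemicParams(beta, 1 / 3, sigma)
        K = build_ngm(truth, params)
        targets = standard_partitions()["sep"]["sep:high"]
        res = type_reproduction(K, targets, pop)
        assert res.feasible
        immune = np.zeros(N_GROUPS)
        for k in targets:
            immune[GROUP_KEYS.index(k)] = res.critical_fraction * pop.counts[
                GROUP_KEYS.index(k)
            ]
        seed = 1e-7 * pop.counts
        traj = simulate_sir(truth, params, seed, initial_immune=immune, horizon=400.0)
        prevalence = traj.I.sum(axis=1)
        assert prevalence.max() <= prevalence[0] * 1.05

    def test_attack_rate_permutation_invariance(self, truth):
        sigma = np.linspace(0.5, 1.0, N_GROUPS)
        beta = calibrate_beta(truth, sigma, 1 / 3, 1.5)
        z = attack_rates(truth, EpidemicParams(beta, 1 / 3, sigma))
        perm = np.random.default_rng(1).permutation(N_GROUPS)
        pop_p = PopulationTable(truth.population.counts[perm])
        hat_p = ExpandedMatrix(truth.values[np.ix_(perm, perm)], pop_p)
        z_p = attack_rates(hat_p, EpidemicParams(beta, 1 / 3, sigma[perm]))
        np.testing.assert_allclose(z_p, z[perm], rtol=1e-9)


class TestControlReport:
    def test_degenerate_homogeneous_ensemble(self, hom):
        params = EpidemicParams(1.0, 1 / 3, child_reduced_sigma(), r0_target=1.5)
        detail, summary = control_strategy_report([hom, hom, hom], params)
        for _, grp in detail.groupby("target"):
            assert grp["overall_effort"].nunique(dropna=True) <= 1
        assert ((summary["success_probability"] >= 0) & (summary["success_probability"] <= 1)).all()

    def test_success_probability_is_feasible_fraction(self, small_ensemble):
        mats, _ = small_ensemble
        params = EpidemicParams(1.0, 1 / 3, child_reduced_sigma(), r0_target=1.5)
        detail, summary = control_strategy_report(mats[:30], params)
        for _, row in summary.iterrows():
            sub = detail[detail["target"] == row["target"]]
            assert row["success_probability"] == pytest.approx(
                sub["feasible"].mean()
            )

    def test_effort_nondecreasing_in_sep_assortativity(self, pop, bar_exact):
        """Within fixed margins, sweeping the SEP assortativity coordinate
        upward never reduces the critical effort for a high-SEP target,
        and extreme assortativity makes control infeasible."""
        from stratmix.expansion import (
            BLOCK_PAIRS,
            block_dof,
            build_block_margins,
            sample_block,
        )

        sigma = child_reduced_sigma()
        targets = standard_partitions()["sep"]["sep:high"]
        efforts = []
        for q_sep in (0.3, 0.5, 0.7, 0.9):
            hat = np.zeros((N_GROUPS, N_GROUPS))
            for pair in BLOCK_PAIRS:
                m = build_block_margins(bar_exact, pop, pair)
                q = np.full(block_dof(m), 0.5)
                if len(q):
                    q[0] = q_sep
                T = sample_block(m, q)
                rows, cols = list(m.row_strata), list(m.col_strata)
                hat[np.ix_(rows, cols)] = T / pop.counts[rows][:, None]
                if pair[0] != pair[1]:
                    hat[np.ix_(cols, rows)] = T.T / pop.counts[cols][:, None]
            hm = ExpandedMatrix(hat, pop)
            beta = calibrate_beta(hm, sigma, 1 / 3, 1.5)
            K = build_ngm(hm, EpidemicParams(beta, 1 / 3, sigma))
            res = type_reproduction(K, targets, pop)
            efforts.append(res.critical_fraction if res.feasible else np.inf)
        assert all(b >= a - 1e-3 for a, b in zip(efforts, efforts[1:]))
        assert efforts[-1] == np.inf  # fully assortative: high-SEP-only control fails
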