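"""CVs, metadynamics deposition, kinetics estimators, and toy oracles."""

import numpy as np
import pytest

import nanotaxis as nt
from nanotaxis.sampling import (BiasState, CVSpec, MetaDConfig, PoissonFit,
                                acceleration_factor, cv_com_xy, cv_contacts,
                                fit_poisson_tau, metad_deposit,
                                run_infrequent_metad, run_metad,
                                run_multiple_walker)
from nanotaxis.toys import (DoubleWell1D, brute_force_fpt,
                            toy_infrequent_metad, toy_wt_metad_profile)
from nanotaxis.units import KB, kbt


class TestCollectiveVariables:
    def test_com_xy_single_and_pair(self):
        types = [nt.BeadType("M")]
        s = nt.System(positions=[[1, 2, 3]], types=types, type_index=[0],
                      groups={"g": np.array([0])}, box=nt.Box(10, 10, 10))
        assert cv_com_xy(s, "g") == pytest.approx([1.0, 2.0])
        s2 = nt.System(positions=[[0, 0, 0], [2, 0, 0]], types=types,
                       type_index=[0, 0], groups={"g": np.arange(2)},
                       box=nt.Box(10, 10, 10))
        assert cv_com_xy(s2, "g") == pytest.approx([1.0, 0.0])

    def test_com_xy_continuous_across_wrap(self):
        """A pair straddling x = 0 must not produce a box-length jump."""
        types = [nt.BeadType("M")]
        s = nt.System(positions=[[9.9, 1, 1], [0.1, 1, 1]], types=types,
                      type_index=[0, 0], groups={"g": np.arange(2)},
                      box=nt.Box(10, 10, 10))
        x, y = cv_com_xy(s, "g")
        assert x % 10 == pytest.approx(0.0, abs=1e-9)

    def test_com_xy_empty_group_raises(self):
        types = [nt.BeadType("M")]
        s = nt.System(positions=[[0, 0, 0]], types=types, type_index=[0],
                      groups={"empty": np.zeros(0, dtype=int)})
        with pytest.raises(ValueError):
            cv_com_xy(s, "empty")

    def test_contacts_switching_values(self):
        types = [nt.BeadType("A"), nt.BeadType("B")]

        def system_at(r):
            return nt.System(positions=[[0, 0, 0], [r, 0, 0]], types=types,
                             type_index=[0, 1],
                             groups={"a": np.array([0]), "b": np.array([1])})

        # r = r0 -> 1/2 (the limit of the rational 6/12 switch)
        assert cv_contacts(system_at(0.6), "a", "b", 0.6) == pytest.approx(0.5)
        assert cv_contacts(system_at(10.0), "a", "b", 0.6) == pytest.approx(0.0, abs=1e-6)
        assert cv_contacts(system_at(0.01), "a", "b", 0.6) == pytest.approx(1.0, abs=1e-6)

    def test_contacts_bounded_by_pair_count(self):
        rng = np.random.default_rng(0)
        types = [nt.BeadType("A"), nt.BeadType("B")]
        pos = np.vstack([rng.uniform(0, 1, (8, 3)), rng.uniform(0, 1, (5, 3))])
        s = nt.System(positions=pos, types=types,
                      type_index=[0] * 8 + [1] * 5,
                      groups={"a": np.arange(8), "b": np.arange(8, 13)})
        assert 0 <= cv_contacts(s, "a", "b", 0.6) <= 40

    def test_contacts_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(1)
        types = [nt.BeadType("A"), nt.BeadType("B")]
        pos = rng.uniform(0, 1.5, (10, 3))
        s = nt.System(positions=pos, types=types, type_index=[0] * 6 + [1] * 4,
                      groups={"a": np.arange(6), "b": np.arange(6, 10)})
        val, grad = cv_contacts(s, "a", "b", 0.6, return_grad=True)
        h = 1e-7
        for b in (0, 3, 7):
            for ax in range(3):
                p = s.copy()
                p.positions[b, ax] += h
                up = cv_contacts(p, "a", "b", 0.6)
                p.positions[b, ax] -= 2 * h
                dn = cv_contacts(p, "a", "b", 0.6)
                assert grad[b, ax] == pytest.approx((up - dn) / (2 * h), abs=1e-5)


class TestBiasDeposition:
    def test_first_deposit_has_full_height(self):
        bias = BiasState(widths=np.array([0.5]))
        cfg = MetaDConfig(height=2.0, widths=(0.5,), stride=10, bias_factor=10)
        metad_deposit(bias, np.array([0.0]), cfg, 300.0, 0.0)
        assert bias.heights[0] == pytest.approx(2.0)

    def test_standard_metad_superposition(self):
        bias = BiasState(widths=np.array([0.5]))
        cfg = MetaDConfig(height=2.0, widths=(0.5,), stride=10)
        for k in range(5):
            metad_deposit(bias, np.array([1.0]), cfg, 300.0, float(k))
        assert bias.evaluate(np.array([1.0])) == pytest.approx(10.0)

    def test_well_tempered_heights_non_increasing_at_fixed_point(self):
        bias = BiasState(widths=np.array([0.5]))
        cfg = MetaDConfig(height=2.0, widths=(0.5,), stride=10, bias_factor=5)
        for k in range(8):
            metad_deposit(bias, np.array([0.0]), cfg, 300.0, float(k))
        assert np.all(np.diff(bias.heights) < 0)

    def test_bias_time_filter_and_nonnegativity(self):
        bias = BiasState(widths=np.array([0.3]))
        cfg = MetaDConfig(height=1.0, widths=(0.3,), stride=1)
        metad_deposit(bias, np.array([0.0]), cfg, 300.0, t=5.0)
        assert bias.evaluate(np.array([0.0]), t=1.0) == 0.0
        assert bias.evaluate(np.array([0.0]), t=5.0) == pytest.approx(1.0)

    def test_gradient_matches_finite_difference(self):
        bias = BiasState(widths=np.array([0.4, 0.7]))
        cfg = MetaDConfig(height=1.5, widths=(0.4, 0.7), stride=1)
        rng = np.random.default_rng(2)
        for k in range(6):
            metad_deposit(bias, rng.normal(size=2), cfg, 300.0, float(k))
        s = np.array([0.2, -0.3])
        g = bias.gradient(s)
        h = 1e-7
        for ax in range(2):
            e = np.zeros(2)
            e[ax] = h
            fd = (bias.evaluate(s + e) - bias.evaluate(s - e)) / (2 * h)
            assert g[ax] == pytest.approx(fd, abs=1e-6)


class TestAccelerationFactor:
    def test_zero_bias_gives_unity(self):
        assert acceleration_factor(np.zeros(100), 300.0) == pytest.approx(1.0)

    def test_constant_bias_closed_form(self):
        v = np.full(50, kbt(300) * np.log(10.0))
        assert acceleration_factor(v, 300.0) == pytest.approx(10.0)
        # numeric instance: k_B T = 2.494 kJ/mol at 300 K
        v2 = np.full(50, 2.494 * np.log(10.0))
        assert acceleration_factor(v2, 300.0) == pytest.approx(10.0, rel=1e-3)

    def test_large_bias_no_overflow_in_log_domain(self):
        from nanotaxis.sampling import log_acceleration_factor
        v = np.full(10, 5000.0)  # exp(beta V) ~ e^2000: needs log-sum-exp
        la = log_acceleration_factor(v, 300.0)
        assert np.isfinite(la)
        assert la == pytest.approx(5000.0 / kbt(300.0))


class TestPoissonFit:
    def test_single_time_mle(self):
        fit = fit_poisson_tau(np.array([3.5]))
        assert fit.tau == pytest.approx(3.5)

    def test_estimator_consistency(self):
        rng = np.random.default_rng(7)
        draws = rng.exponential(2.0, 1000)
        fit = fit_poisson_tau(draws)
        assert 1.9 <= fit.tau <= 2.1

    def test_ks_self_consistency(self):
        rng = np.random.default_rng(12)
        fit = fit_poisson_tau(rng.exponential(1.0, 30))
        assert fit.p_value > 0.05

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, 50)
        assert fit_poisson_tau(5.0 * t).tau == pytest.approx(5.0 * fit_poisson_tau(t).tau)

    def test_summary_mentions_tau(self):
        fit = fit_poisson_tau(np.array([1.0, 2.0, 3.0]))
        assert "tau" in fit.summary()
        assert isinstance(fit, PoissonFit)


class TestToyOracles:
    def test_transition_record_invariant(self):
        toy = DoubleWell1D(barrier=6.0)
        cfg = MetaDConfig(height=0.5, widths=(0.15,), stride=500, bias_factor=10)
        rec = toy_infrequent_metad(toy, cfg, seed=4)
        assert rec.alpha >= 1.0
        assert rec.time >= rec.t_metad

    def test_infrequent_metad_recovers_mfpt(self):
        """Full pipeline vs brute-force MFPT on a ~4 kT barrier, factor 2."""
        toy = DoubleWell1D(barrier=10.0, a=0.5)
        mfpt = brute_force_fpt(toy, 150, seed=5).mean()
        cfg = MetaDConfig(height=0.5, widths=(0.15,), stride=1000, bias_factor=10)
        recs = [toy_infrequent_metad(toy, cfg, seed=100 + k) for k in range(30)]
        times = np.array([r.time for r in recs if not r.censored])
        assert len(times) >= 25
        fit = fit_poisson_tau(times)
        assert 0.5 <= fit.tau / mfpt <= 2.0
        assert fit.p_value > 0.05

    def test_well_tempered_free_energy_recovery(self):
        toy = DoubleWell1D(barrier=10.0, a=0.5)
        cfg = MetaDConfig(height=1.0, widths=(0.1,), stride=500, bias_factor=8)
        grid, f_est = toy_wt_metad_profile(toy, cfg, 2_000_000, seed=11)
        u = toy.potential(grid)
        u -= u.min()
        window = np.abs(grid) <= 0.55
        diff = (f_est - u)[window]
        diff -= diff.mean()
        assert np.abs(diff).max() <= 0.5 * kbt(300.0)


class TestBiasedDynamics3D:
    @pytest.fixture()
    def flat_system(self):
        """One mobile bead on a featureless plane with a wall."""
        types = [nt.BeadType("M", mass=72.0)]
        s = nt.System(positions=[[5.0, 5.0, 0.5]], types=types, type_index=[0],
                      groups={"np": np.array([0])}, box=nt.Box(10, 10, 8))
        from nanotaxis.forcefield import ForceField, PairTable, WallParams
        ff = ForceField(PairTable({"M": 0.47}, {"M": 0.0}), wall=WallParams())
        return s, ff

    def test_zero_height_equals_unbiased_is_impossible_so_bias_spreads(self, flat_system):
        """Metadynamics must push the particle to explore more xy area."""
        s, ff = flat_system
        params = nt.IntegratorParams(seed=21)
        cfg = MetaDConfig(height=5.0, widths=(0.5, 0.5), stride=100, log_stride=20)
        cv = CVSpec("com_xy", ("np",))
        traj_b, bias, log = run_metad(s, cv, cfg, params, ff, 10_000, traj_stride=100)
        traj_u = nt.run_md(s, 10_000, params, ff, traj_stride=100)
        spread_b = np.ptp(traj_b.com_trace("np")[:, :2], axis=0).max()
        spread_u = np.ptp(traj_u.com_trace("np")[:, :2], axis=0).max()
        assert bias.n_kernels == 100
        assert spread_b > spread_u

    def test_no_bias_force_along_z(self, flat_system):
        """com_xy bias leaves z untouched: identical z under same noise."""
        s, ff = flat_system
        params = nt.IntegratorParams(seed=22)
        cfg = MetaDConfig(height=5.0, widths=(0.5, 0.5), stride=200, log_stride=50)
        traj_b, _, _ = run_metad(s, CVSpec("com_xy", ("np",)), cfg, params, ff,
                                 2_000, traj_stride=50)
        z = traj_b.com_trace("np")[:, 2]
        assert (z > 0).all() and z.max() < 8.0  # held by the wall only

    def test_infrequent_metad_on_bound_pair(self):
        """A weakly bound bead biased on the contacts CV escapes; the record
        satisfies t >= t_MetaD and alpha >= 1."""
        from nanotaxis.forcefield import ForceField, PairTable
        types = [nt.BeadType("A", charge=0.0), nt.BeadType("B", frozen=True,
                                                           role="receptor-base")]
        s = nt.System(positions=[[5.0, 5.0, 0.45], [5.0, 5.0, 0.0]],
                      types=types, type_index=[0, 1],
                      groups={"a": np.array([0]), "b": np.array([1])},
                      box=nt.Box(10, 10, 6))
        ff = ForceField(PairTable({"A": 0.35, "B": 0.35},
                                  {"A": 8.0, "B": 8.0}))
        cfg = MetaDConfig(height=1.0, widths=(0.5,), stride=100,
                          bias_factor=10, log_stride=10)
        cv = CVSpec("contacts", ("a", "b"), r0=0.6)
        rec = run_infrequent_metad(
            s, cv, cfg, nt.IntegratorParams(seed=31), ff,
            max_steps=50_000, monitor_stride=20, stop_persistence=5)
        assert not rec.censored
        assert rec.alpha >= 1.0
        assert rec.time >= rec.t_metad
        assert rec.cv_final < 0.5

    def test_infrequent_metad_already_unbound_returns_zero_time(self):
        from nanotaxis.forcefield import ForceField, PairTable
        types = [nt.BeadType("A"), nt.BeadType("B", frozen=True,
                                               role="receptor-base")]
        s = nt.System(positions=[[2.0, 2.0, 4.0], [8.0, 8.0, 0.0]],
                      types=types, type_index=[0, 1],
                      groups={"a": np.array([0]), "b": np.array([1])},
                      box=nt.Box(10, 10, 6))
        ff = ForceField(PairTable({"A": 0.35, "B": 0.35}, {"A": 1.0, "B": 1.0}))
        cfg = MetaDConfig(height=1.0, widths=(0.5,), stride=100)
        rec = run_infrequent_metad(
            s, CVSpec("contacts", ("a", "b"), r0=0.6), cfg,
            nt.IntegratorParams(seed=32), ff, max_steps=1000)
        assert rec.t_metad == 0.0
        assert rec.alpha == 1.0
        assert rec.time == 0.0

    def test_multiple_walker_bookkeeping(self, flat_system):
        s, ff = flat_system
        params = nt.IntegratorParams(seed=23)
        cfg = MetaDConfig(height=2.0, widths=(0.5, 0.5), stride=200, log_stride=100)
        cv = CVSpec("com_xy", ("np",))
        trajs, bias = run_multiple_walker(s, cv, cfg, params, ff, 2_000,
                                          n_walkers=4)
        # 4x the kernels of a single walker at equal per-walker steps
        assert bias.n_kernels == 4 * (2_000 // 200)
        assert len(trajs) == 4
        _, bias1 = run_multiple_walker(s, cv, cfg, params, ff, 2_000, n_walkers=1)
        assert bias1.n_kernels == 2_000 // 200
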