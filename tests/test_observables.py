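"""Engagement, SASA, release, MSD and occupancy observables."""

import numpy as np
import pytest

import nanotaxis as nt
from nanotaxis.dynamics import Trajectory
from nanotaxis.observables import (ObservableSeries, delta_sasa_percent,
                                   engagement_count, guest_release,
                                   msd_and_velocity, region_occupancy, sasa)


def make_system(positions, groups, types=None):
    types = types or [nt.BeadType("M")]
    n = len(positions)
    return nt.System(positions=positions, types=types,
                     type_index=np.zeros(n, dtype=int), groups=groups)


def make_traj(system, frames, dt=1.0):
    traj = Trajectory(system=system)
    for f, pos in enumerate(frames):
        traj.times.append(f * dt)
        traj.positions.append(np.asarray(pos, dtype=float))
    return traj


class TestEngagement:
    def test_far_apart_is_zero(self):
        s = make_system([[0, 0, 0], [5, 5, 5]],
                        {"np-charged": np.array([0]),
                         "receptor-head": np.array([1])})
        assert engagement_count(s) == 0

    def test_bounded_by_charged_group_size(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 0.5, (20, 3))
        s = make_system(pos, {"np-charged": np.arange(5),
                              "receptor-head": np.arange(5, 20)})
        assert engagement_count(s) <= 5

    def test_trivalent_saturation_is_132(self):
        """All 132 charged beads engaged -> the analytic maximum, 132."""
        rng = np.random.default_rng(1)
        n = 132
        charged = rng.uniform(0, 10, (n, 3))
        heads = charged + rng.uniform(-0.2, 0.2, (n, 3))  # one partner each
        pos = np.vstack([charged, heads])
        s = make_system(pos, {"np-charged": np.arange(n),
                              "receptor-head": np.arange(n, 2 * n)})
        assert engagement_count(s) == 132


class TestSasa:
    def test_isolated_sphere_analytic(self):
        a = sasa(np.zeros((1, 3)), np.array([0.3]), probe_radius=0.19,
                 n_sphere_points=960)
        assert a == pytest.approx(4 * np.pi * 0.49**2, rel=0.01)

    def test_separated_beads_additive(self):
        pos = np.array([[0, 0, 0], [5.0, 0, 0]])
        r = np.array([0.3, 0.3])
        both = sasa(pos, r)
        one = sasa(pos[:1], r[:1])
        assert both == pytest.approx(2 * one, rel=0.01)

    def test_buried_bead_contributes_nothing(self):
        # central bead enclosed by a shell of 26 overlapping beads
        offsets = [np.array([i, j, k], dtype=float)
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
        shell = np.array(offsets) * 0.35
        pos = np.vstack([np.zeros(3), shell])
        r = np.full(len(pos), 0.3)
        buried = sasa(pos, r)
        shell_only = sasa(shell, r[1:])
        assert buried == pytest.approx(shell_only, rel=0.02)

    def test_delta_sasa(self):
        series = np.array([50.0, 50.0, 100.0])
        out = delta_sasa_percent(series)
        assert out == pytest.approx([0.0, 0.0, 100.0])
        with pytest.raises(ValueError):
            delta_sasa_percent(series, reference=0.0)


class TestGuestRelease:
    def _traj(self, guest_path):
        """Two monomers fixed at origin; one guest following guest_path."""
        n_frames = len(guest_path)
        frames = [np.vstack([[0, 0, 0], [0.3, 0, 0], g]) for g in guest_path]
        s = make_system(frames[0], {"monomer": np.arange(2),
                                    "guest": np.array([2])})
        return make_traj(s, frames)

    def test_intact_np_no_release(self):
        traj = self._traj([[0.2, 0.2, 0]] * 30)
        rep = guest_release(traj, persistence=5)
        assert rep.final_percent == 0.0

    def test_detached_from_start_released_after_persistence(self):
        traj = self._traj([[5, 5, 5]] * 30)
        rep = guest_release(traj, persistence=5)
        assert rep.final_percent == 100.0
        assert not np.isnan(rep.guest_release_time[0])

    def test_transient_detachment_not_counted(self):
        path = [[0.2, 0, 0]] * 10 + [[5, 5, 5]] * 3 + [[0.2, 0, 0]] * 17
        rep = guest_release(self._traj(path), persistence=5)
        assert rep.final_percent == 0.0

    def test_fraction_non_decreasing_and_partial(self):
        # 1 of 2 guests leaves permanently
        frames = []
        for f in range(30):
            g1 = [5, 5, 5] if f >= 10 else [0.2, 0.2, 0]
            frames.append(np.vstack([[0, 0, 0], [0.3, 0, 0], g1, [0.1, 0.2, 0]]))
        s = make_system(frames[0], {"monomer": np.arange(2),
                                    "guest": np.array([2, 3])})
        rep = guest_release(make_traj(s, frames), persistence=5)
        assert rep.final_percent == 50.0
        assert np.all(np.diff(rep.release_fraction) >= 0)


class TestMsdAndOccupancy:
    def test_static_group_zero_msd_and_velocity(self):
        s = make_system([[1, 1, 1]], {"np": np.array([0])})
        traj = make_traj(s, [[[1, 1, 1]]] * 10)
        series, vel = msd_and_velocity(traj, "np")
        assert np.allclose(series.values, 0.0)
        assert vel == pytest.approx(0.0, abs=1e-12)

    def test_brownian_msd_matches_einstein(self):
        """Free 2D diffusion: MSD(dt) ~ 4 D dt with D = kT/(gamma m)."""
        from nanotaxis.units import KB
        rng = np.random.default_rng(8)
        D = KB * 300 / (1.0 * 72.0)
        dt_frame = 1.0
        n_frames, n_ens = 400, 20
        msds = []
        for e in range(n_ens):
            steps = rng.normal(scale=np.sqrt(2 * D * dt_frame), size=(n_frames, 2))
            xy = np.cumsum(steps, axis=0)
            pos = np.column_stack([xy, np.zeros(n_frames)])
            s = make_system(pos[:1], {"np": np.array([0])})
            traj = make_traj(s, pos[:, None, :], dt=dt_frame)
            series, _ = msd_and_velocity(traj, "np")
            msds.append(series.values[:40])
        lag = series.times[:40]
        mean_msd = np.mean(msds, axis=0)
        slope = np.polyfit(lag, mean_msd, 1)[0]
        assert slope == pytest.approx(4 * D, rel=0.10)

    def test_occupancy_pinned_and_null_model(self):
        spec = nt.two_region_spec(10, 10, 1.0, 0.5)
        s = make_system([[8, 5, 1]], {"np": np.array([0])})
        traj = make_traj(s, [[[8, 5, 1]]] * 20)
        occ = region_occupancy(traj, spec)
        assert occ == pytest.approx([0.0, 1.0])
        # uniform random walk: fractions track region areas
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 10, (4000, 2))
        frames = [np.array([[x, y, 1.0]]) for x, y in pts]
        occ2 = region_occupancy(make_traj(s, frames), spec)
        assert occ2.sum() == pytest.approx(1.0)
        assert occ2[0] == pytest.approx(0.5, abs=0.03)

    def test_series_validation(self):
        with pytest.raises(ValueError):
            ObservableSeries("x", [0, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            ObservableSeries("x", [0, 1], [1, 2, 3])
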