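"""Builder determinism, counts, charges, and packing guarantees."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import nanotaxis as nt
from nanotaxis.builders import OligomerTemplate, round_half_away


def min_separation(positions):
    d, _ = cKDTree(positions).query(positions, k=2)
    return d[:, 1].min()


class TestMcgNanoparticle:
    def test_bead_counts_and_guest_interiority(self):
        s = nt.build_nanoparticle_mcg(1925, 12, seed=1)
        assert s.n_beads == 1937
        assert len(s.group("monomer")) == 1925
        # guests sit inside the monomer shell: all guest radii below the
        # 90th-percentile monomer radius
        center = s.positions.mean(axis=0)
        rm = np.linalg.norm(s.positions[s.group("monomer")] - center, axis=1)
        rg = np.linalg.norm(s.positions[s.group("guest")] - center, axis=1)
        assert rg.max() < np.quantile(rm, 0.9)

    def test_single_bead_degenerate(self):
        s = nt.build_nanoparticle_mcg(1, 0, seed=7)
        assert s.n_beads == 1
        assert np.allclose(s.positions, 0.0, atol=0.05)

    def test_seeded_determinism(self, small_mcg_np):
        again = nt.build_nanoparticle_mcg(100, 5, seed=3)
        assert np.array_equal(small_mcg_np.positions, again.positions)

    def test_minimum_separation(self, small_mcg_np):
        assert min_separation(small_mcg_np.positions) >= 0.9 * 0.43

    def test_infeasible_packing_radius_raises(self):
        with pytest.raises(ValueError, match="packing_radius"):
            nt.build_nanoparticle_mcg(1000, 0, packing_radius=1.0, seed=0)


class TestFcgNanoparticle:
    @pytest.mark.parametrize("heads,charge", [(3, -132.0), (2, -88.0), (1, -44.0)])
    def test_valency_sets_total_charge(self, heads, charge):
        tpl = OligomerTemplate(n_charged_heads=heads)
        s = nt.build_nanoparticle_fcg(tpl, 44, 10, seed=1, relax_steps=0)
        assert s.net_charge() == pytest.approx(charge)
        assert len(s.group("np-charged")) == 44 * heads

    def test_single_oligomer(self):
        s = nt.build_nanoparticle_fcg(OligomerTemplate(), 1, 0, seed=2, relax_steps=10)
        assert s.net_charge() == pytest.approx(-3.0)
        assert s.n_beads == OligomerTemplate().n_beads

    def test_template_topology_is_connected_tree(self):
        tpl = OligomerTemplate()
        _, roles, bonds, _ = tpl.local_layout()
        n = tpl.n_beads
        assert len(bonds) == n - 1
        adj = {k: set() for k in range(n)}
        for i, j, *_ in bonds:
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
        seen, stack = set(), [0]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            stack.extend(adj[k])
        assert len(seen) == n

    def test_amphiphilic_orientation(self, trivalent_np):
        """Tails point inward, charged heads outward."""
        center = trivalent_np.com()
        roles = trivalent_np.roles
        r = np.linalg.norm(trivalent_np.positions - center, axis=1)
        assert r[roles == "oligomer-tail"].mean() < r[roles == "oligomer-head-charged"].mean()

    def test_invalid_head_count(self):
        with pytest.raises(ValueError):
            OligomerTemplate(n_charged_heads=4)


class TestSurfaces:
    def test_tribead_uniform_counts(self):
        spec = nt.SurfaceSpec(20, 20, (nt.Region(0, 20, 0, 20, 1.0),),
                              receptor_model="tribead_tethered", head_charge=1.0)
        s = nt.build_surface(spec, seed=1)
        assert len(s.group("receptor-head")) == 400
        assert s.n_beads == 1200
        # base frozen at z=0, +1e head on top
        assert s.frozen[s.group("receptor-base")].all()
        assert not s.frozen[s.group("receptor-head")].any()
        assert s.charges[s.group("receptor-head")].sum() == pytest.approx(400.0)

    def test_empty_density(self):
        spec = nt.SurfaceSpec(10, 10, (nt.Region(0, 10, 0, 10, 0.0),))
        assert nt.build_surface(spec, seed=0).n_beads == 0

    def test_region_counts_follow_round_half_away(self):
        spec = nt.gradient_stripes_spec([0.0, 0.12, 0.52, 1.12], 30, 30)
        assert spec.lx == 120 and spec.ly == 30
        assert spec.realized_counts() == [0, 108, 468, 1008]
        assert [round_half_away(900 * r.rho) for r in spec.regions] == spec.realized_counts()

    def test_two_region_64fold_ratio(self):
        spec = nt.two_region_spec(40, 40, 1.0, 1 / 64)
        lo, hi = spec.regions
        assert lo.rho == pytest.approx(0.015625)
        s = nt.build_surface(spec, seed=5)
        xy = s.positions[s.group("receptor-head"), 0]
        n_lo = int((xy < 20).sum())
        n_hi = int((xy >= 20).sum())
        assert (n_lo, n_hi) == (13, 800)  # round(800/64), round(800)

    def test_two_region_trivial_cases(self):
        uni = nt.two_region_spec(40, 40, 1.0, 1.0)
        assert uni.regions[0].rho == uni.regions[1].rho == 1.0
        empty = nt.two_region_spec(40, 40, 0.0, 0.5)
        assert nt.build_surface(empty, seed=0).n_beads == 0

    def test_poisson_disc_minimum_gap(self):
        spec = nt.SurfaceSpec(15, 15, (nt.Region(0, 15, 0, 15, 0.5),))
        s = nt.build_surface(spec, seed=2)
        # the gap rule uses the realized density (exact count / area)
        rho = spec.realized_counts()[0] / (15 * 15)
        rmin = 1.0 / np.sqrt(2 * rho)
        assert min_separation(s.positions) >= rmin - 1e-9

    def test_lattice_placement_exact_counts(self):
        spec = nt.SurfaceSpec(12, 9, (nt.Region(0, 12, 0, 9, 0.7),),
                              placement="lattice")
        s = nt.build_surface(spec, seed=0)
        assert s.n_beads == round(12 * 9 * 0.7)

    def test_single_stripe_and_empty_stripes(self):
        one = nt.gradient_stripes_spec([0.5], 10, 10)
        assert one.realized_counts() == [50]
        empty = nt.gradient_stripes_spec([0, 0], 5, 5)
        assert nt.build_surface(empty, seed=0).n_beads == 0


class TestAssembly:
    def test_counterion_neutralization(self):
        npf = nt.build_nanoparticle_fcg(n_oligomers=44, n_guests=10, seed=1,
                                        relax_steps=0)
        spec = nt.SurfaceSpec(25, 25, (nt.Region(0, 25, 0, 25, 0.0),), lz=20)
        surf = nt.build_surface(spec, seed=0)
        s = nt.assemble_system(npf, surf, z_offset=1.0, neutralize=True, seed=4)
        ions = s.group("counterion")
        assert len(ions) == 132
        assert s.charges[ions].sum() == pytest.approx(132.0)
        assert s.net_charge() == pytest.approx(0.0)

    def test_neutral_np_adds_no_ions(self, small_mcg_np):
        spec = nt.SurfaceSpec(15, 15, (nt.Region(0, 15, 0, 15, 0.2),))
        surf = nt.build_surface(spec, seed=1)
        s = nt.assemble_system(small_mcg_np, surf, z_offset=0.8, neutralize=True, seed=2)
        assert "counterion" not in s.groups
        assert s.net_charge() == pytest.approx(0.0)

    def test_assembly_determinism(self, small_mcg_np):
        spec = nt.two_region_spec(30, 30, 0.4, 1 / 64)
        a = nt.assemble_system(small_mcg_np, nt.build_surface(spec, seed=1),
                               z_offset=0.8, neutralize=True, seed=9)
        b = nt.assemble_system(small_mcg_np, nt.build_surface(spec, seed=1),
                               z_offset=0.8, neutralize=True, seed=9)
        assert np.array_equal(a.positions, b.positions)

    def test_frozen_velocity_invariant(self):
        spec = nt.SurfaceSpec(10, 10, (nt.Region(0, 10, 0, 10, 0.5),))
        s = nt.build_surface(spec, seed=3)
        assert np.all(s.velocities[s.frozen] == 0.0)
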