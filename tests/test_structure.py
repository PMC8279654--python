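"""Surface-structure analyses: GRO I/O, density/GDS, H-bonds, orientations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfprop import (
    HBondCriteria,
    Snapshot,
    close_pairs,
    count_hbonds,
    density_profile,
    gibbs_dividing_surface,
    hbond_vs_r,
    hda_angle_distribution,
    interphase_region,
    make_density_snapshots,
    make_hbond_fixture,
    orientation_distribution,
    read_gro,
    write_gro,
)
from surfprop.errors import GeometryError, InputError, ParseError
from surfprop.structure import DensityProfile, select_hbond_atoms

from oracles import brute_force_close_pairs, brute_force_hbond_count

GRO_3ATOM = """three atoms
    3
    1SOL     OW    1   1.500   2.000   2.500
    1SOL    HW1    2   1.560   2.010   2.520
    2ION     NA    3   0.300   0.400   0.500
   4.00000   4.00000   4.00000
"""


def _snap(positions, box=(5.0, 5.0, 5.0), names=None, resids=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return Snapshot(
        box=np.asarray(box, dtype=float),
        names=np.array(names if names is not None else ["X"] * n, dtype=object),
        resids=np.array(resids if resids is not None else [1] * n),
        resnames=np.array(["RES"] * n, dtype=object),
        positions=positions,
    )


class TestGroIO:
    def test_parse_handwritten_file(self, tmp_path):
        p = tmp_path / "a.gro"
        p.write_text(GRO_3ATOM)
        snap = read_gro(p)
        assert snap.n_atoms == 3
        assert list(snap.names) == ["OW", "HW1", "NA"]
        assert snap.positions[0] == pytest.approx([1.5, 2.0, 2.5], abs=1e-3)
        assert snap.box == pytest.approx([4.0, 4.0, 4.0])

    def test_roundtrip_preserves_geometry(self, tmp_path):
        fixture = make_hbond_fixture([(0.28, 0.0), (0.33, 20.0)], seed=5)
        path = tmp_path / "fix.gro"
        write_gro(fixture, path)
        back = read_gro(path)
        assert back.n_atoms == fixture.n_atoms
        assert np.abs(back.positions - fixture.positions).max() < 5.1e-4  # 3-decimal nm
        assert list(back.names) == list(fixture.names)

    def test_truncated_file_is_parse_error(self, tmp_path):
        p = tmp_path / "t.gro"
        p.write_text("".join(GRO_3ATOM.splitlines(keepends=True)[:3]))
        with pytest.raises(ParseError) as err:
            read_gro(p)
        assert err.value.line is not None

    def test_bad_count_line(self, tmp_path):
        p = tmp_path / "b.gro"
        p.write_text("title\nnot-a-number\n")
        with pytest.raises(ParseError) as err:
            read_gro(p)
        assert err.value.line == 2

    def test_malformed_coordinate_field(self, tmp_path):
        bad = GRO_3ATOM.replace("   1.500", "   x.500")
        p = tmp_path / "m.gro"
        p.write_text(bad)
        with pytest.raises(ParseError) as err:
            read_gro(p)
        assert err.value.line == 3


class TestDensityProfile:
    def test_single_bin_density(self):
        snap = _snap([[1.0, 1.0, 2.51], [2.0, 2.0, 2.52]], box=(5, 5, 5))
        snap.resnames[:] = "SOL"
        prof = density_profile([snap], "SOL", bin_width=0.5)
        bin_vol = 0.5 * 25.0
        hot = prof.density[np.argmin(np.abs(prof.z_centers - 2.75))]
        assert hot == pytest.approx(2 / bin_vol)
        assert prof.density.sum() == pytest.approx(2 / bin_vol)

    def test_matches_generating_profile(self):
        snaps = make_density_snapshots(3.0, 2.0, 0.3, 33.0, (3, 3, 6), 200, seed=4)
        prof = density_profile(snaps, "SOL", bin_width=0.1)
        rho = 33.0 * 0.5 * (1 - np.tanh((np.abs(prof.z_centers - 3.0) - 2.0) / 0.3))
        expected_counts = rho * 9.0 * 0.1 * 200
        sigma = np.sqrt(np.maximum(expected_counts, 1.0)) / (9.0 * 0.1 * 200)
        z = np.abs(prof.density - rho) / sigma
        assert np.mean(z < 3.0) >= 0.99

    def test_bin_refinement_preserves_density(self):
        snaps = make_density_snapshots(3.0, 2.0, 0.3, 33.0, (3, 3, 6), 100, seed=5)
        coarse = density_profile(snaps, "SOL", bin_width=0.2)
        fine = density_profile(snaps, "SOL", bin_width=0.1)
        assert fine.bulk_density == pytest.approx(coarse.bulk_density, rel=0.05)

    def test_empty_selection_rejected(self):
        snap = _snap([[1, 1, 1]])
        with pytest.raises(InputError):
            density_profile([snap], "SOL")


class TestGibbsDividingSurface:
    def _profile(self, z, rho, bulk):
        return DensityProfile(
            z_centers=z, density=rho, bulk_density=bulk,
            bin_width=float(z[1] - z[0]), slab_center=3.0,
        )

    def test_step_profile(self):
        z = np.arange(0.05, 6.0, 0.1)
        rho = np.where(np.abs(z - 3.0) < 2.0, 30.0, 0.0)
        gds = gibbs_dividing_surface(self._profile(z, rho, 30.0))
        assert gds == pytest.approx(2.0, abs=0.1)

    def test_tanh_profile_midpoint(self):
        z = np.arange(0.025, 6.0, 0.05)
        rho = 33.0 * 0.5 * (1 - np.tanh((np.abs(z - 3.0) - 2.0) / 0.3))
        gds = gibbs_dividing_surface(self._profile(z, rho, 33.0))
        assert gds == pytest.approx(2.0, abs=0.025)

    def test_gds_recovery_across_interface_widths(self):
        """GDS estimate lands within one bin width of truth for widths 0.1-0.5."""
        for i, width in enumerate((0.1, 0.2, 0.3, 0.4, 0.5)):
            snaps = make_density_snapshots(3.0, 2.0, width, 33.0, (3, 3, 7), 200, seed=20 + i)
            prof = density_profile(snaps, "SOL", bin_width=0.05)
            assert abs(gibbs_dividing_surface(prof) - 2.0) < 0.05

    def test_uniform_profile_has_no_interface(self):
        z = np.arange(0.05, 6.0, 0.1)
        with pytest.raises(GeometryError):
            gibbs_dividing_surface(self._profile(z, np.full(z.size, 30.0), 30.0))


class TestInterphaseRegion:
    def test_standard_interval_from_gds(self):
        assert interphase_region(2.2, 0.6) == pytest.approx((1.6, 2.8))

    def test_zero_halfwidth_rejected(self):
        with pytest.raises(InputError):
            interphase_region(2.2, 0.0)

    def test_arithmetic(self):
        assert interphase_region(2.0, 0.5) == pytest.approx((1.5, 2.5))


class TestCountHBonds:
    def _triple(self, d_da, h_offset):
        """Donor at origin, acceptor at +x, hydrogen on the D->A axis."""
        pos = [[1.0, 1.0, 1.0], [1.0 + h_offset, 1.0, 1.0], [1.0 + d_da, 1.0, 1.0]]
        snap = _snap(pos, names=["OD", "HD", "OA"])
        return snap, np.array([0]), {0: [1]}, np.array([2])

    def test_ideal_bond_counted(self):
        snap, d, h, a = self._triple(0.28, 0.1)
        assert count_hbonds(snap, d, h, a, HBondCriteria()) == 1

    def test_distance_cutoff(self):
        snap, d, h, a = self._triple(0.40, 0.1)
        assert count_hbonds(snap, d, h, a, HBondCriteria()) == 0

    def test_angle_cutoff(self):
        snap = make_hbond_fixture([(0.30, 45.0)], seed=1)
        d, h, a = select_hbond_atoms(snap)
        assert count_hbonds(snap, d, h, a, HBondCriteria()) == 0
        snap = make_hbond_fixture([(0.30, 10.0)], seed=1)
        d, h, a = select_hbond_atoms(snap)
        assert count_hbonds(snap, d, h, a, HBondCriteria()) == 1

    @pytest.mark.parametrize("vertex", ["hydrogen", "donor"])
    def test_matches_brute_force_on_random_fixtures(self, vertex):
        rng = np.random.default_rng(31)
        for trial in range(20):
            geoms = [
                (float(dd), float(aa))
                for dd, aa in zip(rng.uniform(0.15, 0.5, 12), rng.uniform(0, 90, 12))
            ]
            snap = make_hbond_fixture(geoms, seed=int(rng.integers(2**31)),
                                      angle_vertex=vertex)
            d, h, a = select_hbond_atoms(snap)
            crit = HBondCriteria(angle_vertex=vertex)
            assert count_hbonds(snap, d, h, a, crit) == brute_force_hbond_count(
                snap, d, h, a, crit.max_da_distance, crit.max_angle_dev, vertex
            )

    def test_minimum_image_translation_invariance(self):
        snap = make_hbond_fixture([(0.3, 5.0)] * 6, seed=9)
        d, h, a = select_hbond_atoms(snap)
        base = count_hbonds(snap, d, h, a)
        shifted = Snapshot(
            box=snap.box, names=snap.names, resids=snap.resids,
            resnames=snap.resnames, positions=snap.positions + snap.box,
        )
        assert count_hbonds(shifted, d, h, a) == base

    def test_unmapped_donor_rejected(self):
        snap, d, h, a = self._triple(0.28, 0.1)
        with pytest.raises(InputError):
            count_hbonds(snap, d, {}, a)

    def test_hbond_vs_r_flat_and_empty_window(self):
        snap_2 = make_hbond_fixture([(0.28, 0.0), (0.30, 5.0)], seed=2)
        per_window = {1.0: [snap_2], 2.0: [snap_2, snap_2], 3.0: []}
        with pytest.warns(UserWarning):
            series = hbond_vs_r(per_window)
        assert series == [(1.0, 2.0), (2.0, 2.0)]


class TestOrientationDistribution:
    def test_aligned_mass_in_last_bin(self):
        vecs = np.tile([0.0, 0.0, 3.0], (10, 1))
        hist = orientation_distribution(vecs, n_bins=10)
        assert hist.density[-1] > 0
        assert np.sum(hist.density[:-1]) == 0
        assert np.sum(hist.density * np.diff(hist.edges)) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_under_inversion(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=(20000, 3))
        both = np.vstack([v, -v])
        hist = orientation_distribution(both, n_bins=10)
        assert np.allclose(hist.density, hist.density[::-1])

    def test_zero_vector_rejected(self):
        with pytest.raises(InputError):
            orientation_distribution(np.zeros((2, 3)))

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_histogram_always_normalized(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(rng.integers(1, 200), 3))
        v = v[np.linalg.norm(v, axis=1) > 1e-8]
        if len(v) == 0:
            return
        hist = orientation_distribution(v, n_bins=17)
        assert np.sum(hist.density * np.diff(hist.edges)) == pytest.approx(1.0, abs=1e-9)


class TestClosePairs:
    def test_pair_inside_cutoff(self):
        snap = _snap([[1, 1, 1], [1.3, 1, 1]])
        pairs = close_pairs(snap, 1, cutoff=0.35)
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(0.3)

    def test_pair_outside_cutoff(self):
        snap = _snap([[1, 1, 1], [1.4, 1, 1]])
        assert close_pairs(snap, 1, cutoff=0.35) == []

    def test_matches_brute_force_on_random_atoms(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            snap = _snap(rng.uniform(0, 2.0, (20, 3)), box=(2.0, 2.0, 2.0))
            got = {(i, j) for i, j, _ in close_pairs(snap, 1, cutoff=0.35)}
            assert got == brute_force_close_pairs(snap, 1, 0.35)

    def test_sorted_by_distance(self):
        snap = _snap([[1, 1, 1], [1.3, 1, 1], [1.0, 1.1, 1]])
        dists = [d for _, _, d in close_pairs(snap, 1, cutoff=0.5)]
        assert dists == sorted(dists)

    def test_bonded_exclusion(self):
        snap = _snap([[1, 1, 1], [1.1, 1, 1], [1.2, 1, 1]])
        bonds = [(0, 1), (1, 2)]
        got = close_pairs(snap, 1, cutoff=0.5, min_bond_separation=2, bonds=bonds)
        assert [(i, j) for i, j, _ in got] == [(0, 2)]

    def test_unknown_residue_rejected(self):
        snap = _snap([[1, 1, 1]])
        with pytest.raises(InputError):
            close_pairs(snap, 99, cutoff=0.35)


class TestHdaAngleDistribution:
    def test_single_ideal_triple_at_zero(self):
        snap = make_hbond_fixture([(0.30, 0.0)], seed=3)
        d, h, a = select_hbond_atoms(snap)
        dist = hda_angle_distribution(snap, d, h, a)
        assert dist.count == 1
        assert dist.angles_deg[0] == pytest.approx(0.0, abs=1e-5)

    def test_planted_angles_recovered(self):
        snap = make_hbond_fixture([(0.3, 10.0), (0.3, 40.0), (0.3, 90.0)], seed=8)
        d, h, a = select_hbond_atoms(snap)
        dist = hda_angle_distribution(snap, d, h, a)
        assert dist.angles_deg == pytest.approx([10.0, 40.0, 90.0], abs=1e-3)
        assert np.sum(dist.density * np.diff(dist.edges)) == pytest.approx(1.0, abs=1e-9)

    def test_no_pairs_gives_empty_histogram(self):
        snap = make_hbond_fixture([(0.45, 0.0)], seed=3)
        d, h, a = select_hbond_atoms(snap)
        dist = hda_angle_distribution(snap, d, h, a, max_da_distance=0.35)
        assert dist.count == 0
        assert np.all(dist.density == 0)
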