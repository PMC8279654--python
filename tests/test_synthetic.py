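"""Synthetic system: closed forms, sampler statistics, fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from surfprop import (
    KB,
    LangevinParams,
    TruePotentialParams,
    make_density_snapshots,
    make_hbond_fixture,
    make_orientation_fixture,
    sample_window,
    true_enthalpy,
    true_enthalpy_components,
    true_minus_t_delta_s,
    true_pmf,
)
from surfprop.errors import ConfigurationError, InputError
from surfprop.synthetic import check_stability, measure_hbond_geometries, switch

# Closed-form landscape values at default parameters, frozen from an
# independent arbitrary-precision evaluation of the Gaussian-well +
# exponential-wall formula.
PMF_TABLE = [
    (1.0, 1.1242068797697684e-07),
    (1.5, -0.00600259827335077),
    (2.0, -4.727318592357161),
    (2.05, -4.995913228561536),
    (2.5, 0.3123344584802308),
    (3.0, 54.5981500233954),
]


class TestClosedForms:
    @pytest.mark.parametrize("r,expected", PMF_TABLE)
    def test_pmf_matches_frozen_oracle(self, r, expected, default_potential):
        assert true_pmf(r, default_potential) == pytest.approx(expected, rel=1e-12)

    def test_well_depth_at_center(self):
        p = TruePotentialParams(well_depth=5.0, wall_position=100.0)
        assert true_pmf(p.well_center, p) == pytest.approx(-5.0, abs=1e-9)

    def test_bulk_reference_is_zero(self, default_potential):
        assert abs(true_pmf(1.0, default_potential)) < 1e-6

    def test_nonfinite_r_rejected(self, default_potential):
        with pytest.raises(InputError):
            true_pmf(float("nan"), default_potential)

    def test_components_bulk_limit(self, default_potential):
        ww, aaw, aaaa = true_enthalpy_components(0.5, default_potential)
        assert max(abs(ww), abs(aaw), abs(aaaa)) < 1e-3

    def test_components_sigmoid_midpoint(self, default_potential):
        p = default_potential
        ww, aaw, aaaa = true_enthalpy_components(p.switch_center, p)
        assert (ww, aaw, aaaa) == pytest.approx((p.amp_ww / 2, p.amp_aaw / 2, p.amp_aaaa / 2))

    def test_component_at_four_widths(self):
        # amp * S(4) with amp = -20, frozen from the logistic closed form
        p = TruePotentialParams(amp_ww=-20.0)
        ww, _, _ = true_enthalpy_components(p.switch_center + 4 * p.switch_width, p)
        assert ww == pytest.approx(-19.640275800758169, rel=1e-12)

    @given(r=st.floats(min_value=0.5, max_value=3.2))
    @settings(max_examples=50, deadline=None)
    def test_entropy_identity_everywhere(self, r):
        """-T dS_true = G_true - dH_true holds identically at any r."""
        p = TruePotentialParams()
        lhs = true_minus_t_delta_s(r, p)
        assert lhs == (true_pmf(r, p) - true_enthalpy(r, p))

    def test_invalid_widths_rejected(self):
        with pytest.raises(InputError):
            TruePotentialParams(well_width=0.0)
        with pytest.raises(InputError):
            TruePotentialParams(noise_sd=-1.0)


class TestSampler:
    def test_harmonic_window_variance(self, flat_potential):
        """On a flat landscape the restrained coordinate is Gaussian with
        variance kT/k; the long-run sample variance must match within 2%."""
        dyn = LangevinParams(stride=100)
        w = sample_window(flat_potential, dyn, 2.0, 1000.0, 20_000_000, seed=42)
        expected = KB * 300.0 / 1000.0
        assert w.samples.var() == pytest.approx(expected, rel=0.02)

    def test_unbiased_flat_histogram_uniform(self, flat_potential):
        """Zero bias on a flat landscape samples the domain uniformly."""
        dyn = LangevinParams(
            diffusion_coeff=0.1, domain_min=1.0, domain_max=2.0, stride=1000
        )
        w = sample_window(flat_potential, dyn, 1.5, 0.0, 2_000_000, seed=7,
                          with_energies=False)
        counts, _ = np.histogram(w.samples, bins=10, range=(1.0, 2.0))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_same_seed_bitwise_identical(self, default_potential, default_dynamics):
        a = sample_window(default_potential, default_dynamics, 2.0, 1000.0, 50_000, seed=5)
        b = sample_window(default_potential, default_dynamics, 2.0, 1000.0, 50_000, seed=5)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.energies.e_ww, b.energies.e_ww)
        c = sample_window(default_potential, default_dynamics, 2.0, 1000.0, 50_000, seed=6)
        assert not np.array_equal(a.samples, c.samples)

    def test_energy_bookkeeping_exact(self, default_potential, default_dynamics):
        w = sample_window(default_potential, default_dynamics, 2.0, 1000.0, 20_000, seed=1)
        e = w.energies
        assert np.array_equal(e.e_total, e.e_ww + e.e_aaw + e.e_aaaa)

    def test_energy_means_follow_switch(self, default_potential, default_dynamics):
        w = sample_window(default_potential, default_dynamics, 2.5, 1000.0, 2_000_000, seed=3)
        truth = default_potential.amp_ww * switch(w.samples, default_potential).mean()
        se = default_potential.noise_sd / np.sqrt(w.n_frames)
        assert w.energies.e_ww.mean() == pytest.approx(truth, abs=3 * se)

    def test_unstable_configuration_rejected(self, default_potential):
        dyn = LangevinParams(timestep=10.0)
        with pytest.raises(ConfigurationError):
            sample_window(default_potential, dyn, 2.0, 1000.0, 100, seed=1)
        with pytest.raises(ConfigurationError):
            check_stability(default_potential, dyn)

    def test_invalid_langevin_params(self):
        with pytest.raises(InputError):
            LangevinParams(domain_min=2.0, domain_max=1.0)
        with pytest.raises(InputError):
            LangevinParams(stride=0)


class TestDensitySnapshots:
    def test_profile_matches_generating_tanh(self):
        """Empirical binned profile vs the generating rho(z), Poisson errors."""
        bulk = 33.0
        box = (3.0, 3.0, 6.0)
        snaps = make_density_snapshots(3.0, 2.0, 0.3, bulk, box, 200, seed=11)
        zs = np.concatenate([s.positions[:, 2] for s in snaps])
        edges = np.arange(0.0, 6.0001, 0.1)
        counts, _ = np.histogram(zs, bins=edges)
        mid = 0.5 * (edges[:-1] + edges[1:])
        rho = bulk * 0.5 * (1.0 - np.tanh((np.abs(mid - 3.0) - 2.0) / 0.3))
        expected = rho * box[0] * box[1] * np.diff(edges) * len(snaps)
        sigma = np.sqrt(np.maximum(expected, 1.0))
        z = np.abs(counts - expected) / sigma
        # per-bin 3-sigma check with the usual finite-sample allowance
        assert np.mean(z < 3.0) >= 0.99
        assert np.all(z < 5.0)

    def test_half_bulk_at_gds(self):
        snaps = make_density_snapshots(3.0, 2.0, 0.05, 50.0, (4.0, 4.0, 6.0), 400, seed=2)
        zs = np.concatenate([s.positions[:, 2] for s in snaps])
        # density in a thin shell at |z - center| = gds should be bulk/2
        shell = np.sum(np.abs(np.abs(zs - 3.0) - 2.0) < 0.01)
        expected = 50.0 / 2 * 16.0 * 0.04 * 400  # two shells of width 0.02
        assert shell == pytest.approx(expected, rel=0.1)

    def test_narrow_interface_is_step(self):
        snaps = make_density_snapshots(3.0, 1.5, 0.01, 40.0, (3.0, 3.0, 6.0), 50, seed=3)
        zs = np.concatenate([s.positions[:, 2] for s in snaps])
        inside = np.sum(np.abs(zs - 3.0) < 1.4)
        outside = np.sum(np.abs(zs - 3.0) > 1.6)
        assert outside < 0.001 * inside

    def test_box_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            make_density_snapshots(3.0, 4.0, 0.3, 33.0, (3.0, 3.0, 6.0), 1, seed=0)


class TestHBondFixture:
    @pytest.mark.parametrize("vertex", ["hydrogen", "donor"])
    def test_roundtrip_100_random_geometries(self, vertex):
        rng = np.random.default_rng(99)
        geoms = [
            (float(d), float(a))
            for d, a in zip(rng.uniform(0.15, 0.45, 100), rng.uniform(0.0, 120.0, 100))
        ]
        snap = make_hbond_fixture(geoms, seed=4, angle_vertex=vertex)
        meas = measure_hbond_geometries(snap, angle_vertex=vertex)
        for (d_req, a_req), (d_got, a_got) in zip(geoms, meas):
            assert d_got == pytest.approx(d_req, abs=1e-6)
            assert a_got == pytest.approx(a_req, abs=1e-4)

    def test_ideal_geometries_roundtrip(self):
        snap = make_hbond_fixture([(0.28, 0.0), (0.40, 0.0)], seed=1)
        meas = measure_hbond_geometries(snap)
        assert meas[0][0] == pytest.approx(0.28, abs=1e-9)
        assert meas[1][0] == pytest.approx(0.40, abs=1e-9)
        assert abs(meas[0][1]) < 1e-5

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(InputError):
            make_hbond_fixture([(0.05, 0.0)], seed=1)
        with pytest.raises(InputError):
            make_hbond_fixture([(0.3, 200.0)], seed=1)


class TestOrientationFixture:
    def test_aligned_and_planar(self):
        v = make_orientation_fixture("aligned", 10, seed=0)
        assert np.allclose(v[:, 2], 1.0)
        v = make_orientation_fixture("planar", 10, seed=0)
        assert np.allclose(v[:, 2], 0.0)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0)

    def test_isotropic_cos_theta_uniform(self):
        """cos(theta) of directions uniform on the sphere is uniform on [-1, 1]."""
        v = make_orientation_fixture("isotropic", 100_000, seed=12)
        counts, _ = np.histogram(v[:, 2], bins=20, range=(-1, 1))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_unknown_mode_rejected(self):
        with pytest.raises(InputError):
            make_orientation_fixture("radial", 5, seed=0)
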