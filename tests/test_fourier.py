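"""Spectral representation: phase doubling, truncation, reconstruction, synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import v1maps as v
from v1maps import fourier
from v1maps.fourier import (
    EnvelopeSpec,
    apply_phase_doubling,
    decompose,
    decompose_od,
    decompose_op,
    dominant_modes,
    envelope_magnitude,
    mode_wavevector,
    preprocess_external_map,
    reconstruct_od,
    reconstruct_op,
    synthesize_annulus_map,
    synthesize_irregular_map,
    truncate_modes,
)
from v1maps.grid import lattice_grid
from v1maps.pinwheels import (
    anisotropy_index,
    detect_pinwheels,
    gradient_coherence,
    neighbor_sign_fraction,
    od_alignment,
)


class TestPhaseDoubling:
    @pytest.mark.parametrize("phi,expected", [(0.0, 1 + 0j), (90.0, -1 + 0j), (45.0, 1j)])
    def test_reference_angles(self, phi, expected, hypercolumn):
        grid = hypercolumn.grid
        z = apply_phase_doubling(v.OPMap(grid=grid, values=np.full((grid.ny, grid.nx), phi)))
        assert z[0, 0] == pytest.approx(expected)

    def test_unit_modulus(self, hypercolumn):
        z = apply_phase_doubling(hypercolumn)
        assert np.allclose(np.abs(z), 1.0)


class TestDecompose:
    def test_od_has_two_dominant_modes_at_stripe_frequency(self, lattice5_coarse):
        spec = decompose_od(lattice5_coarse.od)
        modes = dominant_modes(spec, 0.1)
        assert len(modes) == 2
        kvecs = sorted(mode_wavevector(spec, m) for m in modes)
        K = np.pi / lattice5_coarse.grid.a
        assert kvecs[0] == pytest.approx((-K, 0.0), abs=1e-9)
        assert kvecs[1] == pytest.approx((K, 0.0), abs=1e-9)

    def test_op_has_four_dominant_modes_with_fourfold_symmetry(self, lattice5_coarse):
        spec = decompose_op(lattice5_coarse.op)
        modes = dominant_modes(spec, 0.5)
        assert len(modes) == 4
        K = np.pi / lattice5_coarse.grid.a
        got = {tuple(np.round(mode_wavevector(spec, m), 9)) for m in modes}
        want = {(K, 0.0), (-K, 0.0), (0.0, K), (0.0, -K)}
        assert {(round(a, 6), round(b, 6)) for a, b in got} == {
            (round(a, 6), round(b, 6)) for a, b in want
        }

    def test_parseval(self, lattice5_coarse):
        z = apply_phase_doubling(lattice5_coarse.op)
        spec = decompose_op(lattice5_coarse.op)
        lhs = np.sum(np.abs(z) ** 2)
        rhs = np.sum(np.abs(spec.coeffs) ** 2) / z.size
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_arrangement_spectra_share_magnitudes(self):
        m1 = decompose_op(v.tile_lattice(2, 2, dx=0.025, arrangement="I").op).magnitude
        m2 = decompose_op(v.tile_lattice(2, 2, dx=0.025, arrangement="II").op).magnitude
        assert np.allclose(m1, m2, atol=1e-6 * m1.max())


class TestTruncation:
    def test_top2_od_keeps_the_stripe_pair(self, lattice5_coarse):
        spec = decompose_od(lattice5_coarse.od)
        trunc = truncate_modes(spec, top_n=2)
        K = np.pi / lattice5_coarse.grid.a
        kept = sorted(mode_wavevector(trunc, m) for m in trunc.selection)
        assert kept[0] == pytest.approx((-K, 0.0), abs=1e-9)
        assert kept[1] == pytest.approx((K, 0.0), abs=1e-9)

    def test_threshold_and_topn_selectors_agree(self, lattice5_coarse):
        spec = decompose_op(lattice5_coarse.op)
        t1 = truncate_modes(spec, top_n=4)
        t2 = truncate_modes(spec, threshold_frac=0.5)
        assert t1.selection == t2.selection

    def test_selecting_everything_is_identity_up_to_dc(self, lattice5_coarse):
        spec = decompose_op(lattice5_coarse.op)
        every = [
            (iy, ix)
            for iy in range(len(spec.ky))
            for ix in range(len(spec.kx))
            if (iy, ix) != spec.dc_index()
        ]
        full = truncate_modes(spec, explicit=every)
        rec = reconstruct_op(full)
        # the phase-doubled lattice has essentially no DC mass, so the
        # reconstruction round-trips
        err = v.circular_op_difference(lattice5_coarse.op, rec)
        assert err.max() < 1e-6

    def test_empty_selection_rejected(self, lattice5_coarse):
        spec = decompose_od(lattice5_coarse.od)
        with pytest.raises(ValueError, match="empty"):
            truncate_modes(spec, explicit=[spec.dc_index()])


class TestReconstruction:
    def test_full_spectrum_round_trip(self, lattice5_coarse):
        rec = reconstruct_op(decompose_op(lattice5_coarse.op))
        assert v.circular_op_difference(lattice5_coarse.op, rec).max() < 1e-8

    def test_two_mode_od_reconstruction_exact(self, lattice5_coarse):
        spec = decompose_od(lattice5_coarse.od)
        rec = reconstruct_od(truncate_modes(spec, top_n=2))
        assert np.abs(rec.values - lattice5_coarse.od.values).max() < 1e-8

    def test_four_mode_op_reconstruction_error(self, lattice5_coarse):
        spec = decompose_op(lattice5_coarse.op)
        rec = reconstruct_op(truncate_modes(spec, top_n=4))
        err = v.circular_op_difference(lattice5_coarse.op, rec)
        assert 3.0 < err.max() < 6.0

    def test_error_shrinks_as_modes_are_added(self, lattice5_coarse):
        # Parseval: the L2 residual of the phase-doubled field equals the
        # omitted spectral energy, so it decreases (weakly) as modes are
        # added in descending magnitude order
        spec = decompose_op(lattice5_coarse.op)
        z = apply_phase_doubling(lattice5_coarse.op)
        errs = []
        for n in (4, 8, 16, 64, 256):
            trunc = truncate_modes(spec, top_n=n)
            z_rec = fourier.inverse_transform(trunc)
            errs.append(np.sqrt(np.mean(np.abs(z_rec - z) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))


class TestEnvelope:
    def test_unit_at_lobe_centre(self):
        env = EnvelopeSpec(k0=np.pi)
        assert envelope_magnitude(np.pi, 0.0, env) == pytest.approx(1.0)

    def test_one_sigma_falloff_radial_and_azimuthal(self):
        env = EnvelopeSpec(k0=np.pi, delta_theta=20.0)
        radial = envelope_magnitude(np.pi + env.dk, 0.0, env)
        assert radial == pytest.approx(np.exp(-0.5), abs=1e-9)
        th = np.deg2rad(20.0)
        azim = envelope_magnitude(np.pi * np.cos(th), np.pi * np.sin(th), env)
        assert azim == pytest.approx(np.exp(-0.5), abs=1e-6)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=50, derandomize=True)
    def test_bounded_by_one(self, kx, ky):
        env = EnvelopeSpec(k0=np.pi)
        assert 0.0 <= envelope_magnitude(kx, ky, env) <= 1.0 + 1e-12


class TestIrregularSynthesis:
    def test_deterministic_for_fixed_seed(self):
        g = lattice_grid(3, 3, dx=0.05)
        a = synthesize_irregular_map(g, seed=11)
        b = synthesize_irregular_map(g, seed=11)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_narrow_envelope_limit_recovers_lattice_modes(self):
        g = lattice_grid(5, 5, dx=0.05)
        op, od, spec, _ = synthesize_irregular_map(g, seed=3, delta_k=1e-6, delta_theta=1e-6)
        modes = dominant_modes(spec, 0.5)
        assert len(modes) == 4
        K = np.pi / g.a
        assert {tuple(np.round(np.abs(mode_wavevector(spec, m)), 6)) for m in modes} == {
            (round(K, 6), 0.0), (0.0, round(K, 6))
        }
        pins = detect_pinwheels(op)
        assert len(pins) == 100
        assert neighbor_sign_fraction(pins) == 1.0

    def test_pinwheel_statistics_across_seeds(self):
        """Most nearest-neighbour pinwheel pairs have opposite signs, and
        centres sit preferentially on OD stripe mid-lines."""
        g = lattice_grid(5, 5, dx=0.05)
        fracs, aligns = [], []
        for seed in range(20):
            op, od, _, _ = synthesize_irregular_map(g, seed=seed)
            pins = detect_pinwheels(op)
            fracs.append(neighbor_sign_fraction(pins))
            aligns.append(od_alignment(pins, od.values, g))
        assert min(fracs) > 0.7
        assert min(aligns) > 1.15

    def test_od_field_is_real_and_bounded(self):
        g = lattice_grid(3, 3, dx=0.05)
        _, od, _, spec_od = synthesize_irregular_map(g, seed=2)
        assert np.abs(od.values).max() <= 1.0 + 1e-12
        # Hermitian spectrum
        from v1maps.fourier import _conjugate_reflect

        assert np.allclose(spec_od.coeffs, _conjugate_reflect(spec_od.coeffs), atol=1e-9)


@pytest.fixture(scope="module")
def annulus():
    g = lattice_grid(5, 5, dx=0.05)
    return synthesize_annulus_map(g, seed=1)


class TestAnnulus:

    def test_spectrum_nearly_isotropic(self, annulus):
        op, od, spec = annulus
        k0 = np.pi / spec.grid.a
        ai = anisotropy_index(np.abs(spec.coeffs), spec.kx, spec.ky, k0)
        reg = decompose_op(v.tile_lattice(5, 5, dx=0.05).op)
        ai_reg = anisotropy_index(np.abs(reg.coeffs), reg.kx, reg.ky, k0)
        assert ai < 0.5
        assert ai_reg > 2.0

    def test_azimuthal_envelope_variation_small(self, annulus):
        # the target magnitude (the envelope) is azimuth flat on the ring;
        # realized coefficients fluctuate only through the random phases
        _, _, spec = annulus
        k0 = np.pi / spec.grid.a
        env = EnvelopeSpec(k0=k0, theta0=(0.0,), delta_theta=1e9)
        theta = np.linspace(0, 2 * np.pi, 73)
        mags = envelope_magnitude(k0 * np.cos(theta), k0 * np.sin(theta), env)
        assert (mags.max() - mags.min()) / mags.max() < 0.1

    def test_map_remains_locally_anisotropic(self, annulus):
        op, _, _ = annulus
        assert gradient_coherence(op) > 0.3


class TestExternalPreprocessing:
    def test_pad_region_zero_and_window_applied(self, lattice5_coarse):
        field, grid = preprocess_external_map(lattice5_coarse.op, pad_factor=2)
        ny, nx = lattice5_coarse.op.values.shape
        assert field.shape == (2 * ny, 2 * nx)
        assert np.all(field[: ny // 2, :] == 0)
        assert np.all(field[:, : nx // 2] == 0)

    def test_dominant_modes_survive_windowing(self, lattice5_coarse):
        field, grid = preprocess_external_map(lattice5_coarse.op, pad_factor=2)
        spec = decompose(field, grid, source="op_phase_doubled")
        modes = dominant_modes(spec, 0.5)
        K = np.pi / grid.a
        kv = np.array([mode_wavevector(spec, m) for m in modes])
        r = np.hypot(kv[:, 0], kv[:, 1])
        assert len(modes) >= 4
        assert np.allclose(r, K, rtol=0.15)
        # four-fold angular placement near the axes
        theta = np.degrees(np.arctan2(kv[:, 1], kv[:, 0])) % 90.0
        assert np.all((theta < 10) | (theta > 80))

    def test_no_window_no_pad_reduces_to_plain_transform(self, lattice5_coarse):
        field, grid = preprocess_external_map(
            lattice5_coarse.op, pad_factor=1, window_sigma=np.inf
        )
        direct = apply_phase_doubling(lattice5_coarse.op)
        assert np.allclose(field, direct)
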