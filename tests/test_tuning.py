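"""Bar stimuli, tuning curves, FWHM extraction, and the parameter sweep."""

import numpy as np
import pytest

import v1maps as v
from v1maps.grid import GridConfigError, GridSpec
from v1maps.tuning import (
    BarStimulusParams,
    FlatCurveError,
    TuningCurve,
    bar_field,
    default_angles,
    fwhm,
    make_bar_stimulus,
    orientation_tuning,
    response_field,
    sweep_fwhm,
    tuning_curve,
)


def _stim_grid(n=161, dx=0.0125):
    return GridSpec(nx=n, ny=n, dx=dx, a=n * dx / 2, origin=(-n * dx / 2, -n * dx / 2))


class TestBarStimulus:
    def test_orientation_is_180_periodic(self):
        grid = _stim_grid()
        s1 = make_bar_stimulus(grid, 30.0, (0.0, 0.0), BarStimulusParams(length=0.6))
        s2 = make_bar_stimulus(grid, 210.0, (0.0, 0.0), BarStimulusParams(length=0.6))
        assert np.allclose(s1.values, s2.values)

    def test_integral_scales_with_amplitude(self):
        grid = _stim_grid()
        p1 = BarStimulusParams(length=0.6, amplitude=1.0)
        p3 = BarStimulusParams(length=0.6, amplitude=3.0)
        s1 = make_bar_stimulus(grid, 70.0, (0.0, 0.0), p1)
        s3 = make_bar_stimulus(grid, 70.0, (0.0, 0.0), p3)
        assert s3.values.sum() == pytest.approx(3.0 * s1.values.sum())

    def test_support_exceeding_grid_rejected(self):
        grid = _stim_grid(n=41)
        with pytest.raises(GridConfigError, match="exceeds"):
            make_bar_stimulus(grid, 0.0, (0.0, 0.0), BarStimulusParams(length=1.2))

    def test_wide_blob_gives_flat_response(self, default_al, default_rf):
        """A stimulus much larger than the kernel support in both
        dimensions drives no orientation modulation."""
        blob = BarStimulusParams(length=40.0, width=25.0)
        thin = BarStimulusParams()
        c_blob = orientation_tuning(45.0, default_al, default_rf, stim=blob)
        c_thin = orientation_tuning(45.0, default_al, default_rf, stim=thin)
        modulation = c_blob.responses.max() - c_blob.responses.min()
        assert modulation < 0.01 * c_thin.responses.max()


class TestResponseField:
    def test_uniform_stimulus_annihilated(self, lattice5_coarse, default_al, default_rf):
        grid = lattice5_coarse.grid
        stim = v.make_bar_stimulus(grid, 0.0, (0.0, 0.0), BarStimulusParams(length=0.6))
        uniform = v.BarStimulus(
            grid=grid, theta=0.0, center=(0, 0), params=stim.params,
            values=np.ones((grid.ny, grid.nx)),
        )
        out = response_field(uniform, lattice5_coarse.op, default_al, default_rf)
        interior = out[40:-40, 40:-40]
        stim_out = response_field(stim, lattice5_coarse.op, default_al, default_rf)
        # residual bounded by the kernel's truncated tail mass (~1e-4)
        assert np.abs(interior).max() < 5e-3 * np.abs(stim_out).max()

    def test_matches_direct_spatial_convolution(self, default_al, default_rf):
        """FFT evaluation equals a brute-force spatial convolution."""
        n, dx = 64, 0.05
        grid = GridSpec(nx=n, ny=n, dx=dx, a=n * dx / 2, origin=(-n * dx / 2, -n * dx / 2))
        op = v.OPMap(grid=grid, values=np.full((n, n), 77.0))
        stim = make_bar_stimulus(grid, 40.0, (0.0, 0.0), BarStimulusParams(length=0.6))
        out = response_field(stim, op, default_al, default_rf)
        k = v.combined_kernel(default_al.with_phi(77.0), default_rf.with_phi(77.0), dx=dx)
        h = k.half_width
        iy, ix = n // 2, n // 2
        # brute-force sum over the kernel support at the central pixel
        acc = 0.0
        for jy in range(k.values.shape[0]):
            for jx in range(k.values.shape[1]):
                sy, sx = iy + (jy - h), ix + (jx - h)
                if 0 <= sy < n and 0 <= sx < n:
                    acc += k.values[jy, jx] * stim.values[sy, sx]
        assert out[iy, ix] == pytest.approx(acc * dx * dx, rel=1e-6)

    def test_rotational_covariance_at_90_degrees(self, default_al, default_rf):
        """Rotating map and stimulus together rotates the response field."""
        n, dx = 80, 0.025
        grid = GridSpec(nx=n, ny=n, dx=dx, a=n * dx / 2, origin=(-n * dx / 2, -n * dx / 2))
        rng = np.random.default_rng(1)
        phis = rng.uniform(0, 180, size=(n, n))
        op = v.OPMap(grid=grid, values=phis)
        stim = make_bar_stimulus(grid, 25.0, (0.1, -0.2), BarStimulusParams(length=0.6))
        out = response_field(stim, op, default_al, default_rf)
        op_rot = v.OPMap(grid=grid, values=(np.rot90(phis) + 90.0) % 180.0)
        stim_rot = v.BarStimulus(
            grid=grid, theta=stim.theta, center=stim.center, params=stim.params,
            values=np.rot90(stim.values),
        )
        out_rot = response_field(stim_rot, op_rot, default_al, default_rf)
        assert np.allclose(out_rot, np.rot90(out), atol=1e-9 * np.abs(out).max())


class TestTuningCurve:
    def test_peak_at_local_preferred_orientation(self, lattice3, default_al, default_rf):
        site = v.find_iso_orientation_site(lattice3)
        curve = tuning_curve(site, lattice3.op, default_al, default_rf)
        phi0 = lattice3.op.angle_at(*site)
        d = abs(curve.peak_angle - phi0) % 180
        assert min(d, 180 - d) <= 1.0

    def test_margin_violation_rejected(self, lattice3, default_al, default_rf):
        with pytest.raises(GridConfigError, match="edge"):
            tuning_curve((-0.99, 0.0), lattice3.op, default_al, default_rf)

    def test_family_over_al_ratio_nearly_coincides(self):
        """Normalized curves for b2/a2 in {1, 2, 10, 20, 100} at aspect 2.5
        form a near-coincident family."""
        rf = v.RFParams.from_aspect(2.5)
        curves = [
            orientation_tuning(45.0, v.ALParams.from_ratio(r), rf).normalize().responses
            for r in (1.0, 2.0, 10.0, 20.0, 100.0)
        ]
        spread = np.max([np.abs(c - curves[0]).max() for c in curves[1:]])
        assert spread < 0.05

    def test_curves_translate_across_preferred_angles(self, default_al, default_rf):
        base = orientation_tuning(0.0, default_al, default_rf).normalize()
        for phi in (30.0, 60.0, 90.0, 120.0, 150.0):
            c = orientation_tuning(phi, default_al, default_rf).normalize()
            shifted = np.interp(
                (c.angles - phi) % 180.0, base.angles, base.responses, period=180.0
            )
            rms = np.sqrt(np.mean((c.responses - shifted) ** 2))
            assert rms < 0.02

    def test_fwhm_invariant_under_stimulus_amplitude(self, default_al, default_rf):
        f1 = fwhm(orientation_tuning(10.0, default_al, default_rf,
                                     stim=BarStimulusParams(amplitude=1.0)))
        f2 = fwhm(orientation_tuning(10.0, default_al, default_rf,
                                     stim=BarStimulusParams(amplitude=250.0)))
        assert f1 == pytest.approx(f2, abs=1e-9)


class TestFWHM:
    def test_triangular_curve(self):
        ang = default_angles()
        resp = 1.0 - np.abs(ang - 90.0) / 90.0
        assert fwhm(TuningCurve(angles=ang, responses=resp)) == pytest.approx(90.0)

    def test_von_mises_closed_form(self):
        """Numerical extraction on a sampled von Mises curve matches the
        analytic width of the baseline-subtracted bump to 0.1 deg."""
        ang = np.arange(0.0, 180.0, 0.2)
        for kappa in (1.0, 2.0, 5.0):
            resp = np.exp(kappa * (np.cos(2 * np.deg2rad(ang - 90.0)) - 1.0))
            # affine normalization: half maximum at (1 + min)/2 of the raw curve
            m = np.exp(-2.0 * kappa)
            expected = np.degrees(np.arccos(1.0 + np.log((1.0 + m) / 2.0) / kappa))
            got = fwhm(TuningCurve(angles=ang, responses=resp))
            assert got == pytest.approx(expected, abs=0.1)

    def test_flat_curve_rejected(self):
        ang = default_angles()
        with pytest.raises(FlatCurveError):
            fwhm(TuningCurve(angles=ang, responses=np.ones_like(ang)))

    def test_wraparound_peak_near_zero(self):
        ang = default_angles()
        resp = np.exp(2.0 * (np.cos(2 * np.deg2rad(ang - 2.0)) - 1.0))
        assert fwhm(TuningCurve(angles=ang, responses=resp)) == pytest.approx(
            fwhm(TuningCurve(angles=ang, responses=np.roll(resp, 90))), abs=0.2
        )


class TestSweep:
    def test_consistent_with_individual_curves(self, default_rf):
        m = sweep_fwhm([1.0], [2.0, 3.0])
        f = fwhm(orientation_tuning(135.0, v.ALParams.from_ratio(1.0, phi=135.0),
                                    v.RFParams.from_aspect(3.0, phi=135.0)))
        assert m[0, 1] == pytest.approx(f, abs=1e-9)

    def test_fwhm_decreases_with_rf_elongation(self):
        m = sweep_fwhm([1.0, 5.0], [1.5, 2.5, 4.0, 6.5])
        assert np.all(np.diff(m, axis=1) < 0)
        # the aspect axis dominates: > 30 deg swing across the Fig-7 range
        assert m[0, 0] - m[0, -1] > 30.0
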