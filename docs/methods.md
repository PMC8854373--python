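# Methods

This note records the model, its conventions, the parameter defaults and
why they were chosen, the numerical choices, and the limits of what the
synthetic maps can show.

## Geometry and conventions

All fields live on uniform square-pixel grids in millimetres of cortex.
Pixel (ix, iy) is centred at `origin + (ix + 0.5, iy + 0.5)·dx`; the
half-pixel offset keeps pinwheel singularities (which fall on
half-integer multiples of the hypercolumn half-width `a`) off the sample
points, so no map pixel ever needs a singular value. Angles cross module
boundaries in degrees; OP values live in [0°, 180°); y increases with
the row index. Wavenumbers are angular (rad/mm) on fftshift-centred
axes.

Defaults: `a = 1 mm` (OD stripe width ≈ 1 mm, the upper end of the
mammalian 0.5–1 mm range) and `dx = 0.0125 mm`, i.e. 160 px per
hypercolumn. This resolves the σy = 0.09 mm kernel short axis with 7 px
and was the coarsest pitch at which the tuning and reconstruction
results below stop moving at the 0.1° level; analyses that only need
map topology (pinwheel statistics, spectra) use `dx = 0.025–0.05 mm`.

## The idealized OP–OD map

OD is a unit sinusoid `Ω = sin(ux + vy)` with wavevector magnitude π/a
along the stripe normal (stripe angle ξ, default 90°: vertical stripes;
borders at Ω = 0, monocular mid-lines at Ω = ±1). The hypercolumn OP map
puts a half-polar-angle pinwheel, `φ = ½·atan2(y − y₀, x − x₀)` mapped
to [0°, 180°), at the centre of the top-right quadrant; the other three
quadrants are its mirror images across the coordinate axes. Mirroring
(a) keeps φ continuous across the quadrant seams and across the
periodic hypercolumn border, and (b) reverses the winding, so charges
alternate in a checkerboard: a full circuit of any centre sweeps
orientation exactly once (topological charge ±1 on the doubled angle),
and the four centres land on the OD mid-lines. `atan2` replaces a
branch-by-branch quadrant definition; the two agree wherever both are
defined. Arrangement II (the variant with left/right OD columns
swapped) is a half-period roll of arrangement I and shares its spectrum
magnitude; arrangement I is used throughout.

The pinwheel detector sums wrapped differences of 2φ around each 2×2
plaquette; plaquettes enclosing a singularity score ±360°, everything
else 0°, which localizes centres to one pixel and yields signs without
thresholds.

One idealization to keep in mind: the azimuthal distribution of
orientations around a *square* quadrant is not uniform (the corner
directions hold ~2× the area of the axis directions), so OP histograms
over a hypercolumn show a smooth factor-≤2 modulation even though all
orientations are fully covered. Tests assert coverage and a bounded
modulation, not strict uniformity.

## The combined orientation operator

`P = a²∂²/∂x′² + b²∂²/∂y′²` in the frame rotated to the preferred
orientation, with the unit-sum parameterization a² = sin²ψ, b² = cos²ψ
(so b²/a² ≥ 1 for ψ ∈ [0, π/4]). The RF weight G is an anisotropic
Gaussian (σx = 0.18 mm; σx fixed by the ~0.56 mm cortical size of a
0.082° parafoveal RF under M = 12/(E + 0.75) mm/deg, the ~30°
half-width constraint on tuning, and the 0.18–0.3 mm axonal range).
P{G} is evaluated in closed form — second derivatives of the rotated
Gaussian — rather than by numerically differentiating a sampled G; a
finite-difference version survives only as a test oracle. The default
support is ±4σx, where the truncated tail (~1e−4 of the L1 mass) is the
floor for every "integrates to zero" statement; property tests that
need the analytic zero use a ±7σx support.

Sign: as written, the operator gives a negative central lobe. The
package returns the kernel with the opposite sign — ON centre, OFF
flanks — matching how receptive fields are plotted and making "response
to an aligned bright bar" positive. Amplitude is arbitrary throughout;
every downstream quantity is normalization invariant.

## Stimuli, tuning curves, and widths

The probe stimulus is a smooth bar: a logistic plateau (half-length
L/2, edge scale = width/2) along the axis times a Gaussian cross
profile (sd = width/2). Defaults: length 1.2 mm, width 0.05 mm,
amplitude 1. The length spans the full RF envelope (~6.7σx, about twice
the 0.56 mm cortical RF size), as experimental bars and gratings extend
beyond the classical RF; the width is one OP microcolumn, thin against
the 0.1 mm flank spacing of the kernel. The tuning curve records the
raw linear response at the measurement point for bar orientations
0–180° in 1° steps.

Curves are normalized affinely — baseline (minimum) subtracted, peak
scaled to 1 — and FWHM is read off the normalized curve by linear
interpolation, outermost crossings, on the circular domain. This is the
convention under which experimental tuning curves are fitted with a von
Mises bump on a baseline. It matters: the model's response to a bar
never falls to zero at 90° off-peak (the residual is ~12% of peak at
aspect 2), and measuring the width of the bump *above that baseline* is
what reproduces the calibrated 45° width at σx/σy = 2 — a plain
rectified peak-normalized readout has a floor of ~53° there for any bar
geometry (infinite-thin-bar closed form: response ∝ (σx²sin²α +
σy²cos²α)^{−3/2}). With these defaults the package computes 47.8° at
aspect 2, a 1.1° drop from b²/a² = 1 to 5 at aspect 2.5, and a total
variation below 1.5° over b²/a² ∈ [1, 100] — the anisotropy of the
Laplacian is immaterial next to the RF elongation, which moves the
width by ~45° over aspects 1.5–6.5.

## Measurement-site pooling

Pooled responses follow `I_w(r₀) = ∫ I(r) W(r − r₀) dr` with W either a
unit-mass Gaussian or the zero-integral Mexican hat
`(1 − d²/2σr²)e^{−d²/2σr²}`, both with σr = 40 μm (one OP microcolumn);
the same σr serves both profiles. Windows span ±4σr; the discrete
Gaussian is renormalized to unit mass (so pooling a constant returns
it exactly), the Mexican hat is left as sampled. Because pooling is
linear, the pooled curve is the response of one *effective kernel* —
the site-weighted sum of the local kernels over the window, with local
orientations quantized to a 1° kernel bank — built once per site; this
makes distance profiles cheap and is exactly equal to averaging the
per-pixel curves. Normalization/rectification happens only at the final
readout.

A structural consequence worth stating: a weighted average of linear
responses is a mixture of the constituent single-site curves, and a
mixture of translates is never narrower than its sharpest constituent.
Pooling therefore *broadens* tuning everywhere — mildly in
iso-orientation domains (the package computes ~51.6° against the
single-site 47.8°), strongly at pinwheel centres (~85°, a 1.65× ratio),
where neurons of all preferences are averaged while each individual
neuron stays as sharp as in a domain. Published pooled widths narrower
than the single-site calibration width cannot arise in this linear
model under any stimulus geometry, site position, or σr.

Distance profiles run from a pinwheel centre along the quadrant
diagonal (toward the hypercolumn centre, away from OD borders), 0–200
μm in 10 μm steps by default. Gaussian pooling gives monotone profiles
(HWHM falling ~43°→27°, strength rising); the exact-centre sample is
delicate (the pooled modulation there is small and shaped by the bar's
radial geometry, producing a ~1° wobble in the first step). Mexican-hat
pooling reproduces the overshoot in strength (~12% above its settled
value near 140 μm) and a shallow dip in HWHM before both settle.
"Strength" is the peak of the raw pooled curve, in arbitrary units.

## Spectral representation and synthesis

Phase doubling `z = e^{i2φ}` makes the circular variable continuous;
spectra are plain FFTs with physical axes. The DC coefficient is
excluded from dominant-mode selection and zeroed in truncation (the
phase-doubled lattice has essentially no mean; dominance thresholds
default to 50% of the non-DC maximum for OP, 10% for OD, both
parameters). Truncations of OD (real source) spectra are symmetrized so
k and −k survive together. Angle recovery is the half argument of the
inverse transform, with near-zero-modulus pixels (none arise in
practice) filled from their nearest valid neighbour. On the default
grid the 4-mode reconstruction of the 5×5 lattice errs by at most 4.25°
(2.9° at dx = 0.05, 4.3° in the fine-grid limit), concentrated at the
pinwheel edges; the 2-mode OD reconstruction is exact because the
stripes are a pure sinusoid.

Irregular maps generalize the lattice's exact mode structure, measured
first on the ideal case: the phase-doubled lattice is `z = F(x) +
i·F(y)` with F a real stripe wave — its left/right lobe pair is
internally Hermitian, the top/bottom pair is the left/right pair
rotated 90° times i, and the OD lobes are the left/right lobes advanced
90° in phase (quadrature), which is what pins pinwheel centres to the
OD mid-lines. The synthesis draws random phases for the right lobe
under the Gaussian envelope `M_k = exp(−(|k|−K₀)²/2ΔK²)·
exp(−ΔΘ(k)²/2ΔΘ²)` (K₀ = π/a, ΔK = K₀/2, ΔΘ = 20°), Hermitian-extends
to get a real F, and builds z and Ω by the same three relations. In the
ΔK, ΔΘ → 0 limit this reproduces a regular lattice up to translation;
at the defaults, over 20 seeds, ≥ 89% of nearest-neighbour pinwheel
pairs have opposite signs and the mean |Ω| at centres is ~1.5× the map
mean (1.57 = 1/(2/π) would be exactly on the mid-lines). The
wide-azimuth limit of the same construction gives the annulus spectrum:
azimuthally flat target magnitude, realized coefficients fluctuating
only through phase interference; its maps have no preferred stripe
direction (azimuthal power CV ~0.3 vs > 2 for the lattice) yet remain
locally anisotropic (structure-tensor coherence ~0.7).

External maps are prepared by phase doubling, a centred Gaussian window
(default sigma = ¼ of the smaller map dimension), and zero padding to
double the linear size, which suppresses the wrap-around seam of the
DFT at the cost of convolving the spectrum with the window transform.

## What the synthetic maps do and do not show

The generators produce straight, parallel OD stripes, square pinwheel
lattices, and sinusoidal OD profiles. Real maps have curved, branching
stripes, variable pinwheel density, and anisotropies tied to
retinotopy; none of that is modelled, so passing tests show that the
*operators and representations* behave correctly on maps with the
idealized local structure, not that they characterize any particular
animal's map. The spectral tools (decomposition, truncation, windowed
preprocessing) accept arbitrary gridded OP maps and are the pieces
meant for measured data. Spiking nonlinearities, membrane-to-spike
sharpening, baseline activity, and direction-of-motion maps are out of
scope.

## Numerical choices

- Kernel bank quantization: 1° in local orientation (pooled-curve error
  well below the angle-grid resolution); angle sampling 1°, FWHM by
  linear interpolation with outermost-crossing tie-breaking.
- FWHM of curves with tied maxima uses the circular centroid of the
  peak set; flat curves raise an error rather than return a width.
- Problem sizes: tuning uses the kernel support only (~117² px);
  pooled analyses a 3×3-hypercolumn lattice at dx = 0.0125; spectral
  acceptance uses the 5×5 lattice at the default pitch (800² FFT);
  synthesis statistics use dx = 0.05 over 20 seeds.
- Determinism: every random draw flows from one integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical maps.
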