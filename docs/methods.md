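# Methods

This note documents the models, parameters and numerical choices behind
`aortiq`, and what the synthetic experiments do and do not demonstrate.

## Phantom and kinematics

The phantom is a 2-D transverse AAA cross-section: a circular lumen
(default radius 10 mm at 45 mm depth), a wall of uniform 2 mm thickness,
optionally an intraluminal thrombus (ILT) layer between a lumen border
and the wall, and diffuse background. Point scatterers are drawn
uniformly over the field (default 4 /mm² on a 40×40 mm field) with
Rayleigh-type amplitudes — |N(0,1)| scaled by region echogenicity
(lumen 0.02, ILT 0.25, wall 1.0, background 0.5). The echogenicity
ordering lumen < ILT < wall is enforced.

Wall motion is plane-strain incompressible: a material point at radius
r maps to `r' = sqrt(r² + a'(t)² − a²)` where `a` is the wall's inner
radius and `a'(t) = a + Δa·p(t)`. Consequences used as test oracles:
annulus areas are conserved exactly, circumferential strain
`(r'−r)/r` decreases monotonically with r, and the lumen-border strain
equals `Δa·p/a`. The default `Δa = 0.19 mm` places the peak lumen-border
circumferential strain at 0.019, a typical anterior-wall value for
aneurysmal aortas (stiffer than healthy vessels); it is a design point
of the phantom, not a measurement.

The pressure waveform `p(t)` is a raised-cosine upstroke over the first
30% of the cycle followed by an exponential decay (rate 4 per remaining
cycle fraction), so one period contains two end-diastoles. The whole
cross-section additionally translates anteriorly by up to 0.3 mm
(`midpoint shift`), following the same waveform — the spine blocks
posterior expansion in vivo, so the centroid moves toward the probe.
This translation is strain-free by construction, which isolates the
midpoint-correction stage for testing. The optional ILT layer pulsates
more at the lumen border than the wall does (compliance ratio 3 by
default, linearly blended to the wall motion at the ILT/wall interface);
thrombus is much more compliant than aneurysm wall, and this
reproduces the larger-strain-near-the-lumen pattern without a full
mechanics solve. The ILT blend is not itself incompressible; the
incompressibility invariant applies to the wall-and-outward map.

## Acquisition model

Two convex arrays approximating abdominal C5-2v probes: 128 elements,
0.508 mm pitch, 49.57 mm curvature radius, 3.7 MHz centre frequency
(element count and pitch are configuration, not vendor data). Transmit
is a steered diverging wave: the virtual point source sits one curvature
radius behind the curvature centre along the steered axis; t = 0 is
referenced to the wavefront reaching the nearest element, which makes
the analytic delay identical to the earliest element-wise spherical
arrival (a brute-force test oracle). The full-scale protocol is 15
angles spanning ±12° per probe at 130 Hz frame rate in an interleaved
T1/T2 schedule; both probes receive on every event, giving the four
pathways per frame. A PRF guard (default 12 kHz) rejects impossible
schedules.

Scattering is linear and single: each receive trace is the sum of
Gaussian-modulated cosines (60% fractional bandwidth, sampled at 4×
the centre frequency) delayed by transmit + receive times of flight
with 1/r receive spreading. No attenuation, aberration, multiple
scattering or elevational dimension. Scatterers are sampled
frame-synchronously (one phantom state per frame shared by that frame's
steering angles).

Channel noise is additive white Gaussian at a configurable SNR relative
to the pathway's RMS signal. The default is **0 dB per channel**:
abdominal imaging of deep targets is clutter- and noise-limited, and
after beamforming gain (~24 dB over 48 elements × 5 angles) this puts
the image noise floor where it limits lumen–wall contrast, the regime
the method is designed for. At high channel SNR the contrast metric
saturates near 1 for any aperture configuration and stops being
informative; the noise level is part of the study conditions, set once.

## Beamforming and compounding

IQ demodulation mixes the RF down at the centre frequency (absolute
time reference) and low-passes with a zero-phase 4th-order Butterworth
at 0.3× Nyquist. DAS then sums, per pixel, the linearly interpolated IQ
samples at the two-way delay, phase-rotated by `exp(+i2πf₀τ)`, over
receive elements (Hann apodization within a depth/2f# aperture,
f-number 1.5) and steering angles. Single-probe pathways are
reconstructed on sector grids with apex at the probe's curvature
centre; the trans-probe pathways share a grid whose apex is a virtual
probe midway between the arrays with the bisector axis. Axial spacing
is λ/8 (0.052 mm at 3.7 MHz and 1540 m/s; at the printed precision of
typical scanner logs, 0.051–0.052 mm), lateral sampling two lines per
pitch (0.41–0.54 mm depending on depth). The bistatic image is the
complex sum `I_T1R1 + I_T2R2 + ½(I_T1R2 + I_T2R1)` on a shared λ/4
Cartesian grid (~0.10 mm); the trans-probe pair is averaged because
acoustic reciprocity makes its two members carry the same information.

Probe registration maximizes the normalized complex correlation between
the T1R2 and T2R1 images beamformed under a candidate probe-2 pose —
reciprocity makes them align only at the true pose — by a coarse-to-fine
grid search (3 levels, 5 steps per axis over rotation and translation).
The coherence objective and search protocol are this package's own
concrete choice for a stage that in practice is scanner-specific;
simulate-and-recover tests hold it to 0.5°/0.5 mm.

B-mode rendering: envelope, log compression clipped at 55 dB dynamic
range, power-law contrast stretch α = 1.3, 8-bit quantization.

## Speckle tracking

Frame-to-frame displacements are estimated per pathway on its sector
grid by two-stage complex normalized cross-correlation: coarse kernel
2.6 × 4.5–5.9 mm (axial × lateral; the lateral extent in pixels follows
the depth-dependent line spacing), then a fine 0.8 × 2.1–2.7 mm kernel
centred on the coarse lag. Search regions default to 3.0 × 4.9–6.5 mm
and 1.0 × 2.5–3.2 mm; the desk presets widen the coarse axial search to
3.6 mm because their frame rate (and hence inter-frame motion) differs
from the 130 Hz full-scale protocol. Both components are median-filtered
with an 11×11-pixel (0.6 × ~5 mm) window.

The whole lag search is evaluated with box-filter sums so each pixel is
estimated at once; the coarse stage runs on an axially decimated pixel
set (factor 2) whose integer result seeds the fine stage. Axial
sub-pixel refinement uses the zero-crossing of the correlation phase
with the phase-per-lag slope estimated from *single*-lag differences:
at λ/8 axial sampling, the carrier advances ~π/2 per lag, so a two-lag
spread sits exactly on the ±π wrap and is ambiguous. Lateral sub-pixel
refinement is a 3-point parabolic fit of the correlation magnitude
(gated to concave neighbourhoods). Perfectly matched kernels
(correlation 1) skip refinement; zero-variance kernels return zero
displacement with zero confidence. Measured bias for a 0.3-px
band-limited shift at 20 dB SNR is ≲0.02 px.

## Mesh, fusion and strain

Segmentations are resampled to C equally spaced (arc-length) points and
R rings interpolated between the lumen–wall border and the outer border
(a contour, or the luminal contour extruded 2 mm along local outward
normals): 5×101 for wall-only, 17×151 for wall+ILT meshes. Local frames
(outward normal = radial, tangent = circumferential) come from central
differences along the circumference. Strain kernels are 5×9 mesh points
for wall-only meshes; for wall+ILT meshes the circumferential extent
grows toward the inner border as `round_odd(15 · spacing_outer /
spacing_ring)` (clipped to [15, C−1]) so the kernel's metric width stays
within ~15% of its outer-border width, where it is 9×15.

Bistatic fusion uses only axial displacements. At each mesh point the
pathway estimate is projected radially, `u_rad = u_ax / cos θ`, with θ
the angle between the pathway's axial ray and the outward normal;
|θ| > 75° is treated as unsupported (the projection diverges at grazing
incidence). Raw weights cos²θ are normalized so
`M11 + M22 + ½M12 + ½M21 = 1` wherever any pathway has support; points
covered by no pathway fall back to the least-oblique single pathway
with a warning. The mask construction (cos² with a hard 75° cutoff) is
this package's documented choice; alternatives share the qualitative
behaviour of favouring near-normal incidence.

**Midpoint correction.** The tracked mesh centroid is smoothed over time
with a cubic smoothing spline (fixed ~0.01 mm residual scale) and its
per-frame-pair shift s removed. The orthogonal-projection form
`c = −(s·n)n` is implemented and exact for displacement fields measured
along the normals. Inside the bistatic loop the same correction is
applied *in each pathway's own axial frame* — `u_ax,k ← u_ax,k − s·â_k`
before the 1/cos θ projection — because the radial projection of a rigid
shift otherwise leaks a tangential term `(s·t̂)tan θ` that the orthogonal
correction cannot see; the per-pathway form reduces to `c = −(s·n)n` at
θ = 0 and exactly nulls a pure translation. Since s is estimated from
the tracked centroids, which radial-only tracking itself under-reports
by ~2×, the correction is iterated (up to 12 passes, converging
geometrically) until the residual smoothed shift is below 0.1 µm. A
pure-translation phantom ends with mid-wall |strain| ~ 1e-4.

**Regularization.** Frame-to-frame fused radial displacements can be
constrained by the thin-plate bending criterion
`E*_bend ≤ ξ*·γ·RMS(u_r)` with ξ* = 0.9 (only ξ* < 1 constrains).
`E*_bend` is defined as the RMS second-derivative roughness of the
field on the mesh lattice, `sqrt(mean(u_rr² + 2u_rc² + u_cc²))` with
physical ring/arc spacings (periodic circumferentially) — linear in u,
so the bound is scale-invariant. γ is the roughness of a unit-magnitude
outward-normal displacement of the initial mesh per unit RMS — a pure
function of the initial geometry that makes a uniform unit expansion
sit exactly at roughness γ. Fields within the bound are returned
untouched (an affine field has zero roughness and always passes); rough
fields are smoothed by a separable Gaussian on the periodic lattice
whose width is found by bisection so the bound holds with ~1% equality.
A spline-fit smoother would serve the same contract; the lattice
Gaussian was chosen because the constraint is evaluated thousands of
times per run. In the single-aperture arm the same smoothing width is
applied to the circumferential component.

**Strain.** Displacements relative to the first end-diastole are fit,
within each point's (circumferentially periodic) kernel window, as
linear functions of the reference positions by least squares; the
symmetric part of the fitted gradient is the infinitesimal strain
tensor, rotated into the local radial/circumferential frame, with the
principal strain the larger eigenvalue. An affine deformation is
recovered exactly; a finite rigid rotation by angle φ leaves the
irreducible `1 − cos φ` residual (~1.5e-4 at 1°).

Cardiac frames (ed1, ed2, end-systole) are the successive minima and
intervening maximum of the mean inner-ring radius — the M-mode proxy.
The pipeline selects them once per experiment from the least-drifting
(bistatic unregularized) track with a 25%-of-range prominence filter,
and shares them across arms: the cardiac phase is a property of the
acquisition, not of an arm's tracking quality.

## Metrics

gCNR = 1 − Σ_bins min(p_wall, p_lumen) over 100 shared equal-width bins
of the envelope image (binning-insensitive by design; checked against
direct density integration to 0.03). The lumen mask is eroded by a
0.6 mm disk so wall specular energy does not contaminate it; the wall
annulus is split into 8 sectors of 45°, region 1 centred on the
single-probe axis (anterior), region 5 posterior, numbered clockwise.
MD is the mean start-to-end distance of middle-ring points between the
two end-diastoles; SNRe = 20 log10(μ/σ) of middle-ring circumferential
strain at end-systole (σ = 0 reports +∞; a non-positive mean is
reported as undefined rather than silently absolute-valued). Likert
summaries use type-7 (linear interpolation) quantiles. Paired
comparisons run a Shapiro normality check on the differences at
α = 0.05 and choose a paired t-test or Wilcoxon signed-rank
accordingly; all-tied samples short-circuit to p = 1.

## Problem sizes

Full-scale parameters (128 elements, 15 angles, 130 Hz, 5 s) are the
configuration defaults. The packaged experiments use two reduced
presets chosen as the package's own fixture scales: **desk** — 48
elements per probe, 5 angles over ±12°, 24 frames at 24 Hz over one
1-s cardiac cycle, 40×40 mm field at 4 scatterers/mm², 55° inter-probe
angle; **tiny** — 32 elements, 3 angles over ±10°, 14 frames at 14 Hz,
34×34 mm field at 3 /mm², 8 mm lumen radius. A desk run takes ~4 min
and a tiny run ~50 s on one core. The replicate study of the precision
mechanism uses ten tiny-preset phantoms with independent seeds.

## What the synthetic experiments show — and what they do not

The phantom exercises the full estimation chain with exact ground
truth, and reproduces the mechanism this method relies on: axial-only
multi-aperture fusion beats single-aperture axial+lateral tracking in
motion drift and SNRe, bistatic compounding raises lumen–wall gCNR in
the noise-limited regime, regularization trades local variation for
drift, and rigid motion is strain-free after the midpoint correction.

It does not emulate: specular (directional) reflection of the wall —
scatterers reradiate isotropically, so the *anisotropy* of wall
visibility with a single probe is under-represented and the single-probe
arm is, if anything, flattered; clutter, reverberation, aberration from
heterogeneous speed of sound; viscoelastic ILT behaviour;
out-of-plane motion; manual-segmentation variability (contours are
analytic, with optional jitter). Quantities measured on clinical
cohorts (absolute gCNR medians, drift in mm, SNRe in dB across
patients) therefore cannot be reproduced here, and the package makes no
attempt to; the acceptance artifacts report the synthetic experiment's
own numbers.

## Known limitations

- The coherence objective and search space for probe localization are
  package-defined stand-ins for a scanner-specific calibration.
- γ and the Gaussian-smoothing regularizer realize the bending-energy
  bound contract but are not a literal thin-plate-spline solver.
- The adaptive-kernel growth law (ratio of ring spacings, nearest odd)
  is one of several rules consistent with "metrically constant" kernels.
- Sub-pixel lateral refinement is magnitude-parabolic only; lateral
  estimates remain the weak point by design (the bistatic arm exists to
  avoid relying on them).
- 2-D only; no elevational beam, no 3-D meshes.
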