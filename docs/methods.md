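# Methods

`droptubes` reproduces, as a tested pipeline, the computational analysis of
dynamic DNA-nanotube self-assembly inside water-in-oil droplets: a
ground-truth synthetic image generator, automated droplet detection,
per-droplet condensation statistics, and a kinetic ODE model of
RNA-triggered tile assembly with transcription and enzymatic degradation.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## 1. The condensation readout

A DAE-E DNA tile carries one fluorophore.  While tiles are free, the
fluorescence inside a droplet is spatially uniform; as tiles polymerize
into nanotubes, the same total signal condenses into a few bright
curvilinear structures over a dimming background.  The shape of the
distribution of pixel intensities inside a droplet therefore tracks
assembly: per droplet we compute the bias-corrected sample skewness

G1 = n² / ((n−1)(n−2)) · m₃ / s³

and bias-corrected excess kurtosis (Fisher convention, normal → 0)

G2 = ((n+1)(m₄/m₂² − 3) + 6) · (n−1) / ((n−2)(n−3)),

with mᵢ the central moments and s the (n−1)-denominator standard
deviation — the conventions of `pandas.Series.skew`/`.kurt` and
`scipy.stats.skew/kurtosis(bias=False)`, which serve as independent
cross-checks in the test suite (the estimators themselves are implemented
directly).  Being shape statistics, both are exactly invariant under
positive affine maps of the pixel values: changing exposure or detector
gain does not move them as long as no pixel saturates.  They measure the
ratio of condensed to free fluorophores, not nanotube concentration, and
cannot distinguish well-formed nanotubes from disordered aggregates.

Two per-droplet estimator modes are provided:

* **pixels** (recommended): ordinary occupancy-weighted moments of all
  interior pixel values;
* **unique**: the pixel sample is first reduced to its *unique binned*
  brightness values — the sample is histogrammed at a fixed bin width
  (default 1 gray level, left-edge representatives) and every occupied bin
  contributes once, occupancy discarded — and the moments are taken over
  that list.  This mirrors a published processing pipeline; the two modes
  genuinely diverge on heavy-tailed samples, and
  `analysis/03_condensation_curve.py` tabulates both side by side.  Where
  the binning procedure is ambiguous (bin anchor, representative) we fix
  minimum-anchored left-edge bins of width 1 and document rather than
  guess further.

Droplets whose sample is degenerate after the selected reduction (zero
variance, fewer than 4 values) are excluded with an explicit reason and
counted in the outputs.  Per time point we report the unweighted mean ±
sample SD (n−1) over valid droplets; a single-droplet SD is reported as
0 with a flag to keep tables numeric.  Droplets are re-detected
independently in every frame — there is no tracking, so timecourses are
population summaries, not trajectories of individual droplets.  Droplets
are not binned by radius; an optional seeded subsample per frame mimics
measuring a random subpopulation.

## 2. Synthetic droplet microscopy

No public raw-image accession exists for this system, so the generator is
a first-class, tested module that emulates the statistical structure the
analysis assumes; every image-side claim in the test suite is exercised on
its output.

**Geometry.** Droplet radii are drawn log-uniformly over 1–20 µm
(vortex-emulsified "shaken" populations have a broad size distribution
with radii from ~1 µm to >20 µm; only the range is known, so the
scale-invariant law on that range is our choice).  Centers are
rejection-sampled so droplets never overlap nor touch the border margin;
failure after a capped number of attempts raises an error naming the count
achieved.  Per-droplet encapsulated tile amounts carry a lognormal
partitioning-noise factor (sd of log = 0.2 by default; droplet-to-droplet
variability is attributed to partitioning noise without a published
magnitude).

**Photometry.** Each droplet has a brightness budget proportional to its
tile concentration.  The free-tile fraction (1−f) is spread over the disk
weighted by the spherical chord depth 2√(R²−ρ²) — the 2D projection of a
uniformly fluorescent sphere — and blurred by a per-droplet defocus kernel
emulating out-of-focus light.  The assembled fraction f is deposited
uniformly along filament polylines.  The assembled total equals f times
the numeric integral of the free-tile depth map, so the per-droplet total
is *exactly* conserved across f: condensation redistributes signal, it
never creates it (tested).  The defocus sigma is chosen so the *total*
blur (defocus ⊕ PSF) equals 0.25·R; this keeps the rendered droplet
scale-free, which in turn makes the f = 0 interior value distribution
near-symmetric (|skewness| ≲ 0.15) at every radius and removes systematic
radius trends from the statistics.  The 0.25 fraction is a generator
design constant: smaller values leave the left-skewed chord dome, much
larger ones produce a right-skewed 1/v profile; 0.25 sits near the
symmetric crossover and is consistent with the defocus cone of a
mid-aperture epifluorescence objective collecting light through a droplet.

**Filaments.** Nanotube bundles are discrete worm-like chains with
persistence length 4.5 µm (measured values are 4–5 µm), step 0.1 µm,
confined to the droplet disk by specular reflection, or to an annulus at
0.85–1.0 R for surface-localized bundles.  Turning angles are Gaussian
with variance 2·step/persistence, giving the 2D tangent-decorrelation law
⟨cos θ⟩ = exp(−step/persistence) (tested against the closed form by Monte
Carlo).  Nanotube number and length per droplet are not quantified in the
source system — this is an open modeling choice, flagged here: we set the
total contour length from the droplet's nucleation capacity,
L = 0.095·R^2.5 µm (between cross-section and volume scaling), *shrinking*
mildly with assembly (factor 1 − 0.5·f) to emulate the observed joining of
nanotubes into fewer, thicker bundles, and split into filaments of about
one droplet diameter.  Because the fixed assembled mass is spread over
that roughly constant footprint, per-pixel filament brightness grows with
f while the bright-pixel fraction stays near 10%: the population mean
skewness then rises strictly from ≈0 through ≈2.2 toward a plateau ≈2.4 at
f = 0.8, with no systematic radius dependence — the qualitative shape the
condensation readout exhibits on real droplet data.  Filaments are
rendered as anti-aliased line splats of fixed physical width 0.5 µm
(bundles are sub-resolution; the width mimics PSF-limited appearance).

**Camera.** The ideal image is convolved with a Gaussian PSF (σ = 1 px),
scaled by the exposure gain, and corrupted by Poisson shot noise plus
Gaussian read noise, then quantized to 16-bit gray levels.  Any pixel
reaching 90% of the dynamic range raises an error instructing a lower
exposure gain — the analysis is exposure-agnostic *only* below saturation,
so the generator refuses to produce saturated data.  All randomness flows
from one seed through labeled CRC-hashed substreams
(`droptubes._seeds.substream`); identical seeds give bit-identical TIFFs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: 3D confocal stacks, multi-channel renders,
evaporation and coalescence, focus drift, surface-adsorption artifacts
beyond the excluded rim, aggregates as distinct from nanotubes, and any
dependence of filament morphology on chemistry.  Results on synthetic
frames demonstrate the *pipeline's* correctness, not instrument physics.

## 3. Droplet detection

The detector treats a droplet as a projected fluorescent sphere and runs a
multi-scale matched filter: normalized cross-correlation of the frame
against blurred chord-depth templates spanning the radius range (20
log-spaced scales).  Normalization makes the response independent of
droplet brightness and exposure.  Before matching, a grayscale
morphological opening with a disk of radius 3 px erases PSF-limited
filament lines (width ≈ 3 px) while preserving the droplet-scale dome, so
detection stays stable as condensation proceeds.  Candidate peaks must
(i) exceed an NCC threshold (0.35), (ii) show interior contrast at least
5× the image noise (median/MAD scale), and (iii) have a radial profile
that returns to the frame background — rejecting bright spots *inside*
larger droplets.  The radius is the best-matching template scale
(parabolically interpolated across scales), refined by the half-intensity
crossing of the ring-median radial profile; for the blurred-dome profile
the half crossing sits at 0.80·R nearly independently of the blur fraction
(0.806 at 0.20 R, 0.796 at 0.30 R), so a single calibration constant
converts crossing to radius.  Overlaps are resolved by non-maximum
suppression (centers closer than half the radius sum keep the stronger
candidate); border-margin droplets are discarded; interior pixels are
sampled from the disk shrunk by 10% to exclude rim artifacts, with a
minimum of 50 pixels for stable moments.

A circular Hough transform was the natural first candidate and was
implemented and benchmarked during development, but on soft-edged
projected-sphere droplets whose brightness spans more than an order of
magnitude, no single edge threshold serves dim and bright droplets at
once (recall plateaued near 0.8), and the gradient ring of a blurred dome
sits near 0.8·R, biasing Hough radii by ~20%.  The matched filter reaches
recall = precision = 1.00 on dispersed frames, mean center error
≈ 0.4 px, and mean radius error ≈ 2%, degrading gracefully with assembly
(recall ≈ 0.93 at f = 0.5).  An Otsu-threshold + connected-components +
circularity ≥ 0.8 fallback remains available (`method="threshold"`, and
as the second stage of `method="auto"`) for sharp-edged, high-contrast
images.  Out-of-focus droplets are not filtered in this version — a known
limitation.

## 4. Kinetic model of triggered assembly and disassembly

Deterministic mass-action ODEs in nM and minutes; state: inactive tiles
Ti, active free tiles Ta, polymerized tile mass P, nucleus density N, free
trigger RNA R, waste-sequestered tiles W, and RNAP relative activity a.

    dR/dt  = k_tx·G·a − k_act·Ti·R
    da/dt  = −δ·a
    dTi/dt = −k_act·Ti·R + (1−w)·k_deg·H·Ta
    dW/dt  = w·k_deg·H·Ta
    dN/dt  = k_nuc·Ta^n
    dP/dt  = n·k_nuc·Ta^n + k_on·Ta·N − k_off·N·P/(P+ε)
    dTa/dt = k_act·Ti·R − k_deg·H·Ta − n·k_nuc·Ta^n − k_on·Ta·N + k_off·N·P/(P+ε)

Mechanistic commitments: transcription of the trigger RNA decays with RNAP
activity (a transcription burst); RNA activates inactive tiles second-order;
assembly is cooperative nucleation (nucleus size n = 3 by default; n ≥ 2
configurable) plus elongation; depolymerized tiles return to the active
pool; RNase H deactivates *only free* active tiles (it hydrolyzes the RNA
half of the hybrid sticky end; polymerized tiles are protected, and free
RNA carries no hybrid so it is not degraded); a fraction w (default 0.2)
of deactivation events yields waste complexes that cannot be re-activated,
representing incomplete degradation products.  Tiles are conserved
exactly, Ti+Ta+P+W = T_total (checked to 1e-12 on the vector field and
1e-6 along trajectories); RNA is not conserved.  The depolymerization flux
saturates as P → 0 (ε = 1e-3 nM): nuclei never disappear in this model, so
an unsaturated −k_off·N would push the polymer pool negative after a pulse
fully disassembles; for P ≫ ε the term is plain k_off·N, and the ε-free
closed-form limit below is untouched.

Integration uses LSODA (stiff-capable) at rtol 1e-8 / atol 1e-10;
negative excursions beyond −10·atol trigger a warning and are clipped.
With nucleation, shedding, and enzymes off and a fixed nucleus pool, the
elongation subsystem has the closed form Ta(t) = Ta(0)·exp(−k_on·N₀·t),
which the integrator matches to 1e-6 — the model's numerical anchor.

**Parameters.**  Defaults (all configurable, TOML-loadable):

| parameter | default | units | role |
|---|---|---|---|
| k_tx | 0.2 | 1/min per nM gene | trigger transcription |
| G | 100 | nM | gene template |
| δ | 0.02 | 1/min | RNAP activity decay (t½ ≈ 35 min) |
| k_act | 2e-3 | 1/nM/min | tile activation by RNA |
| n_nuc | 3 | tiles | nucleus size |
| k_nuc | 3e-6 | nM⁻²/min | nucleation |
| k_on | 1e-2 | 1/nM/min | elongation |
| k_off | 5e-2 | 1/min | depolymerization |
| k_deg | 2.0 | 1/(U/µL)/min | RNase H deactivation |
| w_frac | 0.2 | — | waste fraction |
| T_total | 500 | nM | tile budget |

These are order-of-magnitude choices, **not fitted to data**: their only
mandate is to reproduce the system's qualitative regimes jointly under the
standard conditions (500 nM inactive tiles, 7.5–100 nM gene,
0.025–0.1 U/µL RNase H, hours-long observation): no gene → no assembly;
no RNase H → monotone assembly whose kinetics and plateau rise with gene
template; higher total tile → faster completion of nucleation+elongation
(two-tile preset); transcription decay against constant RNase H → a pulse
of assembled fraction that rises, peaks within the observation window, and
genuinely declines, with peak height strictly decreasing and half-rise
time strictly increasing in RNase H.  The joint requirement pins the
disassembly scale: the post-peak decline rate is bounded by
k_off·N·k_deg·H/(k_deg·H + k_on·N), so k_off ~ 1e-2/min would stretch
disassembly over ~10⁴ min (no visible pulse), while much stronger
degradation collapses the peaks and makes the half-rise non-monotone
(tiny peaks reach half height early).  RNase H stays in its activity
units (U/µL) with k_deg absorbing the conversion; the polymerase dose has
no printed rate mapping and remains a free parameter; crowding (PEG) is
represented only as a multiplicative preset on k_nuc/k_on
(`apply_peg`), with no crowding physics.  Whether the reference model
tracks filament number explicitly or coarser is not derivable from the
main text; the regime suite above is the contract, not coefficient
values.

**Pulse metrics.**  Peak height (parabolic refinement on the grid), peak
time, time above a threshold (linear-interpolated crossings; trajectories
still above threshold at the end are flagged right-censored), and
half-rise time (first crossing of half the peak).

## 5. Closed loop and problem sizes

`analysis/04_closed_loop_pulse.py` (and the corresponding acceptance
check) closes the loop: simulate the pulse at 0.1 U/µL RNase H, render a
six-frame series of 30 droplets (384² px) from the trajectory, analyze it
blind with detection + statistics, and compare the recovered mean-skewness
timecourse with the simulated assembled fraction — the skewness peak falls
within one frame of the assembly peak and the curve rises then falls.

Problem sizes throughout (20 × 50-droplet 512² frames for the detection
benchmark, 100 isolated droplets per assembled-fraction level, 10⁶-draw
analytic-limit checks, 600-min ODE horizons at 601 grid points) were
chosen so the full suite and the acceptance script each run in a few
minutes on one CPU while leaving comfortable statistical margins.

## 6. Known limitations

* Skewness/kurtosis quantify condensation, not correctness of assembly;
  aggregates and nanotubes are indistinguishable to the readout, and the
  generator does not model aggregates at all.
* Detection degrades for heavily assembled droplets (recall ≈ 0.6 at
  f = 0.8) where filament bundles dominate the dome; the closed-loop
  regime (f ≤ ~0.6) is unaffected.
* The unique-binned-value mode discards occupancy weights by
  construction; its values are systematically milder than pixel-mode
  moments and converge differently with droplet size.
* The ODE model is well-mixed and deterministic: no partitioning noise,
  no filament length distribution, no sequence-level thermodynamics, no
  abortive-transcript crosstalk beyond the lumped waste fraction.
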