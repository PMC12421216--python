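# Methods

`gastrokt` implements the retrospective validation loop of an accelerated,
single-coil, contrast-enhanced dynamic MRI protocol for rat gastric motility:
a dynamic stomach phantom, a respiratory-gated time-interleaved Cartesian
acquisition model, a k-t kernel-interpolation reconstruction, and the
image-quality and motility quantification used to judge it.  This note
records the models, the defaults and their units, the numerical choices, and
what the synthetic experiments do and do not establish.

## Phantom signal model

Voxel intensity is proportional to the saturation-recovery fraction
`1 − exp(−t_rec/T1)` of the compartment occupying it.  Defaults emulate a
7 T protocol with a gadolinium-doped semi-solid test meal:

| parameter | default | meaning |
| --- | --- | --- |
| `t1_lumen` | 17 ms | T1 of the Gd-doped meal |
| `t1_tissue` | 800 ms | T1 of saturated surrounding tissue |
| `t_rec` | 127 ms | saturation-pulse-to-echo recovery interval |
| `background_level` | 0.05 | air/noise floor outside the body |
| `tissue_base` | 1.0 | tissue proton density relative to the meal |

At these values the lumen recovers essentially fully (99.9%) while tissue
recovers 14.7%, under the 20% working bound — the contrast premise of the
method.  Flip-angle steady-state effects and TE decay are deliberately
ignored: the recovery term dominates the contrast at this `t_rec`, and TR/TE/FA
are carried only as acquisition metadata.  Noise is additive Gaussian on the
complex-free image followed by a magnitude operation; Rician statistics are
not modelled.  The proton density of tissue relative to the meal is not
determined by the relaxation model itself, so it is exposed as the free
parameter `tissue_base`.

## Phantom geometry and motion

The lumen is the union of two ellipsoids (fundus, corpus) and a tube of
radius 2.6 mm swept along the antral axis, rendered with 2×2×3 sub-voxel
supersampling so boundary voxels carry partial-volume intensities.  The
default grid is 64×64×4 voxels at 0.5×0.5×1.5 mm — a four-slice slab through
the antrum, i.e. a scaled-down stomach (~1.2 mL) rather than the full organ.

The antral radius is modulated by a travelling raised-cosine occlusion wave

    r(s, t) = r0 · (1 − A · w(s − v·t)),   w(u) = (1 + cos(2πu/λ)) / 2,

so the radius occlusion at the wave trough equals `A` and the cross-sectional
area occlusion equals `1 − (1 − A)²`.  Defaults are rat cohort values:
`A = 0.231`, `f = 5.3` cpm, `v = 0.56` mm/s.  The wavelength defaults to
`λ = 60·v/f ≈ 6.3` mm — the unique value for which a fixed cross-section
oscillates at `f` while the wave travels at `v`; the waveform itself is a
modelling choice (any smooth unit-amplitude periodic bump would do).

Respiration is modelled as a pressure trace with one short burst
(inhalation) per cycle — default 20% of the cycle — and a quiescent
baseline (slow exhalation).  Through-plane displacement is applied only
during bursts; since the acquisition model triggers on the burst's falling
edge and images the quiescent phase, the default phantom uses zero
displacement, emulating a well-gated acquisition.  Non-zero displacement is
available to study gating failures.

## Acquisition model

Phase-encode lines are undersampled by an integer reduction factor R at the
k-space periphery while `n_acs` central lines (default 12) are always
acquired; the peripheral interleave advances by one line per frame
(`offset = frame mod R`), so R consecutive frames cover every line.  The ACS
block is centred with the DC line (`n_pe // 2`) as the upper-middle line for
even `n_acs`.

Volume timing follows the packet scheme: slices of a packet are excited
within one TR, so one volume takes `n_packets × lines_per_frame × TR`
(6 × 24 × 10.6 ms = 1.526 s, the protocol's "roughly 1.5 s").  A volume
starts at the first respiratory trigger after the previous volume ends and
runs uninterrupted; triggers arriving mid-volume are ignored.  For periodic
breathing of cycle c the start-to-start interval is `ceil(T_vol/c)·c`, which
for the nominal 1.5 s volume never exceeds 3 s over the physiologic 1–2 s
cycle range.

## k-t kernel reconstruction

Missing lines are estimated as shift-invariant linear combinations of
acquired neighbours in (kx, ky, t) — a k-t GRAPPA-style interpolation for a
single coil.  Two image properties justify the linear predictive model: the
piecewise-homogeneous bright lumen acts as an effective spatial sensitivity
profile (a convolution kernel in k-space), and the narrow-band quasi-periodic
dynamics justify time-invariant kernels.

Kernel support defaults: kx half-width 2 (5 taps); per temporal offset, the
nearest sampled line above and below the target in ky; a temporal window of
R frames centred on the target.  All are configurable.  One kernel shape per
missing phase (R−1 shapes; two for R = 3).  Three numerical choices matter:

- **ACS-feasible ky span.** The ky stencil is pruned to
  `|Δky| ≤ n_acs//2 − 1` so every kernel has calibration targets whose full
  stencil lies inside the ACS block; without this, R ≥ ~ `n_acs` cannot be
  calibrated from a narrow ACS region at all.
- **Temporal edges.** At the first/last frames the window is shifted (not
  truncated) to stay inside the record, and those shifted variants get
  dedicated calibrated kernels, so no frames are discarded and every variant
  keeps at least two temporal source frames.
- **Static/dynamic decomposition** (`subtract_temporal_mean`, default on).
  Each line's temporal mean over its acquired frames — available for every
  line because the interleave revisits each line every R frames — is
  subtracted before calibration and restored after interpolation.  The
  kernels then model only the dynamic residual.  Without this, the
  least-squares fit is dominated by the static background and over-weights
  temporal same-line sources, which smooths the dynamics and can make a
  milder R reconstruct *worse* than a stronger one.  Acquired samples are
  bit-exact under the decomposition, so data consistency is unaffected.

Calibration slides the stencil over all ACS positions (kx, ky, frames, and
slices — one kernel set is shared across slices by default, per the
slice-generic homogeneity argument; per-slice calibration is a flag) and
solves the pooled unregularized least-squares system with an SVD solver.
Underdetermined systems raise; rank-deficient ones fall back to the
minimum-norm solution with a report warning.  Frames are pooled jointly
(stationary-kernel premise); a frame-subset option exists for windowed
calibration.  ky source indices wrap modulo the grid (the DFT of a sampled
image is periodic in k); acquired lines, including ACS, pass into the output
untouched.  On data that exactly obey the kernel model the reconstruction is
exact to numerical precision when R divides the ky count (otherwise the
periodic continuation of the sampling lattice is broken at the two edge
lines, and only those suffer).

## Quality metrics

RE = ‖test − ref‖₂ / ‖ref‖₂ over the vectorized series; PSNR =
10·log₁₀(range²/MSE) with an infinity sentinel for identical images; SSIM is
the standard Wang et al. formulation (7×7 uniform window, K1 = 0.01,
K2 = 0.03) computed per 2D slice/frame and averaged.  Before metric
evaluation both series are normalized to [0, 1] with one *global* scaling —
per-frame scaling would hide temporal intensity dynamics.  The window size
and constants used by the original evaluation are unknown; these defaults
are configurable.

## Motility quantification

The lumen is segmented by Otsu thresholding of the pooled series histogram,
keeping the largest connected component per frame.  For area and volume
measures a *fractional* (partial-volume) segmentation is the default:
intensities are rescaled between a tissue level (median of a ring 2–3 voxels
outside the lumen) and a lumen level (median of the eroded interior), so
boundary voxels carry their lumen volume fraction.  With 1.5 mm slices,
binary voxel counting biases peak cross-sections upward by ~10% and inflates
the occlusion ratio; fractional counting removes the bias.  The boolean path
remains available and is used for segmentation-accuracy checks.

The antral axis is the centroid polyline of the lumen in perpendicular slabs
along a chord (two endpoint hints, or the mask's principal axis),
arc-length parameterized.  Cross-sectional area at position s is the lumen
volume inside the perpendicular slab `|s' − s| ≤ h/2` divided by the slab
thickness h (default 1.0 mm; thicker slabs low-pass the travelling wave
along s).

Because gated sampling is coarse (~3 s frames against a ~11.3 s contraction
period), sub-sample quantities are refined on band-limited (Fourier)
interpolations — justified by the same narrow-band premise as the
reconstruction: peak/valley values are read off an 8× sinc-upsampled copy of
the (uniformly resampled) area series, and the inter-section delay is the
positive lag maximizing the 16× upsampled normalized cross-correlation,
refined by parabolic interpolation.  Amplitude is the mean over cycles of
(peak − following valley)/peak — the occlusion ratio on areas; the
radius-equivalent conversion `1 − sqrt(1 − a)` is used only when comparing
against the generator's radius amplitude.  Frequency is the dominant non-DC
bin of the FFT of the mean-removed series (irregular gated times are
linearly resampled to the median interval first; the estimate is therefore
quantized to one bin, 0.34 cpm for a 3-minute record).  Velocity is
section distance / delay, with delays ≤ 0 or correlation peaks < 0.3
rejected.  Volume is the (fractional) voxel sum times the voxel volume.

## Problem sizes and determinism

The validation experiments run the default 64×64×4 phantom with 60 gated
frames (~3 min of scan time; ~10⁶ voxel samples per series), chosen to hold
several contraction wavelengths and ~16 cycles while keeping the full loop
(three reconstructions plus motility) under a minute of compute.  All
randomness (phantom noise, respiratory jitter, synthetic calibration data,
phantom-size sampling) flows through explicit `numpy` generator seeds;
identical seeds give bit-identical outputs end to end.

## What the synthetic experiments do and do not show

The phantom satisfies the reconstruction's assumptions by construction —
piecewise-homogeneous lumen, strictly periodic narrow-band motion, exact
Fourier encoding, optional white noise.  Passing tests therefore establish
internal consistency (the pipeline recovers what the generator put in, the
calibration equals its algebraic definition, fidelity degrades monotonically
with acceleration) but not in-vivo performance: real stomachs add secretion
mixing and meal inhomogeneity, drifting contraction frequency, imperfect
gating, B0/B1 inhomogeneity and Rician noise, none of which are modelled.
Cohort-scale in-vivo values enter only as generator defaults, not as claims.

## Known limitations

- No Bloch simulation, B0/B1 fields, gastric emptying, or secretion.
- Single coil only; no multi-coil parallel imaging, compressed sensing, or
  learned reconstructions.
- Cartesian trajectories only.
- The raised-cosine contraction waveform and the two-ellipsoid-plus-tube
  geometry are stylized; real antral walls are neither circular nor rigid.
- Frequency estimates inherit the FFT bin quantization of short records.
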