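# gastrokt

Simulation, reconstruction, and analysis toolkit for **contrast-enhanced
dynamic gastric MRI** in small animals.

Imaging the whole rat stomach in motion is hard: antral contractions run at
~5 cycles per minute and must be sampled every few seconds over the full
organ, while respiration corrupts any acquisition that ignores it.  A
practical protocol combines a gadolinium-doped test meal (lumen T1 ≈ 17 ms
at 7 T against tissue T1 > 800 ms, so a saturation pulse ~127 ms before the
echo leaves the lumen bright and tissue suppressed), respiratory gating to
the quiescent exhalation phase, slice grouping into packets, and a
time-interleaved Cartesian undersampling whose skipped phase-encode lines
are recovered by **k-t kernel interpolation** — a single-coil, GRAPPA-style
convolutional interpolation in (k, t) space.  Missing samples are estimated
as

    S(kx, ky, t) ≈ Σ_j  w_j · S(kx + Δkx_j, ky + Δky_j, t + Δt_j)

with shift-invariant complex weights `w_j` calibrated by unregularized least
squares on a fully sampled auto-calibration (ACS) block.  Linear
predictability rests on two properties of these images: the homogeneous
bright lumen acts like a coil-sensitivity profile (a convolution kernel in
k-space), and the quasi-periodic narrow-band motion justifies time-invariant
kernels.

The package is aimed at MRI methods researchers and preclinical GI groups
who want to prototype or validate such protocols without scanner time.  It
provides:

- `gastrokt.phantom` — a dynamic stomach phantom: saturation-recovery
  contrast, travelling raised-cosine antral occlusion wave (defaults: 23.1%
  radius occlusion, 5.3 cpm, 0.56 mm/s), respiration trace synthesis, and an
  exact Fourier forward model;
- `gastrokt.sampling` — interleaved undersampling masks (reduction factor R,
  centred ACS block), protocol timing (6 packets × 24 lines × 10.6 ms ≈
  1.5 s/volume), trigger detection, and gated volume scheduling (≤ 3 s
  effective resolution over 1–2 s breathing cycles);
- `gastrokt.recon` — kernel geometry, ACS least-squares calibration,
  k-t interpolation, and magnitude reconstruction;
- `gastrokt.quality` — relative error, SSIM, PSNR, [0, 1] normalization,
  maximum-intensity projection, Pearson correlation;
- `gastrokt.motility` — lumen segmentation, antral-axis tracing,
  perpendicular cross-section area-time series, and contraction amplitude
  (occlusion ratio), frequency, propagation velocity, and gastric volume;
- `gastrokt.io` / `gastrokt.cli` / `gastrokt.pipeline` — NIfTI + HDF5
  containers and a `gastrokt` command with `simulate`, `undersample`,
  `reconstruct`, `evaluate`, `motility`, `sweep`, and `run` subcommands.

## Worked example

Render the default phantom at respiration-gated frame times, sweep the
reduction factor, and quantify motility:

```python
import numpy as np
from gastrokt import measure_motility
from gastrokt.pipeline import antrum_hints, default_phantom_series, sweep_reductions
from gastrokt.phantom import PhantomConfig

series = default_phantom_series(n_frames=60)
for row in sweep_reductions(series, (2, 3, 11), n_acs=12):
    print(f"R={row['reduction']:>2}  RE={row['re']:.3f}  SSIM={row['ssim']:.3f}  "
          f"PSNR={row['psnr']:.1f} dB")

m = measure_motility(series, axis_hints=antrum_hints(PhantomConfig()),
                     positions=[2.0, 5.0])
print(f"amplitude (radius occlusion): {1 - np.sqrt(1 - m.amplitude):.3f}")
print(f"frequency: {m.frequency:.2f} cpm")
print(f"velocity:  {m.velocity:.3f} mm/s")
print(f"volume:    {m.volume:.2f} mL")
```

prints

```
R= 2  RE=0.036  SSIM=0.871  PSNR=36.4 dB
R= 3  RE=0.050  SSIM=0.852  PSNR=33.7 dB
R=11  RE=0.145  SSIM=0.713  PSNR=24.3 dB
amplitude (radius occlusion): 0.223
frequency: 5.33 cpm
velocity:  0.561 mm/s
volume:    1.24 mL
```

Reconstruction fidelity degrades monotonically with acceleration — mildly up
to R = 3, visibly at R = 11 — and the motility analysis recovers the
generator's ground truth (0.231 radius occlusion, 5.3 cpm, 0.56 mm/s; the
frequency estimate is quantized to the 0.33 cpm FFT bin of a 3-minute
record).  The volume is that of the four-slice phantom slab, not a whole
stomach.

The same loop from the shell:

```sh
gastrokt simulate --frames 60 --out-image ref.nii.gz --out-kspace full.h5
gastrokt undersample --in full.h5 --R 3 --acs 12 --out und.h5
gastrokt reconstruct --in und.h5 --out recon.nii.gz --report calib.json
gastrokt evaluate --test recon.nii.gz --ref ref.nii.gz --out metrics.json
gastrokt motility --in recon.nii.gz --axis 16,10,3:28.5,10,3 --positions 2,5 --out motility.json
```

See `docs/methods.md` for the models, defaults, and numerical choices.

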