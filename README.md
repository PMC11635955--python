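# fusedcae

A desk-scale simulator and reconstructor for a **fused optical–electronic
convolutional autoencoder** in scintillation X-ray imaging.

## The problem

Indirect X-ray detectors convert absorbed X-rays into visible
fluorescence inside a scintillator crystal (here Ce:YAG, refractive
index n ≈ 1.82).  Because the index is high, only light within the
escape cone of total internal reflection leaves the exit face: the
critical angle is arcsin(1/n) ≈ 33.3°, and the trapped fraction of an
isotropic emitter is

    1 − (1 − cos θ_c) / 2  ≈  92 %.

A periodic metasurface (period ξ) etched on the exit face diffracts
trapped large-angle rays back into the collection optics.  The
transmission-grating relation into air,

    sin θ_out = n sin θ − m λ / ξ,      propagating iff |sin θ_out| < 1,

summed incoherently over emission wavelength (400–700 nm), emission
angle, and admitted order m, defines a convolution kernel K: the
**optical encoder**.  The detector frame is

    Ŝ = BIN( Poisson(t_cap · flux · (I_in ⊗ K)) + N(0, σ_read) ),

and the **electronic decoder** (i) learns K from a *single* exposure of
a known calibration sample by minimizing the least-squares inference
target ‖Ŝ − I_known ⊗ K‖²_F, and (ii) inverts the encoder by
Richardson–Lucy deconvolution.  Adjusting ξ selects what gets enhanced:
a 300 nm grating (K_ξ3) admits only large-angle first-order light and
enhances texture (high spatial frequencies); a 500 nm isotropic
structure (K_ξ5) recovers more photons into the low-frequency band and
enhances regional absorption contrast; a 200 nm grating admits nothing
usable.

The package is aimed at computational-imaging researchers who want a
reproducible, fully synthetic test bench for this design: diffraction
physics to PSF, phantom scenes, noisy capture, one-shot calibration,
deconvolution, SNR/CNR evaluation, and a toy parallel-beam tomography
loop with per-projection decoding.

## Worked example

```python
import numpy as np
from fusedcae import (ExposureSettings, CalibrationPair, capture,
                      estimate_kernel, kernel_preset,
                      make_glyph_phantom, make_fringe_phantom,
                      richardson_lucy, escape_fraction)

print(f"trapped photons: {100 * (1 - escape_fraction(1.82)):.1f} %")

# 1. design the texture-enhancing optical kernel (xi = 300 nm)
kernel = kernel_preset("k_xi3")
print(f"photon collection vs plain system: "
      f"{kernel.collection_efficiency / kernel_preset('nsys').collection_efficiency:.1f}x")

# 2. calibrate the decoder from ONE exposure of a known glyph sample
calib = make_glyph_phantom((128, 128), "239", depth=0.5)
shot = capture(calib, kernel, ExposureSettings(bin_factor=1, noiseless=True))
decoder = estimate_kernel(CalibrationPair(calib, shot), (9, 9), epochs=60)
print(f"calibration loss after {decoder.trace.epochs} epochs: "
      f"{decoder.final_loss:.3g}")

# 3. image a 3 um-pitch fringe sample and decode it
fringes = make_fringe_phantom((256, 256), pitch_um=3.0, n_lines=7)
frame = capture(fringes, kernel, ExposureSettings(bin_factor=1, noiseless=True))
out = richardson_lucy(frame, decoder.kernel, iterations=30)
print(f"decoded frame: {out.image.shape}, {out.iterations} RL iterations")
```

prints

```
trapped photons: 91.8 %
photon collection vs plain system: 18.5x
calibration loss after 60 epochs: 1.47e-09
decoded frame: (256, 256), 30 RL iterations
```

91.8 % is the escape-cone loss of a bare Ce:YAG face; the 300 nm
metasurface collects ≈18× more fluorescence than the plain system
because it re-admits trapped large-angle light; the calibration loss
near zero means the decoder has learned the encoder exactly from one
noiseless exposure; the decoded frame retains all seven 3 µm-pitch
absorption lines (see `fusedcae.metrics.section_profile`).

End-to-end comparisons run from configs:

```bash
fusedcae run --scenario regional_vs_texture --out runs/demo
```

which writes per-arm SNR curves, kernels, reconstructions and a
`summary.csv` comparing the plain system against the ξ = 300 nm and
ξ = 500 nm arms at a matched 20 ms photon budget.

## Layout

| module | contents |
| --- | --- |
| `fusedcae.optics` | escape-cone photometry, grating orders, PSF design |
| `fusedcae.phantoms` | glyph/fringe/fiber/two-region scenes, capture model |
| `fusedcae.training` | single-exposure kernel estimation (decoder learning) |
| `fusedcae.reconstruction` | Richardson–Lucy decoding, classical baselines |
| `fusedcae.metrics` | radial SNR curves, intensity ratios, CNR, spectra |
| `fusedcae.tomography` | Radon projection, per-projection decode, FBP |
| `fusedcae.scenarios` | validated configs, seed fan-out, end-to-end runs |

See `docs/methods.md` for the model, its assumptions and limitations.
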