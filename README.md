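# hdimtools

Fisher-information analysis and optimization of multi-dimensional
fluorescence detection: FLIM time gating, spectral channels, polarization,
and their joint (hyper-dimensional) combination.

## The problem

Fluorescence microscopy encodes biochemistry in the photophysics of the
emitted light — excited-state lifetime, emission spectrum, anisotropy.  The
photon budget per pixel is small (hundreds to thousands of photons), so the
precision with which lifetimes or fluorophore abundances can be estimated
is limited by shot noise and by *how the detected photons are partitioned
into channels*.  For `m` independent photon-counting channels with expected
counts `G_i(x) = N f_i(x)`, the Fisher information on a parameter `x` is

    I(x) = Σ_i (∂G_i/∂x)² / G_i ,

and the photon economy of an efficient estimator is the F-value

    F = (σ_x / x) √N ,   σ_x = I^{-1/2} ,

with `F = 1` meaning shot-noise-limited precision and photon efficiency
`p = F⁻²`.  Refining a channel partition can only increase `I`, so
detection schemes that resolve time, wavelength and polarization *in
parallel* extract the most biochemical information per photon.  This
package provides:

- **`models`** — closed-form fluorophore signatures (mono-exponential
  decays, single-exponential anisotropy `r(t) = r₀ e^{−t/θ}`, gamma- or
  Gaussian-shaped emission spectra) on arbitrary
  polarization × wavelength × time detection grids;
- **`fisher`** — scalar and matrix Fisher information, F-values, photon
  efficiency, separability and resolving power, and the comparison of
  detection techniques (FLIM, spectral, anisotropy imaging and all their
  combinations) by marginalizing one full-grid signature;
- **`optimize`** — greedy channel splitting / merging and direct boundary
  refinement for 1-D gating schemes, averaged over a range of lifetimes or
  abundances;
- **`simulate`** — seeded Poisson photon sampling, synthetic
  abundance-gradient images (256 × 256 pixels on a 2 × 16 × 64 = 2,048
  channel grid by default), and Monte Carlo F-value estimation for
  two-time-gate lifetime measurement;
- **`unmix`** — per-pixel (non-negative) least-squares abundance
  estimation with accuracy/precision figures of merit;
- **`phasor`** — first-harmonic cosine/sine transforms along time,
  spectrum and the joint plane, including the 16-coefficient
  hyper-dimensional phasor reduction of a 2,048-channel pixel.

It is aimed at microscope builders and users deciding how many detection
channels to deploy and where to place gate boundaries.

## Worked example

How well can two typical fluorophores (lifetimes 3.0 / 2.0 ns, limiting
anisotropies 0.4 / 0.2, rotational correlation times 12 / 1 ns, 50 nm-wide
spectra peaked 10 nm apart) be unmixed by each detection technique?

```python
import numpy as np
from hdimtools import (DetectionGrid, FluorophoreModel,
                       technique_fvalue_scan, technique_minima,
                       two_gate_optimum)

u, F = two_gate_optimum()
print(f"u*={u:.4f}  F*={F:.4f}")

grid = DetectionGrid.paper_default()          # 2 pol x 16 spectral x 64 time
A = FluorophoreModel(3.0, 0.4, 12.0, 495.0, 50.0, name="A")
B = FluorophoreModel(2.0, 0.2,  1.0, 505.0, 50.0, name="B")
scan = technique_fvalue_scan(A, B, grid, np.arange(0.02, 0.985, 0.005))
print(technique_minima(scan).to_string(index=False))
```

prints

```
u*=1.5936  F*=1.2426
technique    min_F  argmin_abundance  F_at_half
     HDIM 2.246336             0.455   2.250426
     SLIM 2.550286             0.425   2.565082
 SR-ANISO 2.630323             0.460   2.634440
 TR-ANISO 2.930150             0.475   2.931966
     SPEC 3.121120             0.425   3.141751
     FLIM 3.999312             0.420   4.034830
    ANISO 4.365364             0.530   4.370744
```

The first two numbers are the optimal two-time-gate design for lifetime
estimation: placing the second gate boundary at 1.59 lifetimes achieves
F ≈ 1.24, i.e. only 24% more noise than a shot-limited measurement.  The
table ranks detection techniques by the combined F-value of abundance
unmixing (mean relative error of the two abundances, each referenced to
the shot noise of its own photon share): the full 2,048-channel
hyper-dimensional acquisition (HDIM) needs `F² × 400 ≈ 2,000` photons to
reach 5% abundance error, whereas spectral-only detection needs roughly
twice as many and lifetime-only or anisotropy-only detection several times
more.  Any marginalization of the full grid can only lose information, so
HDIM is always the top row.

A command-line surface wraps the same workflows:

```sh
hdimtools fvalue --mode monte-carlo --tau 2 --N 1000
hdimtools optimize-gates --tau-min 0.5 --tau-max 3.0 --T 12.5 --channels 4
hdimtools dimensionality --config fluors.yaml
hdimtools simulate --config fluors.yaml --N 250 --seed 1 --out img.tif
hdimtools unmix --image img.tif --technique hdim
hdimtools phasor --image img.tif --out phasors.tif
```

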