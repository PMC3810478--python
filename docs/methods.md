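# Methods

This note documents the models, conventions and numerical choices behind
`hdimtools`, in the order a reader meets them: the forward photophysical
model, the information-theoretic figures of merit, the partition
optimizers, the Monte Carlo machinery, unmixing, and the phasor reduction.
It closes with known limitations.

## Forward model

A detection grid partitions photons along three axes: time gates within
one laser period `[0, T]`, wavelength bins within a detection band, and
polarization channels (parallel / perpendicular to the excitation
polarization, or analyzer-free "unpolarized").  All bins are half-open
`[lo, hi)` and channels are ordered polarization-major, then wavelength,
then time, so serialized signatures are bit-comparable.  The default grid
is 2 polarizations × 16 spectral bins over 440–630 nm × 64 time gates over
12.5 ns (2,048 channels), matching commercially available spectral-FLIM
hardware with a polarizing beam splitter.

**Time.**  Decays are mono-exponential with lifetime τ.  Under repetitive
pulsed excitation the steady-state histogram within one period is the
wrapped exponential, so the gate `[t_a, t_b)` receives the fraction
`(e^{−t_a/τ} − e^{−t_b/τ}) / (1 − e^{−T/τ})`; a full cover of the period
sums to exactly 1.  The instrument response is a delta function and there
is no background term.

**Polarization.**  Analyzer-resolved intensities follow the standard
single-rotator model: `I_∥ ∝ e^{−t/τ}(1 + 2r(t))/3`,
`I_⊥ ∝ e^{−t/τ}(1 − r(t))/3` with anisotropy decay `r(t) = r₀ e^{−t/θ}`
(`0 ≤ r₀ ≤ 0.4` for one-photon excitation, θ the rotational correlation
time).  Each row is a sum of two exponentials with rates τ and
τθ/(τ+θ); both components are wrapped at the period with their own rate.
"Unpolarized" detection is the analyzer-free sum of the two rows — not the
magic-angle signal — so building a signature on an unpolarized grid equals
summing a polarized signature over its polarization axis.  The summed
decay therefore carries the anisotropy term `(2 + r₀ e^{−t/θ})/3`, which
is deliberate: lifetime-only (FLIM) data derived from a multi-channel
acquisition by binning all photons across the analyzer channels has
exactly this shape.  When a grid selects a single analyzer orientation,
fractions are renormalized over the detected subset.

**Spectrum.**  Emission spectra are unimodal densities integrated over
each wavelength bin and renormalized to the detection band.  The default
is a gamma density reparameterized so that its *mode* equals the requested
peak and its FWHM equals the requested width, with the tail toward longer
wavelengths as in real emission spectra.  The shape parameter defaults to
k = 16, giving skewness `2/√k = 0.5` — visibly asymmetric but still
spectrum-like.  Only the peak and FWHM of the reference spectra are
pinned down externally; the shape is a package choice, and a Gaussian
option is provided for sensitivity analysis.  Spectral figures of merit
(the F-values of SPEC, SLIM and HDIM unmixing) move by roughly 5% between
k = 9 and a pure Gaussian, which bounds the uncertainty this choice
introduces.

The full signature (HDSS) of a fluorophore is the outer product of its
spectral factor and its joint polarization/time factor; it is
non-negative and sums to 1 over the grid.  Mixtures are linear: expected
counts are `G = N Σ_j a_j g_j` for abundances `a` and endmember
signatures `g_j`.

## Fisher information and figures of merit

For independent Poisson channels, `I(x) = Σ_i (∂G_i/∂x)²/G_i`.  Scalar
parameters use central finite differences with a default relative step of
1% (results are stable to 0.1% for steps between 0.5% and 2%); channels
with fractions below 1e−12 are excluded from the sum — their contribution
vanishes in the limit but the division is numerically unstable.

The F-value of a scalar estimate is `F = √(N/I)/x`, independent of `N`.
For the canonical two-adjacent-gate lifetime system with `T ≫ τ` the
closed form is `F(u) = √(e^u − 1)/u` in the reduced boundary `u = t/τ`;
its minimum, found numerically, is F = 1.2426 at u = 1.5936.

For abundance unmixing the information is a matrix with analytic entries
`I_jk = N Σ_i g_ij g_ik / Σ_l a_l g_il` (the forward model is linear, so
no differencing is needed).  The two abundances are free parameters (no
sum-to-one constraint) and the covariance is the matrix inverse.  The
per-abundance F-value references each component's relative error to the
shot noise of the photons that component itself contributes:

    F_j = (σ_j / a_j) √(a_j N) = σ_j √(N / a_j) ,

and the combined F is the unweighted mean over components.  This
normalization makes the two natural anchors exact: two fluorophores with
fully disjoint channel support — each abundance estimated from its own
independent Poisson counts — give `F_j = 1` at any mixture, and the
figure remains independent of total `N`.  Technique comparison
marginalizes both endmember signatures onto each of the seven nonempty
subsets of {time, wavelength, polarization} (FLIM, SPEC, ANISO, SLIM,
time-resolved and spectrally-resolved anisotropy, HDIM) and scans the
relative abundance; the full grid dominates every marginalization at
every abundance, which property tests assert on random fluorophore pairs.

Separability of two parameter values is `S = |x₁−x₂|/√(σ₁²+σ₂²)`; at the
Rayleigh-equivalent threshold `S = 2` with `N` photons per estimate the
smallest resolvable difference is `Δx = 2√2·x/√(pN)` and the resolving
power `R = x/Δx = √(pN)/(2√2)`, with `p = F⁻²` the photon efficiency.
The cost of adding a photon-counting channel with dark counts is
`ε = (DCR/MCR)/N`.

## Partition optimization

Three deterministic strategies share one objective interface (per-channel
information contributions as a function of bin edges, averaged over a grid
of parameter values — lifetimes 0.5–3.0 ns by default for time gating, a
range of abundances for spectral gating):

- **Splitting** scans a dense candidate grid (128 points per channel) and
  accepts the split with the largest mean relative gain `ΔI/I` while it
  exceeds a cost ε (default 1e−4, interpretable as the dark-count cost
  above or as a pure numerical tolerance).  Candidate grids are used
  because closed-form optima do not exist beyond two gates.
- **Merging** starts from a fine partition and removes the boundary whose
  loss is smallest while the mean relative loss stays within ε; an
  optional channel floor expresses "merge down to m channels" directly.
- **Refinement** runs coordinate descent with bounded scalar minimization
  per boundary on the mean F-value until a sweep improves it by < 1e−6.

Ties break toward the lowest coordinate.  On the two-gate lifetime
problem all three routes agree on the boundary to within 0.02 τ, and
refined m-gate schemes dominate equal-width schemes for m = 2, 4, 8.
Relative efficiency of a scheme is the mean of `(F_ref/F)²` against a
256-equal-bin reference (a TCSPC-like or hyperspectral acquisition).

## Monte Carlo validation

Synthetic gradient images place fluorophore A's fractional abundance on a
linear 0→1 ramp along columns, with every row an independent replicate;
counts are independent Poisson draws per channel (equivalent to a Poisson
total multinomially split), at expected totals of 250, 1000 or 10000
photons per pixel.  The default image is 256 × 256 pixels on the
2,048-channel grid; tests and the acceptance script use 128 replicate
rows and 16 gradient columns, which keeps the replicate noise of the
precision estimates below 2% while fitting comfortably in memory and
time.

The two-gate experiment estimates τ̂ per replicate from the closed form
`τ̂ = t_b / ln((G₁+G₂)/G₂)` (or by 1-D multinomial maximum likelihood for
arbitrary gatings) and reports the empirical `F = sd(τ̂)√N/τ`.
Replicates with an empty essential gate are excluded rather than clamped,
their fraction is reported, and a bias flag is raised when it exceeds
10% — at 250 photons and boundaries beyond ≈4.5 lifetimes both the
exclusion fraction and the estimator bias grow, reproducing the
well-known low-count breakdown of late gating.

The boundary scan deserves a note.  `F(boundary)` is extremely flat near
its optimum (it changes by ~0.002 over ±0.3 ns at τ = 2 ns), so the raw
argmin of a scan with independent draws per boundary scatters by more
than a nanosecond at a few thousand replicates.  The scan therefore
re-bins *one* set of simulated photon arrival times per replicate at
every boundary — exactly what a gate-position scan over a recorded
dataset does — which makes the noise common across boundaries and the
curve smooth, and the minimum is localized by a quartic fit over the
1.5–5.5 ns window (`locate_scan_minimum`).  Replicate counts are set to
60,000 / 30,000 / 15,000 at N = 250 / 1000 / 10000, spending replicates
where photons are cheap; across independent seeds this pins the fitted
optimum to 3.17 ± 0.04 ns and the minimum F to 1.24–1.26.  The simulated
time range is 0–50 ns so effectively all photons of a 2 ns decay are
included.

## Unmixing and phasors

Per-pixel abundances come from unconstrained least squares on the linear
mixture model (one precomputed pseudo-inverse for a whole image), with
non-negative least squares available as an option; unconstrained results
are reported because negative excursions carry information and clipping
would bias the accuracy metric.  Fractions are the coefficients
normalized by their sum, kept unclipped.  Endmembers can be estimated
from the pure-abundance ends of a gradient image (replicate-mean
signature of the first and last gradient column, renormalized).  Accuracy
is the mean of `true − estimated` for the reference fluorophore;
precision is the replicate standard deviation per gradient column,
averaged and multiplied by √N.  Ordinary least squares is not the
efficient estimator for Poisson noise, so measured precision sits above
the Fisher bound, but the dimensionality ordering (HDIM best, then SLIM,
then SPEC) holds at all three photon levels both analytically (via the
delta method on the least-squares covariance) and empirically.

Phasor transforms are *unnormalized* first-harmonic cosine/sine
projections, `Σ_t c_t cos(2π(t+½)/n)` and the sine analogue, so they are
exactly linear in counts and the mixture equation survives the reduction
— unmixing in phasor space of a noise-free mixture is exact.  Normalized
(divide-by-total) variants exist for display.  The 16-coefficient
hyper-dimensional reduction comprises: time phasors per polarization per
spectral half (8), spectral phasors per polarization (4), and joint 2-D
time–spectrum phasors per polarization (4).  The spectral halves split at
the middle bin (535 nm on the default grid — the nominal 540 nm
boundary is not bin-aligned); the exact component list is a package
reconstruction constrained by the total of 16, and tests require the
reduced analysis to stay within 20% of full-grid unmixing precision at
1,000 photons per pixel.

## Configuration and reproducibility

Runs are described by YAML/JSON configs (fluorophore blocks in ns/nm
units, grid blocks defaulting to the reference acquisition).  Every CLI
report includes a manifest with the package version, seed and a config
hash, sufficient to reproduce the run bit-for-bit.  All random sampling
flows through `numpy.random.Generator` seeded explicitly.

## Limitations

Decays are single-exponential (no FRET kinetics, no multi-exponential
mixtures), anisotropy is a single rotator, spectra are unimodal with a
fixed shape family, and the instrument response, background, detector
afterpulsing and pile-up are not modeled.  Optimizers treat each
detection axis as an independent 1-D partition (full grids are evaluated,
not jointly co-optimized) and are greedy/local, without global optimality
guarantees.  Passing tests on the synthetic generator demonstrates
correctness of the information calculus and estimators under ideal
Poisson statistics; real detectors add losses and correlated noise that
these figures do not capture, so measured F-values should be read as
lower bounds on achievable performance.  Excitation-wavelength
multiplexing is representable only implicitly, as extra independent
channels.
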