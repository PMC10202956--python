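# Methods

## The model

A podosome is modelled as two coupled force-generating processes. Actin
polymerization drives the protrusive core against the substrate; the
protrusive force `Fp = ks·l1` resists further polymerization through the
stall relation `Vp = Vpm(1 − Fp/Fsp0)`, with the stall force saturating in
substrate stiffness, `Fsp0 = Fp0·ks/(kc + ks)`. The core is held by ventral
actin filaments at angle θ carrying ring tension `Fr = Fp/cosθ`, produced by
an active myosin element `Fm` in parallel with a passive spring `kf`.
Myosin recruitment is mechanosensitive (Rho–ROCK): ring tension feeds back
positively with gain α, filament shortening reduces it with coupling γ, and
the force relaxes with turnover time τm:

    d(l + l1)/dt = Vpm(1 − Fp/Fsp0) − Vd + χp(t)
    τm dFm/dt + Fm = Fm0 − γ(xr − xr0) + α Fr + χm(t)

Geometry closes the system: `xr·cosθ = l`, `height = l + l1`, and
`Fr = Fm + kf(xr − xr0)` exactly. In force variables the pair becomes a
linear two-dimensional system whose behaviour is governed by two groups:

    Γ  = (α·kf − γ)/(kf − γ) · ks/(ks + kf)      (signalling feedback)
    τp = (Fsp0/Vpms)(1/kf + 1/ks)(1 − γ/kf)      (protrusion timescale)

with eigenvalues

    ω₁,₂ = [Γ − 1 − τm/τp ± √((Γ − 1 − τm/τp)² − 4 τm/τp)] / (2 τm).

Oscillations require comparable timescales (τm/τp ~ 1) and intermediate
feedback; the stable-oscillation boundary is Γ = 1 + τm/τp. Near that
boundary the period is `T ≈ 2π√(τm·τp)`.

**A consistency caveat.** The closed-form eigenvalues above match the exact
Jacobian of the force-variable ODE pair only to leading order in γ/kf (the
exact eigenvalues acquire a factor 1 − γ/kf). The model assumes stiff
passive filaments (kf ≫ γ); the package defaults set γ = 0, where the
closed form is exact, and the stability module documents the approximation
for γ > 0.

In a cluster, each podosome consumes G-actin while growing and releases it
while retracting; monomers diffuse between podosomes:

    ∂ca/∂t = Da ∇²ca − µ · d(l + l1)/dt,     Vpm = Vp0 + β·ca.

Linearizing gives a damped diffusion-wave equation with complex wavenumber
`q = √(−(iω + ωp)/Da)`, effective consumption rate `ωp = µβVd/Vpms`,
wavelength `λ = 2π/|Re q|`, spatial damping length `1/|Im q|`, phase angle
`φ = arctan(ω/ωp) − π`, and wavefront speed `v_c = λ/T`. Substrate
stiffness enters twice: through `Fsp0(ks)` and through `µ ∝ ks` (denser
cores on stiffer substrates turn over more monomer), so stiffer substrates
support faster, longer-ranged waves.

## Parameter calibration

The experimental literature pins the model's *outputs* — steady protrusive
force ≈ 10 nN, ventral filament length ≈ 1 µm, total core height ≈ 700 nm,
oscillation period ≈ 400 s, wave correlation length ≈ 3 µm, pattern
lifetime ≈ 5 min — rather than its microscopic inputs. The defaults were
therefore calibrated, once, in three steps (`scripts/calibrate_cluster.py`
reruns step 3):

1. **Geometry and statics.** θ = 60° so that with ks = 50 nN/µm the steady
   observables close exactly: l1 = Fps/ks = 0.2 µm, l = xr·cosθ = 0.5 µm,
   height = 0.7 µm, xr = 1 µm. (A 30° cone cannot reach a 700-nm height
   with xr = 1 µm, since l alone would be 866 nm; only cosθ enters the
   equations, so this is the entire sensitivity to θ.) Fp0 = 40 nN with
   kc = ks gives Fsp0 = 20 nN, and Vd/Vpms = 1/2 gives Fps = 10 nN.
2. **Timescales.** kf = 25 nN/µm, γ = 0 and Vpms = 0.01875 µm/s make
   τp = 64 s exactly; τm = 64 s matches it, and α = 2.75 puts
   Γ = 11/6 ≈ 1.83 in the damped-oscillation regime with eigenperiod
   403.5 s (≈ 400 s at the 15-s / 6000-s FFT resolution). The split
   Vp0 = 0.00375, β·ca_ref = 0.01125 + base makes polymerization mostly
   G-actin-driven, which keeps the concentration field positive at the
   coupling strength waves require.
3. **Cluster coupling.** µ and Da were chosen by a seeded grid search
   scoring the fitted correlation decay length ξ (target ≈ 3 µm) and the
   kymograph patch lifetime (target ≈ 5 min) under the reference protocol
   (30×30 µm domain, ±30% random initial heights, 4000 s, h = 0.5 µm).
   Frozen values: µ = 2.05, Da = 0.0275 µm²/s, giving ξ ≈ 2.9 ± 0.2 µm and
   lifetime ≈ 4.7 ± 0.3 min under the replicate-averaged estimators the
   acceptance script uses. The implied diffusion length
   √(Da·T) ≈ 3.3 µm is consistent with the λ ~ √(DaT) ≈ 3 µm estimate that
   motivated the model. At this coupling the cluster sits at the margin of
   a collective finite-wavenumber instability; individual runs either decay
   slowly or saturate into a sustained wave state, which is the main source
   of seed-to-seed spread in the stochastic observables (see below). The
   two targets pull against each other: stronger coupling lengthens patch
   lifetimes but tips more seeds into the over-synchronized state where the
   correlation length diverges, so the frozen point is the joint optimum,
   with the lifetime centring a few percent below 5 min.

Default noise intensities for noise-sustained single-podosome runs are
σp = 0.001 µm·s^−1/2 and σm = 10 nN·s^1/2 (the `ModelParams` default is
noise-free); they produce height fluctuations of a few percent of the mean
with clearly visible quasi-cycles, matching the qualitative appearance of
LifeAct intensity traces.

## Numerics

* Noise-free integration uses fixed-step classical RK4; noisy runs use
  Euler–Maruyama with additive increments of SD σ√dt at dt ≤ τp/100.
  Fixed steps make every run bit-reproducible given its seed.
* The cluster uses an explicit method of lines on a uniform grid with a
  5-point no-flux Laplacian; the step must satisfy dt ≤ h²/(4Da) (the
  integrator raises otherwise, suggesting a step). Because the G-actin
  sink is exactly the height rate and height is affine in (Fp, Fm), the
  total ∫ca dA + µ∫height dA is a *linear* invariant and is conserved to
  round-off by any Runge–Kutta scheme — this is tested, not assumed.
* Discrete mode places podosomes on a d0-spaced lattice (h ≤ d0/2). The
  default sink/read discretization is area-weighted cloud-in-cell over the
  four surrounding cells; nearest-cell deposition (`deposition="cell"`) is
  available but concentrates each podosome's self-coupling ≈4× above the
  coarse-grained limit, which at the calibrated µ tips the cluster past the
  wave threshold. With CIC, discrete and continuum correlation lengths
  agree to a few percent.
* Concentrations are floored at zero with a warning counter; flooring
  breaks the conservation identity, so a clipped run is flagged.
* The regime classifier uses crisp eigenvalue labels with deterministic
  tie-breaks (zero discriminant → critically damped/monotonic; zero real
  part → sustained boundary). Note that formally-oscillatory labels can be
  *overdamped* (quality factor Im/(2|Re|) ≪ 1, e.g. the Y27632 preset at
  τm = τp); tests treat quality < 0.5 as effectively monotonic.
* The dispersion branch is the principal square root, sign-flipped if
  needed so Im(q) < 0 (decay in +r); the ωp → 0 phase-angle limit −π/2 is
  taken explicitly.

## Analytics

* **Amplitude ratio**: plain rectangular-window DFT of the mean-subtracted
  trace (no window, no detrend), one-sided sinusoid normalization; the
  ratio is the mean of the four largest non-DC bin amplitudes over the raw
  trace mean, and the dominant period is the largest peak's reciprocal
  frequency.
* **Pair correlation**: the printed 1/(N−1) Pearson convention with sample
  standard deviations; pairs are binned by Euclidean distance and the
  binned means fit by exp(−d/ξ)·cos(2πd/λ_f) for d ≤ 10 µm (the cosine
  absorbs the anticorrelation lobe of noise-free oscillations). ξ is the
  reported characteristic length. The reference window is the *last*
  25 min of the run: the random initial condition is spatially white, and
  during roughly the first two periods the measured correlation length
  reflects that initial noise rather than the developed wave field.
* **Patch lifetime**: the kymograph (heights averaged across the short
  axis of a rectangle) is binarized at 1.05× the steady height; connected
  components (4-connectivity) in the position × time plane with spatial
  extent ≥ 2 grid cells are wave patches, and the lifetime is the
  component's time extent. Travelling ridges remain connected along their
  diagonal track, so wave states produce patches that outlive any fixed
  point's half-period visibility window — this is what makes ~5 min
  lifetimes possible with a 400-s period.
* **STICS**: overlapping 32×32-px ROIs (shift 4) and 5-frame TOIs
  (shift 1); per tile, FFT-based normalized spatial cross-correlation
  averaged over frame pairs at each lag, a symmetric 2-D Gaussian fit
  within 8 px of the CF centre, and a linear lag fit of the peak
  displacements gated at R² ≥ 0.9 with ≥ 3 points (largest lag dropped and
  refit otherwise; lags whose peak reaches the fit-window edge are not
  used). QC also caps speeds at 2 µm/min by default. Optional immobile-
  population filtering subtracts the TOI-mean image; a σ = 7 px Gaussian
  prefilter is available for wave-propagation movies.

## What the synthetic data does and does not emulate

The generator renders LifeAct-like movies: intensity proportional to core
height, isotropic Gaussian puncta, 0.14 µm/pixel, 15-s frames, optional
Poisson shot noise and exponential bleaching. It does **not** emulate
stage drift, uneven illumination, camera read noise, podosome birth/death,
or lateral podosome motion. Passing the image-analysis suites therefore
shows the estimators are correct on their stated model, not that they are
robust to every artifact of real microscopy. The translation fixtures for
STICS validation are toroidal (spots wrap), making the imposed velocity
exact for correlation estimators; real ROIs see content enter and leave,
which is the main reason recovered speeds carry a residual few-percent
negative bias.

## Known limitations

* At the calibrated coupling, the collective wave mode's period
  (~500–560 s) exceeds the isolated podosome's 403 s; period preservation
  inside a cluster holds only for weak coupling (µ ≲ 0.5). Both values lie
  within the 5–8 min range reported for measured podosome oscillations.
* The cytochalasin-D preset (τm/τp ≪ 1 at Γ ≈ 1.83) is linearly unstable —
  monotonic growth — so a bare single-podosome cytoD trace has no bounded
  amplitude ratio; cytoD behaviour is exercised through regime
  classification and through cluster runs, where G-actin depletion bounds
  the growth.
* Problem sizes used by the test suite and the acceptance script (domain
  30×30 µm at h = 0.5 µm, 4000-s runs, ≤ 64–128-px fixture movies, 5
  cluster replicates) were chosen so that ξ and lifetime estimates have
  standard errors comfortably below the ~10% scatter of the quantities
  themselves; larger domains mainly add statistics, not new physics.
* Stochastic observables (ξ, patch lifetime) have intrinsic ~10–30%
  seed-to-seed spread at the marginal coupling; the acceptance script
  averages replicate runs and multiple kymograph rectangles to report
  stable means.
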