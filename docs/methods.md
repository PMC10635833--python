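# Methods

`condmech` analyzes the mechanics and transport of protein condensates
(droplets) probed by dual optical traps, FRAP, particle tracking and
ratiometric imaging. Every analysis operation has a matching synthetic-data
generator built as its exact algebraic inverse, so the whole pipeline is
validated by parameter-recovery round trips rather than against deposited
recordings.

## Unit system

Forces in pN, lengths in µm, stiffnesses in pN/µm, moduli in Pa,
frequencies in Hz. Because 1 pN/µm² = 1 Pa, spring constants divided by a
length in µm give Pa directly, with no conversion factor. Angular
frequency ω = 2πf (rad/s) is used wherever a drag or Maxwell product ξω or
ωτ appears; all user-facing frequencies are in Hz.

## Dual-trap active microrheology

A droplet is held between two traps (stiffnesses k₁, k₂, calibrated by
ordinary least squares of force on displacement over a ±100 nm window);
trap 1 is driven sinusoidally with amplitude A = 100 nm over octave-spaced
frequencies 0.5–64 Hz.

1. **Lock-in.** For each frequency segment, the single-bin discrete
   Fourier projection returns the complex amplitude S = X + iY of a signal
   X·sin(ωt) + Y·cos(ωt). The projection is exact when the segment spans
   an integer number of cycles; the generator enforces this by choosing
   segment lengths from the exact rational fs/f (continued-fraction
   reduction), which removes spectral leakage by construction.
2. **System spring constant.** χ*\_sys = (F̃₁ − F̃₂)/(2 x̃\_sys), with
   x\_sys the commanded trap-1 coordinate reversed in sign (trap 2 held
   fixed).
3. **Trap and drag correction.**
   χ* = χ\_sys·[4k₁k₂ + iξω(k₁+k₂)] / (2k₁(2k₂+iξω) − 4χ\_sys(k₁+k₂+iξω)),
   where ξ = 3πη_medium·D is the translational drag of a sphere of
   diameter D in the surrounding medium (η_medium = 1 mPa·s by default).
   Frequencies where the denominator vanishes are flagged and dropped.
4. **Capillary correction.** The droplet spring constant contains both the
   bulk modulus and surface tension γ:
   G* = [χ* − (1.25 + 4.36θ₀²)γ] / [R·P(θ₀)], with contact polynomial
   P(θ₀) = 5.47θ₀⁵ − 29.28θ₀⁴ + 23.29θ₀³ − 5.08θ₀² + 3.79θ₀ − 0.02 and
   θ₀ the contact parameter (sine of the contact half-angle).
5. **Maxwell fit.** G*(ω) = iωτE/(1 + iωτ) with τ = η/E is fitted jointly
   to G′ and G″ with relative residuals (lmfit/least squares), because the
   moduli span decades over the sweep. The crossover ω_c = E/(2πη) (Hz) is
   reported with a 95% CI from first-order propagation of the (E, η)
   covariance; fits whose crossover falls outside the measured band are
   flagged `extrapolated`.

**Surface tension at rest.** Opposed force steps of amplitude A give
Δx₀ = A + F₀⁽¹⁾/k₁ − F₀⁽²⁾/k₂, χ₀ = (F₀⁽¹⁾ − F₀⁽²⁾)/(2Δx₀) and
γ = (χ₀/π)(−ln θ₀ + 0.68). Step relaxations F(t) = F₀ + (F_p − F₀)e^(−t/τ)
are fitted per trap after aligning and averaging the step segments.

**Generator.** The forward model encodes
χ\_sys = 2k₁(2k₂+iξω)χ*/[4k₁k₂ + iξω(k₁+k₂) + 4χ*(k₁+k₂+iξω)] — the exact
inverse of step 3 — with an antisymmetric force split F₁ = −F₂, so the
noiseless round trip recovers E, η and γ to machine precision. Noise can
be additive (`noise_sd_force`, pN) or multiplicative (`noise_relative`).

**Stiff-trap limit.** At ξ = 0 the coupling reduces to
χ\_sys = χ*/(1 + χ*(1/k₁ + 1/k₂)), so the relative deviation between
χ\_sys and χ* is ≈ |χ*|(1/k₁+1/k₂): 2% at a 100× stiffness ratio and below
0.5% only from 400× up. The acceptance test therefore uses a 500× ratio
and additionally checks the first-order scaling.

## FRAP

Double normalization (reference-corrected) followed by full-scale
rescaling:
I_dn(t) = [⟨tot−bg⟩_pre/(tot(t)−bg)] · [(roi(t)−bg)/⟨roi−bg⟩_pre],
I_fs(t) = (I_dn(t) − I_dn(t₀⁺)) / (1 − I_dn(t₀⁺)). Background is the mean
of the background ROI over all frames (a per-frame background would only
inject noise). When the whole punctum is bleached the total-ROI
normalization is biased; `bleach_rate_correction=True` renormalizes
through an unbleached reference ROI instead. The recovery is fitted to
I(t) = Mf(1 − e^(−τt)) (lmfit); t½ = ln2/τ and the Soumpasis estimate
D = 0.224·r²/t½ for bleach radius r. Fits with Mf > 1.1 or flat curves
are flagged. The generator constructs ROI traces whose acquisition
bleaching cancels exactly in the normalization, making the normalized
truth exactly Mf(1 − e^(−τ(t−t₀))). Default frame schedule: 5 prebleach
@371 ms, 5 bleach @344 ms, 10 @371 ms, 10 @20 s.

## Motion

MSD uses overlapping pairs within each track, averaged across tracks with
pair-count weights, up to `max_lag_fraction = 0.25` of the track length.
The power-law exponent comes from ordinary least squares of log MSD on
log lag. **Mobility**: a track is mobile if its net end-to-end
displacement ≥ 2 µm or its drift speed (net displacement / duration)
≥ 0.2 µm/s. Drift speed, not path-length speed, is used deliberately:
with 0.05 µm localization noise at 10 Hz the apparent path speed of a
stationary punctum is ≈0.7 µm/s, which would invert the classifier.
Interpunctum intervals come either from given positions or from peak
detection (`scipy.signal.find_peaks`) on an intensity profile. Morphology
uses `skimage.measure.regionprops` with the Crofton perimeter estimator —
the default chain-code perimeter underestimates thin objects enough to
make a one-pixel line look round — and roundness 4πA/P².

## Imaging

**FRET.** Sensitized emission cF = (I_DA−bg) − d(I_DD−bg) − a(I_AA−bg)
with donor-bleedthrough d and acceptor-cross-excitation a estimated by
Theil–Sen slopes on single-label controls (≥100 pixels above background
required). FRET index = cF/((I_DD−bg) + cF), evaluated inside an Otsu
mask of the acceptor channel; it is invariant to a common gain on all
three channels. The load analysis reports Pearson ρ between FRET index
and indentation together with two statistics: the standard Pearson
t-test, and the literal ratio t = ρ/r_ω with r_ω the half-width of the
Fisher-z 95% CI of ρ. The ratio is reported as specified but it is not a
calibrated test statistic; the standard t-test carries the inference.

**Colocalization.** Pearson ρ with a block-scramble null: the
straightened-neurite image is cut into along-axis column blocks (default
16 px ≈ 5 µm at 0.3 µm/px; at least 4 blocks required) whose order is
permuted, preserving the intensity histogram and within-block structure
while destroying cross-channel alignment. p_emp = (1 + #{|ρ_null| ≥
|ρ_obs|})/(n_perm + 1). With 100 permutations the achievable p-values are
k/101, giving a rejection rate of 5/101 ≈ 0.0495 at α = 0.05 under
independence — verified over 1000 seeded runs.

**Calcium.** ΔF/F = (F − F₀)/F₀ with F₀ the mean of the baseline window
and optional moving-average smoothing; a window of 1 is the identity.

## Orchestration

A run is one YAML/JSON config (unknown keys rejected by name; stage-
required calibration constants checked up front). Stages run in
dependency order; a failing stage aborts with the stage name and the
offending file while earlier outputs remain on disk. Every run echoes its
effective configuration plus a content hash, and equal config + seed
yields byte-identical outputs. Reporting is best-effort: modulus spectra
with the Maxwell overlay and crossover marker, Lissajous ellipses (area
πA²Im χ, the energy dissipated per cycle), FRAP overlays and log-log MSD.

## Problem sizes and defaults

Defaults are desk-scale and chosen for the validation suite, not for any
specific instrument: 5 kHz sampling, ≥10 drive cycles per frequency,
droplet D = 5 µm, θ₀ = 0.5, traps at 50 pN/µm, 100 nm drive, 128–256 px
test images. All are parameters, not constants.
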