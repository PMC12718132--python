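# Methods

`smstoich` implements the quantitative core of a single-molecule
brightness-stoichiometry study: deciding whether a membrane receptor
diffuses as a monomer, dimer or higher oligomer from the brightness of
individual diffraction-limited spots in TIRF movies, with photobleaching
step counting and FRET photometry as orthogonal checks. Because no public
raw data accompany such experiments, the package ships a synthetic movie
generator with complete ground truth; every stage of the analysis is
validated by parameter recovery against that ground truth.

## The brightness model

A fluorescent spot's integrated intensity under TIRF follows a skewed,
log-normal distribution — the dominant fluctuation source is the motion of
the molecule through the evanescent excitation field. We model the
per-frame photon output of an emitter carrying `m` active fluorophores as

    photons = m · L,     L ~ LogNormal(μ_log, σ_log),

with a single fluctuation factor `L` per emitter per frame, shared by all
fluorophores of the complex (they ride through the field together). Under
this model the brightness of a pure n-mer population is exactly log-normal
with geometric mean `n · exp(μ_log)` — which is precisely the assumption the
downstream analysis makes: the calibration ladder expects `g_n = n · g_1`,
and the two-component mixture pins the dimer component at twice the monomer
geometric mean. An alternative model with independent per-fluorophore
fluctuations would make an n-mer's brightness a *sum* of log-normals, whose
geometric mean exceeds `n·g_1` by `exp(σ²(n−1)/2n)` (≈2% for a dimer at
σ = 0.35); we chose the shared-factor model both for physical plausibility
and because it is the generative model of the fitted family.

The geometric mean `exp(mean(log v))` is the central-tendency statistic
throughout; for log-normal data it is the MLE of the distribution median
and is insensitive to the heavy right tail.

## Synthetic data generator (`simulate`)

Default parameters reproduce the emulated acquisition: 250×250 px frames at
84 nm/px, 50 ms exposure, 400 frames (one 20 s analysis window), emitter
density 0.06 /μm², camera gain 0.22 photons/ADU. Remaining defaults are the
package's own choices of realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| `psf_sigma_um` | 0.125 | diffraction-limited PSF for green emission at NA 1.45 |
| `mu_log` | ln 200 | single-fluorophore geometric mean of ~200 photons/frame at 50 ms |
| `sigma_log` | 0.35 | typical single-molecule brightness spread under TIRF |
| `labeling_efficiency` | 0.8 | fluorescent-protein maturation is incomplete; not stated by any source, exposed in config |
| `bleach_rate_per_s` | 0.01 | mean fluorophore lifetime 100 s ≫ the 20 s window — the regime in which window-averaged brightness is insensitive to photobleaching, as the assay requires. (At 0.05 /s the apparent dimer/monomer factor drops from 1.53 to 1.32, i.e. bleaching would dominate.) |
| `diffusion_um2_per_s` | 0.1 | lateral mobility typical of a membrane GPCR |
| `background_photons` | 10 /px/frame | low TIRF background |
| `read_noise_adu` | 7 | ~1.6 e⁻ rms sCMOS read noise at 0.22 photons/ADU |
| `cell_log_jitter_sd` | 0.05 | ±5% cell-to-cell illumination/expression variation of the log-brightness scale |

Mechanics: the emitter count is Poisson(density × area); oligomer sizes are
drawn from `oligomer_fractions`; each subunit carries a matured fluorophore
with probability `labeling_efficiency` (so an n-mer's active count at frame
0 is Binomial(n, p)); fluorophores bleach independently with exponential
lifetimes; positions follow free 2-D Brownian motion with reflecting
boundaries. The PSF is a symmetric 2-D Gaussian integrated over pixel areas
(error-function differences), truncated at 5σ. Photon images receive
Poisson shot noise, are converted to ADU (both gain conventions —
photons-per-ADU and ADU-per-photon — are supported via `adu_convention`),
and Gaussian read noise is added. `shot_noise=False` with zero read noise
yields exact noiseless expectations for oracle tests. `min_separation_um`
switches the initial positions to a hard-core (dart-throwing) layout with a
half-separation edge margin, used for well-separated control spots.

Coordinates: continuous positions in μm with the origin at the outer corner
of pixel (0,0); the centre of pixel `i` is at `(i + 0.5)·pixel_size`.
Frames are 0-based in memory and 1-based in localization CSV files.

`sample_cell_brightness` is the generative model with the optics and camera
stripped away: it returns the per-detection photon values (one per visible
emitter per frame) directly. It is the fast path for replicate-level
statistical experiments; the rendering + detection path is validated
separately and the two agree on the brightness law (tested).

What the generator does *not* emulate: fluorophore blinking/dark states,
3-D PSF structure, EM-gain excess noise, emitter exchange with
out-of-frame membrane, and detection-induced selection biases at low SNR.
Passing tests therefore demonstrate correctness of the *analysis* under the
stated model, not robustness to every real-data artifact.

## Spot detection (`detect`)

Two interchangeable front-end filters: a difference-of-Gaussians band-pass
(σ₁ = diameter/4 in px, σ₂ = 1.6 σ₁; default, with the standard 0.5 μm
estimated diameter) and an à-trous B-spline wavelet (second plane). Both are
linear and reject constant backgrounds; at high SNR they produce the same
localization set (tested to 0.2 px).

Candidate spots are local maxima of the filtered frame above a threshold
expressed in filtered-image ADU (mirroring "15 to 25 AU" style settings);
`threshold=None` selects `median + max(10·MAD·1.4826, 5% of peak response)`,
which behaves sensibly on both noisy and noiseless frames. Maxima within
⌈2σ⌉ px of the border are discarded; non-maximum suppression enforces
`min_separation_px`.

Each candidate is refined by least-squares fitting of a pixel-integrated 2-D
Gaussian (x, y, σ, amplitude, background) in a window of radius
`round(est_diameter_um / pixel_size)` px (≈ 0.5 μm), on the photon-converted
image. The reported intensity is the *volume* of the fitted integrated
Gaussian minus background — not a fixed-aperture sum — making it robust to
σ variation and exact on noiseless data. Localization tables read and write
ThunderSTORM-compatible CSV headers.

Detections are pooled over the analysis window (400 frames at 50 ms);
every detection is one brightness sample, with no track-level
deduplication by default (an optional greedy linking deduplicator exists but
is off, matching the pooling analysis).

## Brightness fitting and classification (`brightness`)

*Single log-normal.* The primary fit is the closed-form MLE in log space
(`μ = mean(log v)`, `σ = sd(log v)`); the literal histogram procedure
(bin-width-1 frequency histogram least-squares-fitted with a scaled
log-normal density) is retained as a cross-checked alternative — the two
agree on geometric means to <3% at n = 10⁴ (tested). Zeros/negatives after
background subtraction are dropped and counted.

*Two-component mixture.* Components share σ; the dimer geometric mean is
pinned at 2× the monomer one (`constrain_ratio=True`). Fitting is by EM
with multi-start over the monomer fraction f. One-channel brightness data
cannot distinguish "all monomers at g" from "all dimers at 2g", so:
(i) with a same-day monomer calibration supplied, the monomer position and
σ are anchored to it and only f is estimated (the identifiable, recommended
procedure); (ii) without a calibration, near-equal-likelihood solutions are
tie-broken toward the higher monomer fraction, so a one-component sample
reads as pure monomer. An unconstrained variant (free second component) is
available behind a flag. An optional incomplete-labeling correction treats
a visible dimer as a Binomial(2, p | ≥1) mixture of one- and two-fluorophore
states; it is off by default.

*Density correction.* Apparent brightness rises with molecule surface
density (random overlaps); per-cell (ρ, G_mean) points are fitted by OLS
(`G_mean = ρ·k + G_i`, statsmodels), per trial, and the intercept `G_i`
with its 95% CI is the density-corrected intrinsic brightness.

*Classification.* Per-cell geometric means of the test condition are
compared against monomer/dimer/trimer control cohorts: D'Agostino–Pearson
normality and Bartlett homoscedasticity gates choose between one-way ANOVA
with Dunnett's post hoc (sample as the reference) and Kruskal–Wallis with a
Bonferroni-adjusted Dunn rank post hoc. By default all tests run on
log-geometric means, the scale on which the normal/equal-variance
assumptions can actually hold for log-normal brightness; the classification
is invariant to this monotone transform. The verdict is the unique control
the sample is *not* significantly different from (α = 0.05);
"indistinguishable-from-all" when the omnibus test is not significant, and
"ambiguous" when no or several controls match.

## Step counting (`steps`)

Traces are median-filtered (width 3) for change-point *detection* only;
levels are re-estimated on raw data. Optimal piecewise-constant
segmentations for 0..max_steps change points are computed by dynamic
programming on the exact least-squares cost (O(k n²), all orders in one
pass); upward level changes are removed by merging (pure bleaching is
monotone); the model order is selected by BIC (default; conservative at low
SNR) or AIC. Benchmarks define the per-trace truth as the number of
*sampling intervals* containing at least one bleach event: two fluorophores
bleaching within one frame produce a single observable (double-height) step
that no algorithm can split. At step-height SNR 5 the counter is exact on
≥95% of traces for 1–3 fluorophores (500 traces/class, bleach rate 0.1 /s,
50 ms sampling over 60 s).

## FRET photometry (`fret`)

Donor-excitation dual-emission photometry gives F480 (donor) and F535
(acceptor) channels contaminated by donor spillover α, acceptor spillover β
and direct acceptor excitation γ. The forward model

    F480 = F_D + β·F_A
    F535 = α·F_D + F_A + γ·A_ref        (acceptor-only reference given)
    F535 = α·F_D + (1+γ)·F_A            (no reference: direct excitation
                                         proportional to the acceptor signal)

is inverted *exactly* (2×2 linear system, denominator 1−αβ resp. (1+γ)−αβ)
at every time point, rather than by sequential approximate subtraction, so
the round trip on synthetic data is exact to machine precision. Both ratio
orientations (F_D/F_A and F_A/F_D) are reported as labelled columns; points
with non-positive corrected channels are masked with a warning. Coefficient
values are instrument-specific and are required config inputs.

Photobleaching baselines are fitted as a mono-exponential (linear fallback)
on stimulus-free samples only and subtracted (default) or divided out,
anchored at the first sample; a level change confined to the stimulus
window cannot be attributed to bleaching and raises an error (heuristic:
both flanking stimulus-free intervals internally flat, >5 SE apart, and the
within-interval slopes explain <20% of the jump).

Acceptor-photobleaching efficiency is the donor-dequenching form
`E = 1 − CFP_before/CFP_after`; negative values are returned but flagged.
Activation/deactivation kinetics are fitted with
`y = baseline + A·(1 − e^{−(t−t₀)/τ})` with data-driven starts (pre-onset
mean, late plateau, 63% crossing time); y is standardised internally so τ
is invariant under affine rescaling of the response.

## Pipeline and reproducibility (`pipeline`, `cli`)

A single global seed expands into named substreams via
`derive_seed(seed, *labels)` (SeedSequence over the seed plus CRC-32 of
each label), so any stage or cell can be regenerated independently.
`make_stoichiometry_dataset` provides presets at the published cohort sizes
(controls 73/24/75/68 cells, receptor 47/52; monomer:dimer mixing ratios
10:0 … 5:5), scalable by a round-half-up factor. `run_pipeline` executes
simulate → (detect) → fit → classify from a YAML/dict config, validates
pre-flight (nothing runs on a bad config) and writes per-cell fits, the
classification report and a manifest with SHA-256 hashes of all outputs;
reruns with the same seed are byte-identical. The `smstoich` CLI exposes
`sim`, `detect`, `steps`, `fit`, `density-correct`, `classify`, `fret`,
`run` and `make-dataset` (exit codes: 0 ok, 2 validation, 3 runtime).

## Problem sizes and numerical choices

Replicate-level experiments (mixing-ratio sensitivity, monomer-fraction
comparison, end-to-end classification; 100 replicates each) run on the
detection-level brightness sampler at the published cohort sizes — the
rendering + detection chain is exercised on its own reduced-scale movies
(a few thousand spots), which is where optical fidelity is actually at
stake. Mixture-comparison cells use 80-frame (4 s) windows, ~2×10³
detections/cell; ladder and recovery fits use ≥10⁴ detections. Degenerate
inputs raise typed errors rather than returning silent values: all-equal
samples (σ undefined), <3 regression points or all-equal densities,
constant kinetic traces, non-positive CFP-after, stimulus-window-confined
trends. EM uses 9 starts (5 in replicate loops), tolerance 1e-8 on the
log-likelihood; the kinetic fit uses tolerances 1e-14.

## Known limitations

- No blinking or dark-state photophysics; step counts and brightness assume
  pure bleaching.
- The mixture model is two-component with a fixed 2× ratio; genuine trimer
  admixtures would be absorbed into f rather than detected.
- Density correction assumes artifacts linear in density over the
  experimental range (~0.01–0.12 /μm²).
- The detector's Gaussian refinement is least squares, not MLE; its
  precision is ~1.3× the CRLB at high SNR, sufficient for brightness work.
- The uncorrectable-trend detector in `photobleach_detrend` is a heuristic;
  pathological baselines (oscillations on the bleach timescale) can evade
  it.
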