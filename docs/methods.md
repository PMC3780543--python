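# Methods

This note records the statistical models, estimator design, numerical
choices, and limitations behind burstkit. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The telegraph model and what the data identify

A gene switches between an inactive and an active promoter state with
first-order rates *a* (activation) and *b* (inactivation); while active it
initiates transcripts at rate *c*; mRNA decays at rate *d*. Fixed-cell
snapshots are informative only about the decay-normalized ratios
α = a/d, β = b/d, γ = c/d: the absolute time scale cancels at stationarity,
so *d* is never estimated from count data. Live-cell traces, in contrast,
resolve absolute dwell times in minutes. The two views are linked by the
active fraction α/(α+β) = a/(a+b) and the stationary mean γ·α/(α+β).

Assumptions inherited from the model: a single two-state promoter (no
refractory or multi-state cycles), exponential dwell times, Poissonian
initiation within the active state, first-order decay, and cell-to-cell
homogeneity of (β, γ) within a condition. Frequency modulation additionally
assumes a = k·dose with b, c, d dose-independent.

## Stationary PMF: stable evaluation and an independent oracle

`telegraph_pmf` evaluates

P(n) = [Γ(α+n)Γ(α+β) / (Γ(n+1)Γ(α+β+n)Γ(α))] γⁿ ₁F₁(α+n; α+β+n; −γ).

Direct evaluation of ₁F₁ at a negative argument overflows or cancels
catastrophically already around γ ≈ 100, far below the γ ≈ 340 regime of a
strong reporter. We therefore apply the Kummer transformation
₁F₁(α+n; α+β+n; −γ) = e^(−γ) ₁F₁(β; α+β+n; γ), whose series has all-positive
terms, and sum it in log space with log-sum-exp. Two implementation details
matter for speed: the Pochhammer ratios (β)ₖ/(α+β+n)ₖ live on the lattice
Γ(α+β+m), m = 0..n_max+K, so one `gammaln` vector serves every (n, k) pair by
indexing; and the series is truncated at K = γ + 12√γ + 40 terms (the tail
decays like a Poisson(γ) tail), processed in blocks to bound memory. Edge
cases are exact: γ = 0 gives the point mass at zero; β = 0 gives Poisson(γ).

`cme_oracle` is the package's independent check: it assembles the truncated
generator of the joint (promoter state, copy number) Markov chain in sparse
form, solves the stationary balance equations by sparse LU with an explicit
normalization row, and marginalizes the promoter state. It shares no code
path with `telegraph_pmf`; the test suite verifies elementwise agreement
within 1e-6 on a 27-point (α, β, γ) grid, and the agreement threshold is the
test's, not a fitting tolerance.

Default truncation (`default_n_max`) is mean + 12 SD + 60; `telegraph_pmf`
warns when the left-out tail exceeds 1e-6.

## Binned maximum-likelihood fitting

Copy-number histograms are fit by multinomial maximum likelihood with bin
probabilities equal to the PMF summed over each bin (bin width 100 mRNA by
default, matching the field's convention for histograms of strong reporters),
the final bin open-ended so truncation mass is accounted for exactly.
Two modes share one code path: a single condition with (α, β, γ) all free,
and a joint dose series with shared (β, γ) and one α per dose — the
frequency-modulation parameterization.

Optimization is L-BFGS-B on log-parameters (positivity for free), multi-start
from a method-of-moments-flavoured guess (γ₀ from the data range, β₀ = 1,
α₀ from the group means) perturbed by a seeded Latin-hypercube design with
multiplicative factors up to 6; ties between starts break by log-likelihood,
then by smaller γ. γ is capped at 30× the top occupied bin edge: the
conditional law given a long active period is Poisson(γ), so the data range
bounds plausible γ, and the cap keeps the hypergeometric series finite along
optimizer excursions. Parameters ending within ~0.1% of a bound are flagged
(`boundary_flags`) — in particular β → 0 on Poisson-like data, where the
always-on ridge leaves β unidentified. Uncertainty is by parametric bootstrap
(resampling from the fitted law via the exact Poisson–beta representation and
refitting from the point estimate); it is opt-in (`bootstrap(n_boot=200)`)
because a 200-replicate bootstrap of a joint six-dose fit is two orders of
magnitude more work than the fit itself.

## Hill fitting and the correspondence

`HillRegressor` is weighted nonlinear least squares on
A_max·xʰ/(EC50ʰ + xʰ), weights 1/SE² when per-point standard errors are
supplied, unweighted otherwise; `fix_h` freezes the coefficient (the
two-parameter fit). Initialization: A_max ← max response, EC50 ← dose nearest
half-max, h ← 1. Standard errors come from the fit covariance
(`absolute_sigma` when weights are real SEs). With frequency modulation the
telegraph means are *identically* a first-order Hill curve (A_max = γ,
EC50 = β/k); the test suite checks this identity to machine precision, and a
free-h fit to frequency-modulated synthetic means returns h ≈ 1.

## Synthetic data

`simulate_counts` with `horizon="steady"` draws exact stationary samples via
the Poisson–beta mixture representation (p ~ Beta(α, β), n ~ Poisson(γp)) —
no burn-in, no discretization error, fast at 5000 cells per dose. Transient
horizons (induction from the inactive, mRNA-free state) use the exact
stochastic simulation algorithm; frames and snapshots interrogate the exact
trajectory, never a tau-leaped one.

`simulate_trace` simulates the promoter and its initiation events exactly,
then forms the site intensity at each frame as the number of initiation
events in the trailing `nascent_dwell` window plus Gaussian measurement
noise. Each nascent transcript thus contributes one intensity unit for a
fixed residence time (default 5 min, the elongation time scale of a ~7 kb
reporter at typical polymerase speeds; configurable, since elongation rates
are construct-specific). Modes: `steady` (initial state from the stationary
law, event history pre-filled over one nascent window), `induction` (starts
off, silent), `pulse` (starts active once, never reactivates — the
single-activation scenario), `always_on` (b = 0, the non-chromatinized
reporter limit). Defaults for the trace experiments: 15-min frames over 15 h
(60 frames), initiation rate 2/min (≈70 transcripts per ~36-min burst,
consistent with ~170 mRNA/cell at half-active saturation and a ~3 h mRNA
lifetime), on-state intensity 10 units, noise SD 2 (SNR 5). The hidden state
sequence, true dwell intervals, and initiation times are returned for oracle
testing.

`render_image` renders 2-D Gaussian spots of width `psf_sigma` (integrated
signal amplitude·2πσ²) over a constant background, optionally over painted
elliptical cells/nuclei which are themselves PSF-blurred (a camera never sees
step edges), with Poisson shot noise and Gaussian read noise. Truth (spot
list, structures) is retained as a JSON sidecar.

One integer seed drives everything; per-cell/trace/image streams are split
with `numpy.random.SeedSequence`, so outputs are bit-identical given the seed.

What the generators do **not** emulate: extrinsic cell-to-cell parameter
variability, cell division and mRNA partitioning, photobleaching, 3-D optics
(images are born 2-D), diffusing cytoplasmic particles, and promoter models
with more than two states. Parameter-recovery results on these synthetics
therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to their violation.

## Trace segmentation and dwell-time estimation

Traces are segmented with a two-state Gaussian-emission HMM (Baum–Welch +
Viterbi, via hmmlearn) with k-means-based initialization and five seeded
restarts; states are relabeled so "on" is the higher emission mean. The
published algorithm this analysis descends from is variational-Bayes, but
with two states and a binary decoding target EM is equivalent in practice
and standard. Normalization before fitting is a (5th, 95th)-percentile
rescale, per trace when traces are fit individually and with a single global
window when many traces are fit jointly (per-trace windows would blow
noise-only traces up to full scale and corrupt a pooled fit). Convergence:
log-likelihood change below 1e-8 or 500 iterations. A trace set whose two
fitted means are closer than 2 pooled emission SDs is declared effectively
single-state and decodes all-off — this is what makes vehicle controls
(noise only) report ~zero occupancy rather than segmenting their noise.

Decoded paths are run-length encoded into dwells (duration = run length ×
frame interval, so dwells sum to the trace duration); the first and last runs
are censored. `fit_dwell_exponential` is the exponential MLE — the sample
mean of uncensored dwells, or (total observed time)/(uncensored count) when
censored dwells contribute survival terms.

**Frame sampling is the dominant bias at 15-min frames.** With dwell means
near 35 min, naive run-length means overshoot badly: dwells shorter than a
frame are missed entirely, merging the neighbouring runs of the opposite
state. Two corrections are provided, in increasing order of fidelity:

1. `estimate_switching_rates` — the frame-sampled state of a two-state
   continuous-time Markov process is itself an exact Markov chain with
   p(off→on) = π_on(1 − e^(−rΔt)), p(on→off) = π_off(1 − e^(−rΔt)); counting
   transitions and inverting this map gives closed-form MLEs of the rates,
   unbiased with respect to discretization (the test suite verifies this on
   true sampled state sequences). Standard errors by the delta method.
2. `calibrate_dwell_means` — the decoder sees intensity, not state: nascent
   transcripts persist for the residence window, so sub-window dwells are
   smoothed away and even the rate MLE retains a residual upward bias. The
   calibrated estimator removes it by indirect inference: candidate dwell
   means are iterated (multiplicative secant, common random numbers) until
   traces simulated at the candidate kinetics, pushed through the *same*
   fitted decoder and the same rate statistic, reproduce the statistic
   observed on the data. It assumes the acquisition/emission configuration
   (frame interval, nascent residence time, initiation rate, noise) is known
   or assumed — true by construction for synthetic studies, a modelling input
   for real data. Convergence is typically 3 iterations.

The pipeline reports the rate-MLE dwell means per dose alongside the naive
run-length means; the headline dwell recoveries in the acceptance script use
the calibrated estimator.

## Spot analysis

Coordinates are 0-based (row, col) with spot centers in sub-pixel units at
pixel centers, everywhere. Detection: difference-of-Gaussians band-pass
(σ, 3σ), local maxima above a robust threshold (5 × 1.4826·MAD of the
band-passed image by default, or a manual value). Localization: iterative
Gaussian-mask centroid at the fixed PSF width — background-subtracted
weighted centroid updates until the shift is below 1e-3 px — with photometry
Σw(I−bg)/Σw², the least-squares amplitude of a unit Gaussian (integrated
intensity = amplitude·2πσ²). Candidates whose local signal does not
correlate with the PSF (centered Pearson correlation on the ±3 px window
below 0.6) are rejected; this is what separates diffraction-limited spots
from the boundary ridges of extended structures, which band-pass thresholds
alone cannot do. Refined detections within 1 px merge, keeping the brighter.

Segmentation: nuclei by intensity threshold on a spot-suppressing smoothed
image — Otsu for two-class images, the upper multi-Otsu threshold when a
cell-body channel is present, or a manual override (manual adjustment is a
supported mode, not an error path) — followed by area filtering and removal
of border-touching nuclei; cells by watershed on the smoothed intensity
seeded from the nuclei, so cell label k contains nucleus k.

Counting: spots are assigned to the cell label under their center; nuclear
spots at least `ts_rule` (default 2) × the median single-spot intensity are
called transcription sites. The median-intensity TS rule is an operational
stand-in for by-eye brightness classification; the factor is configurable.
TS can optionally count as round(intensity/median) mRNA-equivalent units.

Tracking: optimal (minimal total displacement) frame-to-frame assignment
within `max_jump` px, with gaps up to `max_gap` frames bridged at zero
intensity — absence of nascent signal is evidence for the off state, so
traces span the full acquisition.

## Pipeline and problem sizes

`run_dose_pipeline` chains counts → joint telegraph fit → per-dose means →
Hill fits (free and fixed h) → a report that confronts the two
parameterizations (A_max vs γ; EC50 vs β/k̂ with k̂ the least-squares slope of
α on dose). `run_trace_pipeline` chains traces → pooled HMM per dose → dwell
summaries and mean TS intensity. Reports are flat JSON plus tidy CSV, stamped
with the seed and a config hash; identical config + seed reproduces reports
byte-identically.

Problem sizes in the shipped tests and acceptance script are the package's
chosen study conditions: 6 doses × 5000 cells (bin width 100) for joint
distribution fitting; 500 traces × 60 frames for dwell recovery; 60 cells
per dose for Hill fits on means (matching the per-dose sample size such
dose-response panels typically use; at that size a three-parameter fit's
saturation estimate carries a standard error of several percent, so the
dedicated saturation-recovery test evaluates the median of five seeded
replicate series). Unit tests use smaller versions of the same designs.

## Known limitations

- All fitting assumes the two-state model; real promoters with refractory
  off-states or multi-state cycles will bias β and the dwell shapes.
- The calibrated dwell estimator conditions on an assumed observation model
  (nascent residence time, initiation rate, noise); misspecifying those
  propagates into the dwell means.
- The HMM treats frames as conditionally independent given the state;
  nascent-window carry-over correlates adjacent frames and is only corrected
  at the dwell-mean level, not in the decoder itself.
- Spot counting assumes resolvable (non-overlapping) single molecules;
  crowded cytoplasm at very high expression undercounts, which is why
  distribution fitting at high means uses intensity-integrated bins rather
  than raw spot counts.
- Images are 2-D by construction; there is no 3-D localization or
  deconvolution.
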