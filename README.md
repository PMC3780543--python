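# burstkit

Quantitative analysis of **frequency-modulated transcriptional bursting** in
steroid-induced gene expression — for researchers who measure transcription
one molecule (or one locus) at a time and want to connect a classical
sigmoidal dose response to the digital on/off behaviour of single genes.

Most genes transcribe in bursts: the promoter toggles between an inactive and
an active state, and a steroid ligand could in principle steepen the dose
response by lengthening bursts, loading more polymerases per burst, or making
bursts more frequent. burstkit implements the analysis chain that
discriminates these possibilities, exercisable end-to-end on synthetic data
with known ground truth.

## The model

The **random telegraph model**: a gene activates at rate *a*, inactivates at
rate *b*, initiates transcripts at rate *c* while active, and mRNA decays at
rate *d*. Snapshot (smFISH) data identify the decay-normalized parameters
α = a/d, β = b/d, γ = c/d. The stationary copy-number distribution is

```
P(n) = Γ(α+n) Γ(α+β) / [Γ(n+1) Γ(α+β+n) Γ(α)] · γⁿ · ₁F₁(α+n; α+β+n; −γ)
```

with mean ⟨N⟩ = γ·α/(α+β) and active fraction α/(α+β). Under **frequency
modulation** — the ligand dose changes only the activation rate, a = k·[L] —
the mean is *exactly* a first-order Hill curve

```
⟨N⟩([L]) = A_max·[L] / (EC50 + [L]),   A_max = γ,  EC50 = b/k
```

so a Hill coefficient of 1 at the population level is the signature of pure
burst-frequency control. burstkit provides:

- `simulate` — exact (Gillespie / analytic-stationary) generators for
  per-cell mRNA counts, transcription-site (TS) intensity traces, and
  diffraction-limited spot images, all with recorded ground truth;
- `telegraph` — the stationary PMF evaluated stably in log space, an
  independent truncated-master-equation oracle, and joint maximum-likelihood
  fitting of binned copy-number histograms across a dose series (shared β, γ;
  per-dose α);
- `hill` — weighted Hill fits (free or fixed coefficient) and the
  telegraph correspondence;
- `hmm` — two-state hidden-Markov segmentation of TS traces, dwell-time
  extraction with boundary censoring, exponential dwell fits, and
  discretization-aware dwell estimators for frame intervals comparable to
  the dwells themselves;
- `spots` — nucleus/cell segmentation, Gaussian-mask sub-pixel spot
  localization, per-cell mRNA counting with TS calling, and frame-to-frame
  TS tracking;
- `pipeline` / `burstkit` CLI — config-driven orchestration of the
  fixed-cell (dose response) and live-cell (trace kinetics) arcs.

## Worked example

Simulate a six-dose series (1000 cells per dose) at β = 1.5, γ = 340 with
activation linear in dose, fit the full copy-number distributions jointly,
and compare with the Hill view of the per-dose means:

```python
import numpy as np
from burstkit import (TelegraphParams, DoseMap, TelegraphFitter, HillRegressor,
                      simulate_dose_series)

series = simulate_dose_series(
    TelegraphParams(a=0.0, b=1.5, c=340.0, d=1.0),
    DoseMap([1.56, 3.125, 6.25, 12.5, 25.0, 50.0], activation_scale=1.5 / 9.6),
    n_cells_per_dose=1000,
    seed=0,
)
fit = TelegraphFitter(bin_width=100, n_starts=4, random_state=0).fit(
    series.table.mrna_count, series.table.dose_uM
)
print(f"shared b/d = {fit.beta_:.2f}   shared c/d = {fit.gamma_:.1f}")
for dose, a in zip(fit.group_labels_, fit.alpha_):
    print(f"  dose {dose:>6} uM: a/d = {a:.3f}")

g = series.table.groupby("dose_uM")["mrna_count"]
hill = HillRegressor(fix_h=1.0).fit(
    g.mean().index, g.mean().to_numpy(), se=(g.std() / np.sqrt(g.size())).to_numpy()
)
print(f"Hill (h=1): A_max = {hill.amax_:.0f} mRNA/cell, EC50 = {hill.ec50_:.1f} uM")
```

prints

```
shared b/d = 1.60   shared c/d = 345.1
  dose   1.56 uM: a/d = 0.242
  dose  3.125 uM: a/d = 0.557
  dose   6.25 uM: a/d = 0.984
  dose   12.5 uM: a/d = 1.935
  dose   25.0 uM: a/d = 3.933
  dose   50.0 uM: a/d = 7.920
Hill (h=1): A_max = 342 mRNA/cell, EC50 = 9.8 uM
```

The shared burst parameters come back at their generative values (β = 1.5,
γ = 340), the per-dose activation estimates are proportional to dose
(a/d ≈ 0.156·dose, i.e. k = β/EC50), and the Hill fit to the same data
recovers A_max ≈ γ and EC50 ≈ β/k — the frequency-modulation correspondence.
Because 50 µM sits only ~5× above the EC50, the fitted saturation reflects γ
(full saturation), not the response at the top measured dose.

The live-cell arc is analogous:

```python
from burstkit import RunConfig, run_trace_pipeline
report = run_trace_pipeline(RunConfig(mode="trace_kinetics", seed=1))
```

decodes simulated 15-h TS traces at four doses and reports per-dose on/off
dwell means (off-times fall with dose; on-times stay flat) plus the decoded
active fraction.

## Command-line interface

```sh
burstkit simulate counts|traces|images|dose-series --out ... --seed ...
burstkit fit-counts counts.csv --out fit.json --bin-width 100
burstkit fit-hill response.csv --out hill.json --fix-h 1.0
burstkit fit-traces traces.csv --out dwells.csv --report summary.json
burstkit detect-spots field.tif --out spots.csv
burstkit run --config run.yaml
```

Exit codes: 0 success, 2 validation error, 3 convergence failure.

See `docs/methods.md` for the statistical methods, estimator design,
numerical choices, and known limitations.
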