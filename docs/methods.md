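# Methods

## Model

The synaptic current model treats a single inhibitory (GABA_A) synaptic
event under somatic voltage clamp. The conductance waveform is the standard
phenomenological double exponential
`g(t) = w·(exp(−t/τ_d) − exp(−t/τ_r))` with rise and decay time constants
τ_r < τ_d. A minimal transsynaptic layer modulates it: cleft
neurotransmitter `N` is driven by `β·α_f·g(t)·NLG2` and cleared at rate
α_b; adhesion-pair level `NLG2` follows Michaelis–Menten production
(maximum `Nlmax = GEPH`, half-saturation `Nhalf = GEPH/2`, `F(GEPH) = 1`)
with turnover φ; receptors `Ry` are inserted at `h·GEPH` and removed at
`h₁·Ry`. The recorded current is `I = c₁·N·Ry·(v − e_rev)`.

Assumptions: the gephyrin level is constant over the few tens of
milliseconds of one event, and `NLG2` and `Ry` sit at their steady states
(`NLG2_ss = GEPH(2−φ)/(2φ)`, requiring φ < 2; `Ry_ss = (h/h₁)·GEPH`)
throughout the event — their dynamics are slow relative to a single event.
Under these assumptions the `N` equation is linear with a double-exponential
drive and the current is available in closed form (see the `models` module
docstring). The closed form is the exact solution of the stated ODE system;
`integrate_ode` integrates the full three-variable system numerically and
the two agree to better than 1e−6 of the peak, which is asserted over 100
random parameter draws.

Two structural facts drive everything downstream:

- **Amplitude lumping.** The shape of the current depends only on
  (α_b, τ_r, τ_d, t₀); every other parameter enters through the scalar
  `I_FACT = c₁·(h/h₁)·GEPH²·(2−φ)/(2φ)·β·α_f·w`. A single trace therefore
  identifies at most (I_FACT·(v−e_rev), α_b, τ_r, τ_d, t₀); the h↔h₁,
  GEPH²↔c₁ etc. trade-offs inside I_FACT are pure degeneracies, and the
  ensemble analysis shows them as strong rank correlations.
- **Rate symmetry.** The amplitude-free shape is the triple convolution of
  `e^(−α_b t)`, `e^(−t/τ_r)` and `e^(−t/τ_d)`, hence invariant (up to
  scale) under any permutation of the three rates. The three rates are
  attributable to their roles only because their allowed bands are
  disjoint: rise rates 2–20 /ms, clearance 0.35–2 /ms, decay
  0.05–0.33 /ms. The default clearance band (α_b ∈ 0.4–1.8 /ms, i.e.
  clearance time constants ≈0.6–2.5 ms) is both the physically expected
  fast-clearance regime for GABA leaving the cleft and the one that yields
  times-to-peak of 0.2–2 ms, as observed somatically.

The singularities of the closed form at α_b = 1/τ_r and α_b = 1/τ_d are
removable; vectors within 1e−6 of either are rejected (`GUARD_EPS`) rather
than special-cased — the guard composes naturally with the exclusion-rule
machinery, and cancellation error remains ~1e−10 at the guard boundary.

Sign convention: traces are stored as recorded (inward negative, since the
holding potential is below the chloride reversal potential); event traces
and model evaluations used in fitting carry positive magnitudes.

The bi-exponential alternative model is peak-normalized: the normalization
factor makes the conductance maximum equal the `weight` parameter (the
common built-in convention of the simulator dialect its parameter names
come from). This is a documented dialect choice.

## Preprocessing

Parameters, with defaults and why:

- **Baseline window, 5 ms.** The mean of the 5 ms preceding the detected
  onset is subtracted; the onset is the last pre-peak sample within 3
  baseline-noise SDs of a first-pass baseline. A pre-event segment at
  least this long is required.
- **Moving window, max(1 ms, 20·dt) capped at 5 % of trace duration.**
  Wide enough to span the fastest rise (τ_r ≥ 0.05 ms) while averaging
  noise; adapted per trace.
- **Detection, 10 % of global peak.** An event begins where the smoothed
  magnitude rises by more than 10 % of the trace's peak magnitude across
  the moving window. The statistic is directional (a *rise*), because a
  symmetric range statistic splits one event into rise and decay regions
  with a dead zone at the peak. A robust floor of 5× the MAD-estimated
  noise scale of the rise statistic keeps pure-noise traces from
  generating windows; small noisy events that do slip through are caught
  later by the RMSE threshold, mirroring how such traces are handled in
  practice.
- **Clipping, 20 % of peak.** The event is cut at the first post-peak
  sample (of a 3-sample median-filtered copy, to resist lone noise spikes)
  at or below 20 % of the peak; the index maps back to the unfiltered
  trace. This keeps late small events out of the decay.
- **Rejection.** Events with less than 5 ms retained after the peak are
  `rejected_short`; events whose successor begins before the 20 % decay
  point are `rejected_overlap`. Both pass through the fitting layer as
  recorded states, never exceptions.

The pipeline is deterministic: identical input gives identical output.

## Configuration dialect

A plain-text file with five fixed sections (fitted parameters with initial
values; bounds; dependency rules; exclusion rules; warning exemptions)
fully specifies a fitting run; the printed double-exponential example
parses verbatim, including the `^*^` typographic variant of `*`. Names are
opaque and mapped to model parameters through per-model alias registries,
so simulator-style names (`syn[0].tau1`, `nc[0].weight`, `nstim.start`)
work unchanged. Expressions are restricted to names, numbers, `+ − * / ^`,
comparisons and parentheses — deliberately not a general language.
Dependencies evaluate in declaration order and may not reference targets
assigned later. The warning section is read as "all except": every fitted
parameter is outlier-checked unless listed. Unknown or out-of-order section
headers fail loudly. A canonical serializer makes parse → serialize →
parse the identity.

Three configurations ship: `gephyrin` (all 12 parameters free — the
ensemble/degeneracy workhorse), `gephyrin_reduced` (the identifiable set
c₁, α_b, τ_r, τ_d, onset — the recovery workhorse), and `biexp`.

## Fitting

- **Cost**: RMSE between model and the retained (clipped) samples, in pA;
  accepted when below 10 % of that event's peak amplitude. The
  `running_mean` variant replaces the data by its centered running mean
  (window = the preprocessing moving window) before the residual.
- **Optimizer**: `praxis_minimize` wraps the Powell direction-set method
  (the principal-axis family) with scipy's truncated-line-search box
  bounds, restarted from the incumbent whenever a pass converges but the
  previous restart still improved the objective. The restart resets the
  search directions to the coordinate axes, which is what escapes the
  curved, ill-conditioned valley the amplitude/rate trade-off produces.
  The budget (`max_iter`, default 3000) counts objective evaluations — the
  enforceable unit — and the best point seen is always returned.
  Tolerances: line-search `xtol = 1e−6`, `ftol = 1e−14`, restart
  improvement threshold 1e−12 relative; all deterministic given the start.
- **Multi-start**: starts are uniform within bounds (default 100;
  exclusion-violating draws are redrawn), seeded per (trace, start) as
  `seed + 10⁴·trace_index + start_index`, so results are bit-identical
  regardless of how traces are distributed over worker processes.
- **Onset**: the onset time is a fitted parameter, but its bounds are
  narrowed to ±2 ms around the detected onset of each event.
- **Warnings**: an accepted fit with a warned parameter within 1 % of the
  bound range of either bound is flagged as an outlier — boundary-pinned
  parameters indicate non-identifiable or misspecified fits.
- **Exclusions**: vectors violating an exclusion rule are rejected at the
  start draw, penalized during search, and filtered at the end; they never
  appear in ensembles.

## Synthetic data

The generator emulates the recordings this tool targets: 20 kHz-like
sampling (dt = 0.05 ms) over 80 ms with onset at 20 ms; peak amplitudes
drawn from a 4-parameter pseudo-Voigt restricted to 10–100 pA (defaults
follow one of the measured per-experiment amplitude distributions; all
five printed parameter sets are available); τ_r uniform in 0.05–0.5 ms,
τ_d in 3–20 ms, α_b in 0.4–1.8 /ms (resampled if within 0.05 of a
singularity); white noise of 2 pA SD (or a stated fraction of each trace's
peak); a holding offset uniform in [−60, −20] pA; and with probability 0.1
a second event of 30–100 % relative amplitude starting 1–20 ms after the
first peak. The target amplitude is realized by solving for c₁ given the
sampled kinetics, keeping amplitude statistically independent of kinetics
— which is what makes the recovery and time-to-peak analyses meaningful.
Datasets regenerate bit-identically from (spec, seed).

What the generator does *not* emulate: 1/f and series-resistance noise,
acquisition artifacts, event-train temporal statistics, dendritic
(cable-filtered) events, and model misspecification — real synapses do not
follow the fitted kinetic scheme exactly. Passing recovery tests therefore
demonstrate the correctness and precision of the machinery under the
model's own assumptions, not the fidelity of the model to biology.

## Ensemble analysis

Pooled analyses use the best fit per trace by default (using every
accepted fit would over-weight clean traces, which admit many good fits);
full ensembles are available for trace-level analyses. The Spearman screen
highlights |ρ| > 0.2 and refuses constant columns. Grouped comparisons run
a Kruskal–Wallis omnibus first and flag pairs only if it is significant at
α (default 0.05), using Dunn's rank-based z post-hoc (implemented
in-package: pooled ranks, tie correction `Σ(t³−t)/(12(N−1))`, family-wise
adjustment — classical Bonferroni-style by default, Holm or none by
option) or Tukey's HSD via statsmodels for the time-to-peak style
analysis. Pseudo-Voigt histogram fits use fixed 5 pA bins over the
observed range and report the Pearson R between curve and bin heights.

## Problem sizes and numerical checks

The shipped validation (test suite and `scripts/acceptance.py`) runs the
recovery experiment at 50 traces per condition with 10 starts × 2000
evaluations on the 5-parameter reduced configuration — sizes chosen so the
full validation completes in minutes while leaving the conclusions
unchanged from larger runs. Noiseless events are recovered essentially
exactly (median errors below 0.01 % for α_b, τ_r, τ_d and the lumped
amplitude, median RMSE ~1e−7 of peak). With noise at 5 % of peak, median
errors are ≈7 % for α_b, ≈1–2 % for τ_d and ≈6 % for the amplitude factor;
τ_r is the exception (≈35 % median): at 20 kHz a 0.05–0.5 ms rise places
only ~1–10 samples on the rising phase, so the rise constant is
information-limited at that noise level regardless of optimizer. This is a
resolution limit of the data, and it is reported rather than hidden.

Degenerate inputs are handled by refusal with specific exceptions:
non-positive rates, τ_r ≥ τ_d, φ ≥ 2 (non-positive steady state, also
expressible as the shipped exclusion rule), singular-guard violations,
zero driving force, constant columns in correlation, too-short traces.
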