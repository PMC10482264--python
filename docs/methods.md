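# Methods

## The trace model

The package's central object is a scalar *memory trace* per stimulus.  A
presentation of duration *d* (seconds) encodes intensity
`1 − exp(−g·d)` — saturating so that very long exposures cannot dominate
without bound; a linear law `g·d` is available via
`TraceParams(encoding="linear")` for sensitivity analyses.  After offset
the intensity decays as `exp(−λ·t)` with a single rate λ (per second).
Repeated presentations of the same stimulus add.  A sequence is therefore
represented as an *unordered* map from stimulus identity to intensity:
order information exists only insofar as the earlier stimulus has decayed
longer.  With λ = 0 the representation of AB and BA is identical — the
formal statement of order blindness that the sequence-discrimination
contrast exploits.

Choice among the on-screen options is a softmax with inverse temperature β
over the intensities, mixed with a lapse ε toward uniform.  Simulated
single-trial readout instead perturbs the intensities with zero-mean
Gaussian noise (s.d. σ; a Weber-style multiplicative variant,
`noise_model="weber"`, is available) and takes the maximum; the two
readouts agree in the sense that the analytic softmax is the smooth
counterpart used for likelihoods while the noisy argmax generates
behaviour.  Decision time is the onset of the response options, taken to
follow the last sample offset after the scheduled delay with no additional
rendering latency.

Defaults: g = 1 /s, λ = 0.5 /s, σ = 0.3, β = 3, ε = 0.02.  The gain and
unit trace scale are a normalization (only β·m and σ relative to m are
identified); λ = 0.5 gives a trace half-life of ~1.4 s, in the range that
produces above-chance zero-delay matching yet near-chance 10-s-delay
matching; σ = 0.3 is of the order of the trace differences the sequence
task produces, so confusions are common but sample/foil discrimination is
easy — both features of the behaviour being emulated.

Two closed forms:

* retention: `P(correct | delay) = c + (1 − c)·a·exp(−λ_r·delay)`, bounded
  in [c, 1] by construction, with c the two-option chance level (0.5);
* probe prediction: the conditional probability of choosing the first of
  two probe samples among four options (two foils at intensity 0),
  conditioned on a sample being chosen.  It is non-decreasing in the first
  duration, non-increasing in the second, equals 0.5 at equal durations
  with λ = 0, and drops below 0.5 under any positive decay (recency).

## Task schedulers

The three simulated paradigms implement the source designs' composition
guarantees exactly: 5/5 colour and correct-side balance per 10-trial
matching window; 0-s delays on every odd trial of the delayed phase with
the non-zero delays {2, 5, 10} s drawn as shuffled balanced triples
("pseudo-random" is not otherwise defined, so balanced shuffling was
chosen — it makes long-run per-delay counts exact); 18-trial sequence
blocks of 9 AB + 3 AA + 3 BA + 3 BB (AB → left, rest → right); and one
unrewarded probe per 10-trial block at a uniformly random position, with
probe samples drawn without replacement from the 20-item pool and options
= both samples + two foils.  Sequence stimuli last 1 s with a 0.3-s gap;
the same gap is used inside probe sequences, and the retention interval
between the second probe stimulus and the options is 0 s (unstated in the
source; both are config arguments).  Error blackouts affect only session
time, not learning.  Counterbalanced colour naming is metadata — agents
never see colour names, only stimulus identities.

## Agents

`TraceAgent` perceives, on sequence trials, only the pair of
noise-perturbed trace intensities at decision time, and maps the feature
vector (m_A, m_B, 1) to left/right action values by a linear model trained
with the delta rule (normalized step `α / max(1, ‖x‖²)`, which keeps the
rule stable at any noise scale; α = 0.1).  Notably, the four-sequence task
is *not linearly separable* in trace space even with λ > 0 (AB lies
between BB and BA along the m_A − m_B axis), so the agent hovers near
chance on the order discrimination while still showing type-specific
biases — the qualitative pattern of the trace-limited subjects it
emulates.  On matching trials it takes the noisy-max readout over the
option traces.

`FaithfulAgent` receives the ordered sequence as a lossless key and learns
tabular action values with learning rate 1 and ε-greedy exploration
(ε = 0.1).  Values start optimistic (0.5, between the 0 of an error and
the 1 of a reward) so a single unrewarded mistake eliminates an option;
this yields criterion passage within ~20–30 trials, the human-like
signature.

`run_task` executes a schedule, enforces the agent/option contract,
re-inserts failed sequence trials as correction trials until answered
correctly, never rewards probes, and emits a `TrialLog` that serializes to
a one-row-per-trial CSV.  The CSV schema includes a `sample_ids` column
(pipe-joined) in addition to durations, because probe analyses must know
which option was the first sample; logs round-trip through the reader with
full equality.

## Statistics

The exact two-sided binomial p-value uses the minimum-likelihood
convention (sum all outcome masses ≤ the observed mass, with a 1 + 1e-7
relative tie tolerance), matching standard statistical software; the
chi-square test is the plain Pearson statistic with margin-derived
expectations and no continuity correction by default.  Binomial masses and
χ² tail areas come from scipy; the summation and statistic are implemented
here and cross-checked in the tests against `scipy.stats.binomtest` /
`chi2_contingency` and against a 2^n enumeration oracle.  Learning
criterion: first trial whose trailing 20-trial window within a session
reaches ⌈0.8·20⌉ = 16 correct; windows never straddle sessions.  Block
performance includes correction trials (as the source scoring did);
trailing partial blocks are reported with their own n and flagged.
Per-delay summaries use Wilson 95% intervals (the CI flavour is a
parameter).

## Fitting

Both fits are binomial maximum likelihood with bounded L-BFGS-B from 8
fixed starting points and an objective tolerance of 1e-8.  The retention
fit estimates (a, λ_r) with a ∈ [0, 1], λ_r ∈ [0, 50].  The trace probe
fit pins g = 1 and ε = 0 by default and estimates (λ, β): with six
conditions and ~20 choices each, (g, λ, β) are jointly weakly identified,
and g is a scale normalization once β is free.  Any pin can be overridden
(`fixed=`), including fully pinned models, which makes the
equal-probability null expressible for likelihood-ratio tests.
Confidence intervals are profile likelihood (re-optimizing the other free
parameter on a bisection search for the χ²(1)/2 drop), not Wald, because
the counts are small.  When the fit does not improve on the
equal-probability null by more than 1e-6 in deviance the result carries a
`flat_likelihood` diagnostic — the graceful report for order-information-
free data, and the expected outcome on chance-level probe tables.
`recovery_study` runs the simulate-and-refit loop and reports bias, RMSE
and CI coverage per free parameter, deterministically per seed.

## Synthetic studies

`generate_study` emits a full study bundle: 4 trace-limited subjects
(delayed MTS, 2,304 sequence trials before corrections = 128 blocks,
probe phase of 120 probes) and 5 order-faithful subjects (sequence task),
plus ground-truth JSON with every parameter and seed.  Per-subject
parameters are log-normally jittered (s.d. 0.1) around the cohort means to
emulate between-subject spread.  DMTS accuracy is drawn directly from each
subject's retention curve (cohort means a = 0.72, λ_r = 0.35 /s, giving
~86% at 0 s, ~68% at 2 s, ~56% at 5 s, ~51% at 10 s — the observed
pattern); the sequence and probe logs are generated mechanistically by
`TraceAgent`.  Regeneration with the same master seed is byte-identical.

What the generator does *not* emulate: real session structure and refusal
patterns, unequal per-delay exposure between subjects, motivational
drifts, stimulus-specific salience, or any within-condition response
correlations.  Passing tests on synthetic data therefore show that the
pipeline and estimators behave as designed under the model's own
assumptions — not that real subjects obey the model.

The transcribed probe-count fixtures reconstruct trial logs from published
per-condition counts; the within-condition response order in those logs is
invented (marked synthetic in the metadata) and no analysis here depends
on it.

## Problem sizes and numerical choices

The validation suite uses: retention recovery at 1e5 trials per delay
(estimates within ±0.02 of truth); trace-decay recovery over 50
simulate-and-refit replicates at 2,000 choices per condition (profile-CI
coverage ≥ 90%); the agent contrast over 100 seeded runs each (faithful
criterion < 100 trials in ≥ 95%; order-blind trace agent inside the
two-sided 99% chance band on balanced AB/BA accuracy in ≥ 95%).  The
balanced accuracy (mean of per-type accuracies on first-attempt trials) is
used for the chance band because side biases — which the reward structure
encourages on the shared AB/BA trace state — cancel in it exactly.
Likelihood computations clip probabilities to [1e-12, 1 − 1e-12];
deviances more negative than −1e-8 raise an optimization error rather
than being silently clamped.

## Known limitations

* The trace model here is one concrete instantiation (exponential
  encoding/decay, softmax readout); the underlying hypothesis constrains
  the representation, not these functional forms.
* The probe fit's identifiability is marginal at study-sized counts (six
  conditions × 20 probes); this is faithfully reflected in wide profile
  CIs and the flat-likelihood diagnostic rather than hidden.
* Agents have no motivational state, no session effects, and no
  stimulus-identity generalization; the faithful agent's one-shot learning
  is an idealization of "learned almost immediately", not a model of human
  learning dynamics.
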