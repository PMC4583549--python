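# Methods

This note documents the models, the task protocols the package
simulates, the likelihood and fitting machinery, the synthetic-data
generator, and the numerical and design choices made where more than one
reasonable option existed.

## The betasort model

Each stimulus *i* of an *n*-item list carries four non-negative tallies:
positional evidence *U_i* (top of the unit span) and *L_i* (bottom), and
outcome counts *R_i* (rewarded trials containing *i*) and *N_i*
(unrewarded). All start at zero for a fresh session and may become
fractional through decay. The position belief is the beta density
`Beta(x; U_i + 1, L_i + 1)`; the +1 offsets act as a uniform prior and
keep the density proper when tallies are zero. The point estimate is
`V_i = U_i / (U_i + L_i)`, defined as 0.5 when both tallies are zero.

A trial executes **choice → relaxation → feedback**:

* **Choice.** One uniform draw per trial decides whether memory is
  consulted: with probability τ every visible stimulus receives an
  independent Uniform(0,1) value, otherwise stimulus *i* receives
  `X_i ~ Beta(U_i + 1, L_i + 1)`. The largest value wins; exact ties
  (impossible under continuous draws, relevant only for degenerate
  generators) break uniformly at random. The per-trial noise draw was
  chosen over a per-stimulus draw so that the simulator agrees exactly
  with the closed-form choice probability used for fitting (the τ/2
  mixture term below); we also measured the per-stimulus variant and it
  behaves slightly worse on the massed-trial robustness benchmark, so
  nothing argues for it.
* **Relaxation.** `R_i ← ξ·R_i`, `N_i ← ξ·N_i`; then with recent reward
  rate ρ = R/(R+N) the extra factor `ξ_R = ρ/(ρ+1) + 0.5` (1.0 for a
  perfect record, 0.5 for an all-failure record) scales the positional
  evidence: `U_i ← ξ_R·ξ·U_i`, `L_i ← ξ_R·ξ·L_i`. When `R_i + N_i = 0`
  we set `ξ_R = 1`: no evidence should trigger no extra forgetting, and
  the choice is inert at session start because the tallies are zero
  anyway. Relaxation never moves any `V_i` (both shapes scale equally);
  it only widens the distributions.
* **Feedback.** Position estimates `V` are snapshotted from the relaxed
  memory before any update. On reward, every stimulus — present or not —
  is consolidated: `U_i += V_i`, `L_i += 1 − V_i`, which adds one unit
  of evidence mass at the current position, exactly preserving `V_i`.
  On non-reward, the chosen stimulus gets `L_ch += 1`, the unchosen one
  `U_nc += 1`; each absent stimulus is consolidated if
  `V_nc ≥ V_i ≥ V_ch` (boundary equalities consolidate — the symmetric
  treatment that avoids double updates), pushed up by one if
  `V_i > V_nc`, and pushed down by one if `V_ch > V_i`. The two unit
  pushes are independent conditions: when the pair's estimates are
  inverted (`V_ch > V_i > V_nc`) both apply, which is the literal
  reading of the piecewise update and self-corrects the inversion.
  Finally the outcome is tallied for the present stimuli only
  (`R += 1` on reward, else `N += 1`).

Consolidating the *absent* stimuli is the implicit-inference step: it is
what converts adjacent-pair feedback into a calibrated ordering of the
whole list, and what protects the ordering when one pair is massed.

**betaQ** uses the identical choice policy and relaxation but restricts
feedback to the two stimuli on screen: reward consolidates the pair,
non-reward applies only the `L_ch`/`U_nc` unit pushes. This is the
minimal restriction consistent with classical associative assumptions,
and isolates what implicit inference contributes.

**Q/softmax** keeps one value per stimulus, initialised to 0.5, with
delta-rule updates `Q_i ← Q_i + α·δ_i` where `δ_i = 1 − Q_i` when the
outcome favours *i* (rewarded and chosen, or unrewarded and not chosen),
`δ_i = −Q_i` otherwise, and zero for absent stimuli. Choices are
softmax: `p(i) ∝ exp(β·Q_i)` over the present set, computed with
max-shifting so large β cannot overflow. A chosen-stimulus-only variant
(`symmetric_update=False`) is provided; matched-seed simulations show
its accuracy curves are nearly indistinguishable from the symmetric
form. Values stay in [0, 1] by the form of the update for α ∈ [0, 1],
so no clamp is applied.

## Task protocols

The reward rule is deterministic: choosing the item earlier in the
latent order is rewarded. Stimuli are indexed 0..n−1 (lettered A.. in
files), index 0 being the earliest. Blocks are counterbalanced for
screen position: each scheduled pair appears once per left/right
arrangement within a block, in a uniformly random order. Screen position
is recorded for data fidelity but has no effect on any model.

* *Full protocol* ("monkey"): 20 blocks of the 6 adjacent pairs
  (240 trials), then 10 blocks of all 21 pairs (420 trials).
* *Short protocol* ("human"): 3 adjacent blocks (36), 3 blocks of the 15
  non-adjacent pairs (90), one all-pairs block (42).
* *Massed protocol*: 200 adjacent trials, 200 all-pair trials, 200
  trials of the single pair FG. Phase lengths of 200 are not multiples
  of the 12- and 42-trial block sizes, so whole counterbalanced blocks
  are generated and truncated at the phase boundary; counterbalancing is
  exact for every complete block. The massed phase is built from
  two-trial FG/GF blocks.

Every scheduled trial completes; incomplete trials (fixation failures)
are not modelled, nor are inter-trial intervals, reward magnitude, or
motivation drift.

`probe_accuracy` evaluates, without touching memory, the analytic
probability of a correct choice for any pair: the exact choice integral
for beta-memory models, the softmax probability for Q/softmax. Learning
curves for pairs not currently scheduled are computed this way rather
than by injecting extra trials, which would themselves perturb memory.

### Probe accuracy versus realised accuracy

These two estimands differ in one informative case. Under Q/softmax with
symmetric updating, every trial of pair *XY* deterministically nudges
`Q_X` up and `Q_Y` down, while the neighbouring pairs nudge them back.
A pair's value difference therefore follows a small sawtooth whose
troughs coincide with the pair's own trial onsets — which is exactly
when realised accuracy samples it. With a sharp softmax (β = 10) this
puts realised accuracy on non-terminal adjacent pairs a few points
*below* 50% even though the values are at chance on average. The
analytic probe, averaged over all trial times, sits at 50.0%. The
chance-level benchmark for Q/softmax is therefore defined on the probe,
which is the quantity the hypothetical learning curves plot.

## Likelihood and fitting

For a recorded session, the model is replayed trial by trial using the
subject's recorded choices and rewards (never simulated ones), and the
log-probability of each recorded choice is accumulated from the memory
state that the recorded history implies. For beta-memory models the
choice probability is

    p(A over B) = τ/2 + (1 − τ) ∫₀¹ Beta(x; U_A+1, L_A+1) I(x; U_B+1, L_B+1) dx,

the probability that A's position draw exceeds B's, mixed with the
uniform branch of the choice policy. The +1 offsets mirror the choice
policy so the fitted likelihood and the generating process coincide; a
`prior_offset` argument exposes the bare integral for comparison (with
offset 0 the integral is undefined at zero tallies, one more reason the
offsets are the default).

Numerics: the scalar `choice_prob` uses adaptive quadrature (absolute
tolerance 1e-8, interval split at the mean of A's distribution so sharp
peaks are found). Session replays use a vectorised fixed rule instead:
substituting x = Q_A(p) (A's quantile function) makes the integrand a
bounded monotone sigmoid in p for *any* shape parameters, and a 64-node
Gauss–Legendre rule with a smoothstep endpoint transform
(p = t²(3 − 2t), which suppresses the endpoint derivative singularities
that fractional shapes induce) agrees with the adaptive result to better
than 1e-8. Probabilities are floored at 1e-300 before the log.

Noise and recall trade off near chance performance (high τ mimics low
ξ), so they are not fit jointly. τ is estimated first from accuracy on
the easiest pairs — AF, BG, AG, whose discriminations are near ceiling —
as `τ = clip(2 − 2·accuracy, 0, 1)`: assuming the memory branch is
perfect on those pairs, residual errors are pure guessing. If a session
contains no easy-pair trials, τ defaults to 0.05 with a diagnostic
warning. ξ is then estimated by bounded scalar likelihood maximisation
on (1e-4, 1 − 1e-4), run on three subintervals to guard against a
multimodal profile, best candidate kept. Q/softmax has no such
degeneracy: (α, β) are fit jointly by Nelder–Mead from five fixed
starts, α clipped to [0, 1] and β capped at 100. Flat likelihood ridges
(β ≈ 0 makes α unidentifiable; α = 0 makes β unidentifiable) are
flagged in the fit diagnostics rather than treated as errors. All fits
are deterministic functions of the data.

## Model comparison

Per-model scores pool the transfer phase (the all-pairs trials), where
the inference question lives: per-trial log-likelihoods are re-evaluated
at each session's fitted parameters and summed over transfer trials.
SBIC = k·ln(n) − 2·LL uses n = pooled transfer-trial count and k = 2
parameters per fitted session (parameters are per-session). The G
statistic compares each model against a saturated per-pair binomial:
observed per-pair success counts over each session's first all-pairs
block versus the model's mean predicted per-pair probability of a
correct response, with the 0·log 0 = 0 convention for empty cells.
Approximate log Bayes factors are ΔSBIC/2. Bookkeeping for n and k is
stated here because reasonable alternatives exist (pooled k = 2, or
per-session n); results in this package always say which trials entered
the score.

## Synthetic data

`generate_synthetic_dataset` simulates independent sessions under any
protocol, each with its own freshly randomised schedule and child RNG
stream, so a dataset is a pure function of its seed; a ground-truth
sidecar accompanies it for recovery experiments. The generator emulates
completed, counterbalanced trials with a deterministic reward rule. It
does not emulate incomplete trials, position biases, session-to-session
motivation changes, or the rote memorisation that lets humans acquire
adjacent pairs quickly — so passing recovery and benchmark tests shows
the estimators work under the model's own assumptions, not that real
subjects satisfy them.

Defaults used by the standing benchmarks: 7-item lists; betasort and
betaQ at τ = 0.05, ξ = 0.95 (parameters typical of high-performing
subjects); Q/softmax at α = 0.03, β = 10; 200 replicate sessions for
simulation benchmarks and 50 sessions of the full 660-trial protocol for
parameter recovery — enough that the Monte-Carlo error of each reported
mean is well inside the tolerance it is checked against, while keeping
a full run in the minutes range.

## Known limitations and edge behaviour

* The massed-trial robustness of betasort is real but not absolute: the
  ordering survives massed FG training in roughly nine of ten replicate
  sessions at τ = 0.05, ξ = 0.95. The failures are near-ties between E
  and F produced by the upward compression of all values during the
  massed phase (errors push every upper stimulus up by a unit count
  while relaxation equilibrates total evidence mass). The contrast with
  the baselines is qualitative, not marginal: betaQ and Q/softmax lose
  the ordering in essentially every replicate.
* τ and ξ remain weakly coupled even with the heuristic: sessions with
  few easy-pair errors pin τ well, short sessions do not.
* The likelihood treats the recorded reward as given; sessions whose
  rewards contradict the deterministic rule are replayed as recorded.
* Beta tallies can decay to denormal magnitudes under long
  low-information stretches; position estimates then reset to 0.5 when
  the total mass underflows to zero exactly, which the tests exercise.
* Fitting assumes two-alternative trials throughout (the choice policy
  itself supports larger sets).
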