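# Methods

This note documents the models, procedures, defaults and numerical choices
implemented in `pavbias`, and what the synthetic-data checks do and do not
establish.

## Task model

The go/no-go task crosses required action (go / no-go) with available reward
(immediate / delayed), four cued conditions at 50 presentations each
(`TaskDesign`, 200 trials in 4 blocks of 50). Feedback is probabilistic:
with probability 0.20 the displayed outcome contradicts the correctness of
the response (a correct response shows no reward, an incorrect one shows
the cue's reward). The response window (600 ms) is carried as metadata
only; no timing is modelled.

Condition sequences are pseudorandom with exact per-condition counts and no
more than two identical conditions in a row. The constraint is enforced
across block boundaries, since it is a property of the whole sequence.
Generation is sequential constrained sampling — each position draws among
run-legal conditions with probability proportional to remaining counts,
restarting on the (rare) dead ends. This is not exactly uniform over the
constrained-sequence space, but it is unbiased across conditions by
symmetry, and every emitted sequence satisfies the constraints exactly
(checked over a 1,000-seed sweep).

Query trials and attention checks from the original protocol are not
generated: they carry no likelihood and are excluded from modelling; the
trial table's `excluded` flag covers analyst-excluded trials generically.

## Learning models

All six models are Rescorla–Wagner learners over the four cues with two
actions. Design choices the equations leave open:

- **Initial Q** = 0 for every (cue, action) cell — a neutral start,
  standard for win/no-win tasks.
- **Reward coding**: r = 1 when a reward is displayed, 0 otherwise. Agents
  learn from the *displayed* (possibly incongruent) feedback — participants
  never observe latent correctness.
- **Q bookkeeping**: both actions' values are tracked per cue; only the
  chosen action's cell is updated.
- **Learning-bias selection (M4/M5)**: the bias-congruent rate α₀ applies
  when a displayed reward follows a congruent pairing (go with an
  immediate-reward cue, no-go with a delayed-reward cue); α₁ applies
  otherwise, *including* all no-reward feedback, whose treatment the
  model equations leave unstated.
- **Nesting**: M4 and M5 retain the go bias of M2; M5 with α₀ = α₁ is
  exactly M3, M3 with π = 0 exactly M2, and so on down to M0. These
  identities are enforced by tests at 1e−12.
- The softmax is computed in its two-action logistic form with the usual
  max-subtraction stabilization; per-trial probabilities are floored at
  1e−300 before the log, so the likelihood is finite on the closed
  parameter boxes.
- Excluded trials contribute no likelihood term but still drive learning:
  the participant saw that feedback, and this also makes the log-likelihood
  exactly additive in per-trial terms.

The likelihood and simulator inner loops are numba-compiled; an independent
pure-Python per-trial product oracle verifies the likelihood on a large
randomized battery in the test suite.

## Fitting

Per-participant MAP estimation with box constraints α, α₀, α₁, ξ ∈ [0, 1],
τ ∈ [0, 50], b, π ∈ [−3, 3]. Priors: τ ~ Gamma(shape 3, rate 0.3), b and
π ~ N(0, 1), flat priors for the learning rates and ξ (the boxes already
regularize them). The Gamma prior is read in the rate parameterization
(R's `dgamma` default), giving a prior mode of (3 − 1)/0.3 ≈ 6.7 — the
scale on which fitted inverse temperatures actually live. Under the
alternative scale-0.3 reading (mode 0.6) the prior overwhelms the
likelihood at 200 trials: τ estimates collapse toward 2–4 and ξ is driven
to 0 on data simulated at published-scale parameters, which is
incompatible with the reported behaviour of these fits. The Gamma density
at τ = 0 (where the box is closed but the density vanishes) is replaced by
its log-underflow limit (−745) rather than −∞ to keep the objective finite
on the box.

The optimizer is scipy's differential evolution: population 15 × k, at most
300 generations, tolerance 1e−8, immediate updating, L-BFGS-B polish, with
an optional multi-start (`OptimizerConfig.n_starts`) that keeps the best
mode across independently seeded runs. Fits are deterministic given a seed;
cohort drivers derive per-(participant, model) seeds from a master seed via
CRC-tagged seed sequences. AIC is computed from the log-*likelihood* at the
MAP point (2k − 2ℓ̂), not the log-posterior, since AIC is defined on
likelihood.

**Identifiability caveat.** The likelihood surface has a long, nearly flat
α–τ–ξ ridge at 200 trials: very different (α, τ) pairs produce almost
identical choice probabilities. Consequently the learning rate recovers
poorly from single sessions (Pearson r ≈ 0.4 in the recovery harness)
while ξ, b and π recover well (r ≈ 0.67–0.83). The maximum-likelihood
point converges to the generating values as the session length grows
(verified at 50× the task length); at realistic lengths, interpretation
should focus on the bias parameters.

## Model comparison

Median AIC across participants and model frequency (the proportion of
participants for which a model attains the lowest AIC). Within-participant
AIC ties split the frequency mass equally among tied models, making the
table independent of model ordering.

## Validation

- **Parameter recovery**: simulate one dataset per generating vector, refit
  the same model, report Pearson (primary) and Spearman associations per
  parameter. Zero-variance generating parameters yield NaN (undefined), not
  0. Generating vectors default to truncated Gaussians anchored at the
  fitted-cohort summary values (below).
- **Model recovery**: simulate agents per generating model, fit every
  candidate, tabulate AIC winners into a confusion matrix (rows sum to 1,
  ties split). Default 50 agents per generating model — desk scale. The
  directional checks use a moderate cue-response bias regime (π ~ N(0.5,
  0.2), and separated learning rates for M5) so the biases are actually
  expressed in behaviour; with the cohort-level π of ~0.03 the bias models
  are behaviourally indistinguishable from their null nests at 200 trials.
- **Posterior predictive checks**: simulate `n_datasets` cohorts at the
  fitted per-participant parameters (default 1,000) and summarize the
  trial-by-trial mean p(go) per condition with 2.5/97.5 percentile bands;
  observed raw curves can ride along for visual comparison
  (`plots.plot_ppc`).

## Synthetic cohorts

`generate_cohort` emulates the study's structure: 184 participants by
default, each with 200 trials (4 × 50, 80/20 feedback), generating
parameters drawn from truncated Gaussians anchored at the fitted cohort's
summary statistics — means α 0.19, τ 7.33, ξ 0.17, b 0.06, π 0.03, with
scales implied by the corresponding 95% CIs at n = 184 (α 0.21, τ 2.77,
ξ 0.21, b 0.31, π 0.24), truncated to the fitting boxes. Per-participant
randomness is spawned from the master seed, so a config reproduces its
study byte for byte.

What the generator does *not* emulate: response times, within-session
non-stationarity (fatigue, strategy shifts), attention-check failures and
dropout, rating tasks, and any between-participant correlation structure
among parameters. Passing recovery and predictive checks on these cohorts
therefore establishes internal consistency of the pipeline under the
model's own assumptions, not that real participants satisfy them.

## Titration

The monetary choice questionnaire uses the standard 27-item bank (fixed
order, amounts read in euros; immediate €11–80, delays 7–186 days). The
discount rate is estimated by consistency maximization: candidate k values
are geometric midpoints between consecutive item-boundary ks (plus points
beyond both ends); the candidate predicting the most observed choices under
V = A/(1 + kD) wins, with ties resolved by their geometric mean. All-patient
and all-impatient responders land beyond the ladder's ends.

The staircase starts at the present value 28/(1 + 120k) rounded to the
nearest even integer (ties upward), moves in €2 steps opposite to each
choice over the even integers in [0, 28], and stops when the six most
recent amounts span at most €2 (a sliding window); the indifference value
is their mean rounded half-away-from-zero. Boundary preferences trigger a
confirmation trial: a confirmed preference for €0 today excludes the
participant; a confirmed preference for the delayed €28 over €28 today
fixes the indifference value at €28. Participants not stable within 50
trials are excluded. Stability is checked before boundary confirmation, so
a chooser oscillating at a boundary resolves as stable rather than via the
confirmation path. Simulated choosers are hyperbolic discounters with
optional logistic choice noise on the immediate-minus-present-value
difference.

## Problem sizes in the checked properties

The full-scale test battery runs the likelihood oracle on 1,000 random
short sequences, the feedback statistics at n = 10⁵, sequence constraints
over 1,000 seeds, parameter recovery with 100 agents × 200 trials, model
recovery with 50 agents per generating model over the four bias-capable
candidates, and posterior predictives with 12 participants × 30 datasets —
sizes at which the directional and quantitative signatures are stable
across seeds while the whole battery completes in a few minutes on one
core.

## Known limitations

- AIC ties and model frequency are sensitive to optimizer noise when two
  nested models fit equally well; the tie-splitting rule mitigates but does
  not remove this.
- The consistency-maximizing MCQ estimator returns a point on a coarse
  ladder; k is only identified up to the bracket between adjacent item
  boundary values.
- The learning-bias rate α₀ (M4/M5) is weakly identified at 200 trials,
  consistent with the validation results reported for this model family.
- No hierarchical pooling: each participant is fitted independently, so
  cohort-level summaries inherit single-subject estimation noise.
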