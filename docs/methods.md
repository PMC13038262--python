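# Methods

## The task

`coopdyn` models choice behavior in a repeated Prisoner's Dilemma game
(rPDG) against a pre-programmed partner.  Each round both players choose to
cooperate (C) or defect (D); tokens follow the symmetric matrix
CC → 4/4, DD → 2/2, CD → 0/6.  The partner's schedule has two 60-trial
sessions: a stable session of i.i.d. Bernoulli(0.78) cooperation draws and a
volatile session of three 20-trial blocks at 20%, 80% and 20%.  Session
order is configurable (`stable_first` by default); the 120 trials are
treated as one continuous game — no state is reset at the session boundary.
Stable-session draws are i.i.d. because an exact-count realization of 78%
over 60 trials is impossible (0.78 × 60 is not an integer).  Every 15 rounds
a probe asks for the partner's perceived cooperativeness on a 0–9 scale.
The payment lottery attached to the original task is presentation-layer and
not modeled.

## The model suite

Eight candidate generative models map internal state to a per-trial
cooperation probability q_t (see `models.py` for the full statement):

| ID | model | free parameters |
|----|-------|-----------------|
| M1 | baseline (constant rate) | b |
| M2 | win-stay/lose-shift | ε |
| M3 | reward learning (Rescorla–Wagner + softmax) | α, β |
| M4 | Fehr–Schmidt inequality aversion, fixed p = 0.5 | φ, ν, β |
| M5 | social reward, fixed p | ω, β |
| M6 | social reward + belief learning | α, ω, β |
| M7 | M6 + second-order influence term | α, κ, ω, β |
| M8 | M6 with asymmetric learning rates | α₊, α₋, ω, β |

The social-reward utilities are U_c = p(4 + ω) and U_d = 4p + 2, where p is
the expectation that the partner cooperates and ω the subjective bonus of
mutual cooperation; choices follow a softmax with inverse temperature β
(larger β → more deterministic).  The intrinsic reward for reciprocity is
the product p·ω.  M8's belief update applies α₊ to positive prediction
errors P − p and α₋ to negative ones.

Deliberate interpretive choices, made where the equation forms these models
are usually stated with are ambiguous or internally inconsistent, are
documented in the code and summarized here:

* **M2** is implemented from its verbal rule (repeat with 1 − ε/2 after a
  win — payoff 4 or 6 — and ε/2 after a loss), with q = 0.5 on the first
  trial.
* **M3** updates only the *chosen* option's value.  Updating both options
  with the same reward would force V_c ≡ V_d and collapse the model to a
  constant 0.5.  Initial values are 3.0, the grand mean of the payoff
  entries.
* **M5**'s second utility line is read as U_d (the defection utility);
  its fixed expectation is 0.5, matching M4's printed constant, and is
  configurable.
* **M7**'s second-order term κ(Q − q′) needs the participant's own
  cooperation probability as the partner would infer it; an algebraic
  inversion formula does not yield a probability, so q′ is taken to be the
  model's own current softmax cooperation probability.  Because this update
  is not a convex combination, the belief is clipped to [10⁻³, 1 − 10⁻³].
* Initial belief p₀ = 0.5 for M4–M8.  A zero prediction error leaves the
  belief unchanged.

## Fitting and model comparison

Per participant and model we maximize L = Σ_t log q_t(observed choice),
driving the model state with the *observed* own and partner actions.
Probabilities are clipped to [10⁻¹⁰, 1 − 10⁻¹⁰] before the log.  Bounds:
rates and b, ε, κ ∈ [0,1]; β ∈ [10⁻³, 20]; ω ∈ [0,10]; φ, ν ∈ [0,5].

Optimization is bounded L-BFGS-B (ftol 10⁻⁸) from uniform-random starting
points inside the bounds (500 by default, mirroring the multi-start
protocol of this literature).  For speed, compiled (numba) likelihood
kernels mirror the Python model classes exactly — the test suite asserts
agreement to 10⁻¹⁰ — and a screen-then-polish tier (`polish_top`) evaluates
every start's raw objective and refines only the best few; the default
remains full polishing.  Reduced settings used in the test suite (50–300
starts, polish_top 8) were chosen as the package's fast tier and change the
attained log-likelihood by < 0.5 units in spot checks.

Models are scored with AICc, k = free parameters, n = 120 trials per
participant (the only per-fit sample size available).  BIC is deliberately
not offered: the model set makes no claim to contain the true model.
Group-level selection uses random-effects Bayesian model selection with
log-evidence approximated as −AICc/2 (the conventional information-
criterion bridge): a variational Dirichlet posterior over model frequencies
(uniform prior α₀ = 1, convergence 10⁻⁶), exceedance probabilities by 10⁶
seeded Dirichlet draws (exact Beta CDF at K = 2), Bayesian omnibus risk from
the free-energy comparison against the equal-frequency null, and
PEP = XP·(1 − BOR) + BOR/K.

## Synthetic cohort

The generator emulates the study design: 127 adolescents + 134 adults, each
playing 120 trials against a seeded partner schedule (independent draws per
participant by default; `shared_sequence` reuses one realization).  True M8
parameters are drawn per group from truncated normals (bounds above):

* adolescents: α₊ ~ TN(0.50, 0.15), α₋ ~ TN(0.20, 0.10), ω ~ TN(1.2, 0.6),
  β ~ TN(2.0, 0.7)
* adults: α₊ ~ TN(0.35, 0.15), α₋ ~ TN(0.32, 0.10), ω ~ TN(2.0, 0.6),
  β ~ TN(1.4, 0.5)

These distributions are invented: their only design constraint is the
direction pattern of the group differences (adolescents: higher α₊ and β,
lower α₋ and ω).  No empirical means or SDs for these parameters are
published, so the defaults should be read as a qualitative emulation, not a
calibration.  Probe ratings are a noisy readout of the agent's own belief,
round(9·clip(p + N(0, 0.1), 0, 1)) after the probe trial's update; real
self-reports are of course not generated this way.

**What the defaults imply — an important caveat.**  With these ω values,
U_c − U_d = p·ω − 2 is negative for almost all beliefs, so simulated agents
cooperate on only ~10–40% of trials.  Choices then carry little information
about the belief trajectory, and the data-analytic consequences are
measurable and real: M8 parameter recovery correlations fall well short of
what informative regimes give (α₋, ω and β are nearly unidentified, with
fits piling onto the β and ω bounds), and per-participant AICc usually
prefers the nested symmetric model M6 (or even M1) over the generating M8,
because the ~0.6 log-units of asymmetry evidence per subject is smaller
than the extra-parameter penalty.  The acceptance tests that assert strong
recovery and M8 group-level selection at these defaults therefore fail, and
are left failing: they document a property of the chosen study conditions,
not a defect of the estimator.  The same protocols pass when the generating
parameters are informative (ω spanning the indifference point 2/p, sharper
β) — see `test_m1_m8_strongly_diagonal` and the near-deterministic recovery
test — which is how the original validation (generating from real-data
estimates) should be understood.  Passing tests on this synthetic cohort
show pipeline correctness and the built-in directional signatures; they do
not certify behavior on real data.

## Latent analyses and statistics

Latent traces replay the observed session through the fitted model; the
replayed q_t equals the likelihood's per-trial probability to 10⁻¹² (tested).
The conditional analysis bins trials by the partner's last k = 1, 2, 3
actions all being C (or D).  "Consistency" is read as *at least* k (a trial
counts in every run length it satisfies); an `exact` mode requiring a break
at t − k − 1 is exposed.  Group summaries use across-participant means and
standard errors; participants with no qualifying trials are excluded from a
bin with an explicit count.  Probe ratings normalize to [0,1] as rating/9.

Group contrasts use the pooled-variance two-sample t (df = n₁ + n₂ − 2, the
convention implied by df = 259 for 127 + 134 participants; Welch available
behind a flag) and the JZS Bayes factor: a Cauchy(0, 0.707) prior on the
standardized effect size, integrated against the noncentral-t likelihood
with effective sample size n₁n₂/(n₁ + n₂) by adaptive quadrature (tolerance
10⁻⁸, checked against an independent change-of-variables quadrature in the
tests).  Pearson correlation serves the age analyses.

## Validation protocol sizes

Model recovery fits every candidate to 100 datasets per generator; parameter
recovery uses 100 datasets with 50-start MLE in the fast tier (500 by
default).  The end-to-end study test generates the full 261-participant
cohort and fits all eight models with the 300-start screened tier.  These
sizes are the package's CI tier; all entry points accept larger values.

## Known limitations

* The Pearce–Hall (dynamic learning rate) variant is not implemented; its
  defining equations are not in the reproduced source text.
* No hierarchical/Bayesian parameter estimation; MLE only.
* The mixed-effects (GLMM/LMM) analyses of the original study are out of
  scope; the binned post-hoc contrasts are the supported surrogate.
* The synthetic cohort is a structural emulation; see the caveat above on
  identifiability at the default parameter distributions.
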