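# Methods note

Conventions and estimation choices used throughout `moodrisk`, in the order
the pipeline applies them.

## Task and generator

**Quiz sessions.** 64 trials per session in a fixed episode plan:
medium (8), easy (20), medium (8), hard (20), medium (8). Answer accuracy is
drawn per episode type (defaults: easy 0.75, medium 0.50, hard 0.20).
Feedback is +1 for correct answers; incorrect answers are flipped to +1 with
an episode-dependent bias rate (easy 0.50, medium 0.25, hard 0.00), so the
feedback stream is partially decoupled from performance. 16 mood ratings per
session are placed with inter-rating gaps of 2–6 trials (rejection sampling).

**Offers.** Gains and losses are drawn from 1–5 € with the inner bins
oversampled (bin weights 1:2:2:1 over [1,2], [2,3], [3,4], [4,5], so 2/3 of
draws fall in [2,4]). Difficulty levels are uniform in [1,5] and converted
to timing margins through the subject's calibrated precision (below).

**Cohorts.** Subject-level generative parameters are drawn once from fixed
truncated-normal/uniform priors (e.g. `gamma ~ TN(0.69, 0.20)` on
[0.05, 0.95], `sigma ~ U(0.06, 0.17)`, `kg, kl ~ TN(1.0, 0.3)` on
[0.2, 2.0]). Mood biases choices through an additive utility term
(coupling 0.25 by default), producing the residual mood–choice slope the
pipeline later estimates.

**Synthetic iEEG.** Each site is 1/f-shaped background noise plus weak 10-
and 20-Hz oscillations plus band-limited 50–150 Hz noise whose amplitude in
the 4-s pre-choice window is modulated by the z-scored TML — positively at
"vmPFC-like" sites, negatively at "dAIns-like" sites, not at control sites.

## Mood model

The theoretical mood level after trial t is

```
TML_t = w0 + wf * S_t + wt * t,   S_t = gamma * S_{t-1} + F_t,
F_t   = feedback_t + delta * TML_{t-1},   TML_0 = w0,
```

with feedback in {+R, −1}. The recursion restarts at each session boundary.
With `gamma = 0.69`, a feedback four decay steps old keeps
`0.69^4 ≈ 0.227` of the newest one's weight (the "23 %" worked example).

**Inversion.** Ratings are z-scored and modelled as Gaussian observations of
TML at the rated trials. Estimation is maximum a posteriori over an
unconstrained parameterisation (logit for `gamma`, log for `R` and the noise
sd; the time slope is fitted on `t / n_trials` for conditioning), with
independent Gaussian priors (sd 2) and multistart L-BFGS-B. The log model
evidence is the Laplace approximation at the mode,
`log p(y) ≈ −NLJ(x̂) + d/2·log 2π − ½·log det H`, with a central-difference
Hessian (jitter-regularised if not positive definite). A time-only null
model (`a + b·t + noise`) is fitted identically; the mood vs null comparison
across subjects uses random-effects Bayesian model selection (below).

## Choice model

`ps = erf(m / (sigma√2))` is the probability of landing a 1-s timing
challenge within margin m given Gaussian motor noise sd `sigma`. Difficulty
levels 1–5 map linearly to target success 0.75–0.35, and margins are the
closed-form inverse `m = sigma * Φ⁻¹((1+ps)/2)`. Acceptance is logistic in
`k0 + ps·kg·g − (1−ps)·kl·l + kt·t`.

**Inversion and the calibration-centred sigma prior.** The Bernoulli
likelihood is maximised a posteriori the same way as the mood model. At
~200 trials the likelihood has a ridge trading `k0`, `kg`, `kl` and `sigma`
against each other, so weak priors leave the weights poorly identified. The
task itself resolves this: margins are *constructed* from the subject's
training-calibrated precision, so `median(margin / Φ⁻¹((1+ps_level)/2))`
recovers that calibration from the trial table alone
(`choice.calibrated_sigma`). The prior on `log sigma` is centred there with
sd 0.25 — encoding that subjective precision sits near calibrated
precision — with `k0 ~ N(0,1)` and `kg, kl ~ N(0,2)`. On a 30-subject
cohort this yields median absolute errors ≈15 % for `kg`/`kl` and ≈5 % for
`sigma`. Residual choices (`choice − p_accept`) regressed on z-scored mood
quantify the mood bias; baseline-activity analyses refit the model on
high/low baseline halves of "undetermined" trials (middle of the fitted
p-accept range) with `kt` frozen at the full-data estimate.

## Envelope extraction

Broadband gamma (50–150 Hz) is processed in ten 10-Hz sub-bands (the lower
bands use their own steps: gamma 33–49/4, beta 13–33/5, alpha 8–13/1, theta
4–8/1). Each sub-band is band-passed with an odd-length windowed-sinc FIR
(Hamming, ~0.5 Hz transition) applied by FFT convolution centred on the
sample — a symmetric kernel applied this way is exactly zero-phase. The
Hilbert magnitude of each sub-band is normalised to a session mean of 100
(cancelling the 1/f amplitude drop-off across sub-bands) and sub-bands are
averaged; the session mean of the result is 100 by construction. The
envelope is then smoothed with a 250-ms boxcar (reflection padding),
down-sampled to 100 Hz on a 10-ms grid, epoched on an inclusive grid (a
−4…0 s window holds 401 samples), and z-scored across trials per site and
time sample.

## Statistics

**Timepoint GLMs.** Ordinary least squares of normalised power on a
z-scored trial regressor, per site and time sample, vectorised in closed
form.

**Cluster permutation.** Observed statistic: per time sample, a one-sample
t across the ROI's per-site OLS slopes; clusters are maximal contiguous
same-sign runs above the two-sided pointwise threshold (t df = S−1,
α = 0.05), scored by the sum of t. Null: a fixed number of trial-label
shuffles per site; each null draw combines one shuffle per site (random
combinations, or exhaustive enumeration for oracle checks) and records the
maximal absolute cluster mass. Corrected p-values use the add-one
convention `(1 + #null ≥ |mass|) / (1 + n_draws)`. Calibration is verified
empirically: over 200 null ROI analyses the false-positive rate stays inside
the binomial 95 % interval around 0.05, while an injected 0.5-s coupling of
β = 0.5 is detected in > 90 % of runs.

**Band-model family.** Per site, 16 Gaussian GLMs of mood on baseline
power: broadband gamma alone plus every subset of {gamma, beta, alpha,
theta}. Each is scored by a BIC-style log evidence
(`loglik − ½(k+1)·log n`).

**Random-effects Bayesian model selection.** The model identity per
site/subject is a random effect with a Dirichlet population prior
(α₀ = 1); variational updates (digamma re-weighting of per-site posteriors,
Dirichlet count updates) iterate to 10⁻⁶. Exceedance probabilities are
Monte-Carlo estimates of `P(model k most frequent)` from Dirichlet draws;
on two-model problems they match the exact Beta integral to < 10⁻².

**Group summaries.** Site-level estimates are averaged within subject
before a one-sample t across subjects (subjects, not sites, as the random
effect).

## Pipeline profiles

`fast`: 8 subjects × 2 sessions, 300 shuffles/site, 5 000 combinations,
10⁴ BMS draws. `tiny`: 3 subjects × 1 session, for smoke tests. Reports
carry a config hash, the seed and the package version; identical configs
reproduce the report bit for bit.
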