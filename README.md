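# moodrisk

Computational pipeline linking mood dynamics, risky choice and intracranial
broadband-gamma activity.

## The scientific problem

Mood fluctuates on the timescale of minutes, and those fluctuations bias
economic decisions: people in a good mood accept more risky offers than their
stable preferences predict. `moodrisk` implements an end-to-end synthetic
test bed for this claim:

1. **A quiz task with biased feedback** induces mood drift. Sessions of 64
   general-knowledge trials alternate easy / medium / hard episodes; on easy
   episodes half of the *incorrect* answers are nevertheless rewarded, on hard
   episodes no incorrect answer is, so the feedback stream — not the
   subject's competence — drives mood up and down. Subjects rate their mood
   on 16 of the 64 trials.
2. **A theoretical mood level (TML)** summarises the feedback history: an
   exponentially forgetting sum of *perceived* feedbacks, where perception is
   itself biased by the previous mood (`F_t = feedback_t + delta * TML_{t-1}`),
   plus constant and linear-time terms. With forgetting factor
   `gamma = 0.69`, a feedback five trials back still carries ~23 % of the
   newest one's weight.
3. **An expected-utility choice model** covers interleaved risky challenges:
   accept or reject an offer (gain g, loss l, timing margin m). Success is
   a Gaussian timing game, `ps = erf(m / (sigma * sqrt(2)))`, and acceptance
   is logistic in `k0 + ps*kg*g - (1-ps)*kl*l + kt*t`. Residual acceptance
   (beyond the fitted model) is regressed on mood to quantify the mood bias.
4. **Synthetic intracranial EEG** couples a 50–150 Hz broadband-gamma
   envelope to the TML with opposite signs at "vmPFC-like" and
   "dAIns-like" sites. The analysis chain — sub-band Hilbert envelopes
   normalised to session mean 100, smoothing, down-sampling, pre-choice
   baseline epochs, per-timepoint GLMs, cluster-level permutation
   correction, and random-effects Bayesian model selection over a 16-model
   frequency-band family — recovers that coupling and its direction.

Everything is simulated; the package's value is that every statistical claim
in the chain is checked against ground truth, brute-force enumeration, or a
closed-form oracle.

## Worked example

Simulate one subject (3 sessions, 192 trials) and invert both behavioural
models. Model classes follow a statsmodels-like shape: construct, `fit()`,
inspect the returned results object.

```python
from moodrisk import (ChoiceModel, ChoiceParams, MoodModel, MoodNullModel,
                      MoodParams, QuizDesign, simulate_subject)

mp = MoodParams(w0=0.0, wf=0.10, wt=0.0, gamma=0.69, delta=0.30, R=1.0)
cp = ChoiceParams(k0=0.0, kg=1.0, kl=1.0, sigma=0.08, kt=0.0)
trials, truth = simulate_subject(QuizDesign(), mp, cp, n_sessions=3, seed=42)

mood = MoodModel.from_trials(trials).fit()
print(mood.summary())
```

```
Mood model results (mood)
==================================
rated trials:  48
log evidence:  36.54
residual sd:   0.065
w0    -0.118
wf    +0.512
wt    +0.00047 per trial
gamma 0.540
delta +0.382
R     0.889
```

The forgetting factor and perception bias are recovered near their true
values (`gamma` 0.54 vs 0.69, `delta` +0.38 vs +0.30); because ratings are
z-scored before fitting, `wf` is identified up to scale, so its *sign* is the
recoverable quantity. A time-only control model is decisively rejected:

```python
null = MoodNullModel.from_trials(trials).fit()
print(null.log_evidence)   # -75.16  (mood model: +36.54)

choice = ChoiceModel.from_trials(trials).fit()
print(choice.summary())
```

```
Choice model results
==================================
trials:        192
log evidence:  -124.29
mean p(accept) 0.558
k0    -0.081
kg    +1.061
kl    +0.808
sigma 0.0839 s
kt    -0.00174 per trial
```

The gain/loss weights and the timing precision come back close to the truth
(`kg` 1.06 vs 1.00, `kl` 0.81 vs 1.00, `sigma` 0.084 s vs 0.080 s). The
timing-precision prior is centred on the value implied by the task's own
margin/difficulty calibration (see `docs/methods.md`).

The full chain — cohort simulation, behavioural fits, envelope extraction,
cluster statistics, band-family model selection — runs from the CLI:

```bash
moodrisk run-all --profile tiny --seed 3 --out report.json   # ~1 min smoke run
moodrisk run-all --profile fast --seed 0 --out report.json   # desk-scale run
```

Other commands: `moodrisk simulate`, `fit-mood`, `fit-choice`, `extract-bga`
(`moodrisk --help` for options).

## Reproduction

All numbers above, and every validation claim, are reproducible offline:

```bash
# full test suite (unit, property-based, oracle and acceptance tests)
python -m pytest -q

# machine-readable acceptance targets (calibration round trips, envelope
# normalisation, feedback-bias rate) -> JSON
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` writes, per target, the computed value and the
sample size it was computed from, e.g. `t8` ≈ 50 % positive feedback among
incorrect easy-episode answers over 500 sessions. All simulations take an
explicit integer seed; identical seeds reproduce results bit for bit.

## Package layout

| Module | Contents |
| --- | --- |
| `moodrisk.simulate` | quiz sessions, offers, subjects, cohorts, synthetic iEEG |
| `moodrisk.mood` | TML recursion, rating interpolation, mood-model inversion |
| `moodrisk.choice` | success geometry, expected utility, choice-model inversion, baseline splits |
| `moodrisk.envelopes` | bipolar montage, sub-band Hilbert envelopes, epoching, z-scoring |
| `moodrisk.stats` | timepoint GLMs, cluster permutation, RFX-BMS, band-model family |
| `moodrisk.pipeline` | end-to-end orchestration with a JSON report |
| `moodrisk.plotting` | diagnostic figures |

A methods note with the exact estimation and statistical conventions is in
[`docs/methods.md`](docs/methods.md).
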