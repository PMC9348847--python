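"""Synthetic behavioural sessions and intracranial-like recordings.

Emulates the quiz/mood/choice task structure the analysis assumes:
64-trial sessions composed of easy / medium / hard quiz episodes with
biased feedback (a wrong answer still earns a positive feedback 50 % of
the time in easy, 25 % in medium and never in hard episodes), mood
ratings on 25 % of trials spaced 2-6 trials apart, and offers sampled
on gain x loss x difficulty grids with medium bins oversampled 2:1.
Behaviour is generated by the package's own mood and choice models, and
multichannel voltage traces carry a 50-150 Hz component whose pre-choice
amplitude couples (positively or negatively, by site role) to the
latent mood, on top of 1/f background noise and band-limited
oscillations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice import (
    ChoiceParams,
    difficulty_to_success,
    invert_success_level,
    success_probability,
)
from .envelopes import RawRecording
from .mood import MoodParams, compute_tml

__all__ = [
    "QuizDesign",
    "NeuralConfig",
    "ParameterPriors",
    "SubjectRecord",
    "generate_quiz_session",
    "generate_offers",
    "simulate_subject",
    "generate_ieeg",
    "generate_cohort",
    "write_trials",
    "read_trials",
]

#: additive utility weight of z-scored mood on choice; sized so that the
#: slope of choice residuals on z-scored mood is about 0.05
DEFAULT_MOOD_CHOICE_COUPLING = 0.25


@dataclass(frozen=True)
class QuizDesign:
    """Episode plan, feedback bias and rating placement of one session."""

    n_trials_per_session: int = 64
    episode_plan: tuple = (
        ("medium", 8),
        ("easy", 20),
        ("medium", 8),
        ("hard", 20),
        ("medium", 8),
    )
    bias_rates: dict = field(
        default_factory=lambda: {"easy": 0.50, "medium": 0.25, "hard": 0.0}
    )
    rating_fraction: float = 0.25
    accuracy_rates: dict = field(
        default_factory=lambda: {"easy": 0.75, "medium": 0.50, "hard": 0.20}
    )
    rating_gap: tuple = (2, 6)

    def __post_init__(self):
        total = sum(n for _, n in self.episode_plan)
        if total != self.n_trials_per_session:
            raise ValueError(
                f"episode lengths sum to {total}, expected {self.n_trials_per_session}"
            )
        for label, _ in self.episode_plan:
            if label not in self.bias_rates or label not in self.accuracy_rates:
                raise ValueError(f"missing bias/accuracy rate for episode label {label!r}")
        if not 0 <= self.rating_fraction <= 1:
            raise ValueError("rating fraction must lie in [0, 1]")

    @property
    def n_ratings(self) -> int:
        return int(round(self.rating_fraction * self.n_trials_per_session))


@dataclass(frozen=True)
class NeuralConfig:
    """Layout of the synthetic multichannel recording."""

    sampling_rate: float = 512.0
    site_roles: dict = field(
        default_factory=lambda: {
            "vmpfc1": "positive_coupling",
            "vmpfc2": "positive_coupling",
            "dains1": "negative_coupling",
            "dains2": "negative_coupling",
            "ctrl1": "null",
        }
    )
    coupling_gain: float = 0.5
    background_exponent: float = 1.0
    background_amplitude: float = 1.0
    oscillation_specs: tuple = ((10.0, 2.0), (20.0, 1.5))
    gamma_amplitude: float = 1.0
    trial_spacing: float = 10.0
    padding: float = 6.5

    def __post_init__(self):
        highest = max([150.0] + [f for f, _ in self.oscillation_specs])
        if self.sampling_rate < 2 * highest:
            raise ValueError("sampling rate below Nyquist for synthesised components")

    @property
    def n_sites(self) -> int:
        return len(self.site_roles)


def _place_ratings(n_trials: int, n_ratings: int, gap: tuple, rng) -> np.ndarray:
    """1-based rating-trial positions with consecutive gaps in [gap0, gap1]."""
    if n_ratings <= 0:
        return np.array([], dtype=int)
    if n_ratings == 1:
        return np.array([int(rng.integers(1, n_trials + 1))])
    lo, hi = gap
    if 1 + lo * (n_ratings - 1) > n_trials:
        raise ValueError("cannot place ratings with the minimum spacing")
    for _ in range(100_000):
        first = int(rng.integers(1, min(hi, n_trials) + 1))
        gaps = rng.integers(lo, hi + 1, size=n_ratings - 1)
        pos = first + np.concatenate([[0], np.cumsum(gaps)])
        if pos[-1] <= n_trials:
            return pos.astype(int)
    raise RuntimeError("rating placement failed")


def generate_quiz_session(design: QuizDesign, seed: int) -> pd.DataFrame:
    """One session of quiz answers, biased feedbacks and rating slots."""
    rng = np.random.default_rng(seed)
    labels = np.concatenate(
        [np.repeat(lab, n) for lab, n in design.episode_plan]
    )
    n = design.n_trials_per_session
    acc = np.array([design.accuracy_rates[lab] for lab in labels])
    correct = rng.random(n) < acc
    bias = np.array([design.bias_rates[lab] for lab in labels])
    flipped = (~correct) & (rng.random(n) < bias)
    feedback = np.where(correct | flipped, 1, -1)
    rating_pos = _place_ratings(n, design.n_ratings, design.rating_gap, rng)
    has_rating = np.zeros(n, dtype=bool)
    has_rating[rating_pos - 1] = True
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "episode_label": labels,
            "answer_correct": correct,
            "feedback": feedback,
            "has_rating": has_rating,
        }
    )


#: offer bins [1-2], [2-3], [3-4], [4-5] with the medium bins oversampled 2:1
_OFFER_BINS = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
_OFFER_WEIGHTS = np.array([1.0, 2.0, 2.0, 1.0]) / 6.0


def generate_offers(n_trials: int, seed: int) -> pd.DataFrame:
    """Gain, loss and difficulty sampled on the weighted interval bins."""
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in ("gain", "loss", "difficulty_level"):
        bins = rng.choice(4, size=n_trials, p=_OFFER_WEIGHTS)
        lo = _OFFER_BINS[bins, 0]
        hi = _OFFER_BINS[bins, 1]
        cols[name] = lo + (hi - lo) * rng.random(n_trials)
    return pd.DataFrame(cols)


def simulate_subject(
    design: QuizDesign,
    mood_params: MoodParams,
    choice_params: ChoiceParams,
    rating_noise_sd: float = 0.1,
    n_sessions: int = 3,
    seed: int = 0,
    mood_choice_coupling: float = DEFAULT_MOOD_CHOICE_COUPLING,
    kg_modulation: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one subject's full behavioural record.

    Feedbacks come from the quiz design, mood from the TML recursion
    (restarted each session), observed ratings are an affine map of
    z-scored mood plus Gaussian noise clipped to [0, 1], margins invert
    the subject's difficulty levels through their timing precision, and
    choices are Bernoulli draws from the softmax of expected utility
    plus ``mood_choice_coupling`` x z(TML).

    With ``kg_modulation`` set, the gain weight varies trial-by-trial
    with an independent standard-normal baseline-activity modulator
    (``kg_t = kg + kg_modulation * b_t``); the modulator is returned in
    the truth dict for split-refit recovery tests.

    Returns (trial table, truth dict with the latent series).
    """
    rng = np.random.default_rng(seed)
    sessions = []
    for s in range(n_sessions):
        sess = generate_quiz_session(design, int(rng.integers(0, 2**31 - 1)))
        sess.insert(0, "session", s + 1)
        sessions.append(sess)
    trials = pd.concat(sessions, ignore_index=True)
    trials["trial_index_global"] = np.arange(1, len(trials) + 1)

    tml_parts = [
        compute_tml(g["feedback"].to_numpy(), mood_params).tml
        for _, g in trials.groupby("session", sort=True)
    ]
    tml = np.concatenate(tml_parts)
    sd = tml.std()
    z_tml = (tml - tml.mean()) / sd if sd > 0 else np.zeros_like(tml)

    ratings = np.full(len(trials), np.nan)
    mask = trials["has_rating"].to_numpy()
    noise = rng.normal(0.0, rating_noise_sd, size=int(mask.sum())) if rating_noise_sd > 0 else 0.0
    ratings[mask] = np.clip(0.5 + 0.15 * (z_tml[mask] + noise), 0.0, 1.0)
    trials["mood_rating"] = ratings

    offers = generate_offers(len(trials), int(rng.integers(0, 2**31 - 1)))
    trials = pd.concat([trials, offers], axis=1)
    ps_target = difficulty_to_success(trials["difficulty_level"].to_numpy())
    trials["margin"] = invert_success_level(ps_target, choice_params.sigma)

    ps = success_probability(trials["margin"].to_numpy(), choice_params.sigma)
    kg = np.full(len(trials), choice_params.kg)
    baseline_mod = None
    if kg_modulation is not None:
        baseline_mod = rng.standard_normal(len(trials))
        kg = kg + kg_modulation * baseline_mod
    u = (
        choice_params.k0
        + ps * kg * trials["gain"].to_numpy()
        - (1.0 - ps) * choice_params.kl * trials["loss"].to_numpy()
        + choice_params.kt * trials["trial_index_global"].to_numpy()
        + mood_choice_coupling * z_tml
    )
    p_accept = 1.0 / (1.0 + np.exp(-u))
    trials["choice"] = (rng.random(len(trials)) < p_accept).astype(int)
    trials["response_time"] = rng.lognormal(np.log(2.2), 0.35, size=len(trials))

    truth = {
        "tml": tml,
        "z_tml": z_tml,
        "p_accept": p_accept,
        "mood_params": mood_params,
        "choice_params": choice_params,
        "mood_choice_coupling": mood_choice_coupling,
        "baseline_modulator": baseline_mod,
    }
    return trials, truth


def _one_over_f(rng, n: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.maximum(f, 1.0) ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _band_noise(rng, n: int, fs: float, low: float, high: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = ((f >= low) & (f <= high)).astype(float)
    x = np.fft.irfft(spec * mask, n=n)
    return x / x.std()


def generate_ieeg(
    trials: pd.DataFrame,
    tml: np.ndarray,
    config: NeuralConfig = NeuralConfig(),
    seed: int = 0,
) -> RawRecording:
    """Synthesize a continuous recording whose 50-150 Hz amplitude in each
    trial's pre-choice window (-4..0 s) is scaled by 1 + gain * z(TML) with
    the sign set by the site's role.

    Event markers (feedback onset ~5.5 s before choice, choice onset,
    response) are written alongside the signal.
    """
    tml = np.asarray(tml, dtype=float)
    n_trials = len(trials)
    if tml.size != n_trials:
        raise ValueError("TML length does not match trial count")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    duration = 2 * config.padding + n_trials * config.trial_spacing
    n = int(round(duration * fs))
    choice_times = config.padding + 5.6 + config.trial_spacing * np.arange(n_trials)
    fb_times = choice_times - 5.5 + rng.uniform(-0.1, 0.1, size=n_trials)
    rts = (
        trials["response_time"].to_numpy()
        if "response_time" in trials.columns
        else np.full(n_trials, 2.0)
    )
    events = pd.DataFrame(
        {
            "label": ["feedback"] * n_trials + ["choice"] * n_trials + ["response"] * n_trials,
            "time": np.concatenate([fb_times, choice_times, choice_times + rts]),
        }
    ).sort_values("time", ignore_index=True)

    sd = tml.std()
    z = (tml - tml.mean()) / sd if sd > 0 else np.zeros_like(tml)
    t_axis = np.arange(n) / fs
    signal = np.empty((config.n_sites, n))
    role_sign = {"positive_coupling": 1.0, "negative_coupling": -1.0, "null": 0.0}
    for i, (label, role) in enumerate(config.site_roles.items()):
        x = config.background_amplitude * _one_over_f(
            rng, n, fs, config.background_exponent
        )
        for freq, amp in config.oscillation_specs:
            x += amp * np.sin(2 * np.pi * freq * t_axis + rng.uniform(0, 2 * np.pi))
        amp_t = np.ones(n)
        s = role_sign[role]
        if s != 0.0:
            for k, t0 in enumerate(choice_times):
                a, b = int(round((t0 - 4.0) * fs)), int(round(t0 * fs))
                amp_t[a:b] = 1.0 + config.coupling_gain * s * z[k]
        if np.any(amp_t < 0):
            warnings.warn(f"negative gamma amplitude clipped at zero on site {label}")
            amp_t = np.clip(amp_t, 0.0, None)
        x += config.gamma_amplitude * amp_t * _band_noise(rng, n, fs, 50.0, 150.0)
        signal[i] = x
    return RawRecording(
        signal=signal,
        sampling_rate=fs,
        site_labels=list(config.site_roles),
        events=events,
        site_roles=dict(config.site_roles),
    )


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection failed")


@dataclass(frozen=True)
class ParameterPriors:
    """Population distributions the cohort generator draws subjects from.

    Defaults reflect the study conditions: the forgetting factor is
    centred on 0.69 with a population sd of 0.20 (back-computed from the
    reported group SEM), the timing precision spans the observed
    inter-subject margin range (sigma ~ U(0.06, 0.17) s), and the
    feedback / mood-bias weights are positive on average.
    """

    gamma: tuple = (0.69, 0.20, 0.05, 0.95)
    wf: tuple = (0.10, 0.05, 0.02, 0.30)
    delta: tuple = (0.30, 0.10, 0.05, 0.60)
    w0: tuple = (0.0, 0.3, -1.0, 1.0)
    wt: tuple = (0.0, 0.002, -0.01, 0.01)
    R: tuple = (1.0, 0.2, 0.5, 2.0)
    kg: tuple = (1.0, 0.3, 0.2, 2.0)
    kl: tuple = (1.0, 0.3, 0.2, 2.0)
    k0: tuple = (0.0, 0.5, -1.5, 1.5)
    kt: tuple = (0.0, 0.005, -0.02, 0.02)
    sigma_range: tuple = (0.06, 0.17)

    def draw(self, rng) -> tuple[MoodParams, ChoiceParams]:
        for _ in range(1000):
            mp = MoodParams(
                w0=_trunc_normal(rng, *self.w0),
                wf=_trunc_normal(rng, *self.wf),
                wt=_trunc_normal(rng, *self.wt),
                gamma=_trunc_normal(rng, *self.gamma),
                delta=_trunc_normal(rng, *self.delta),
                R=_trunc_normal(rng, *self.R),
            )
            if mp.loop_gain() < 1.5:
                break
        cp = ChoiceParams(
            k0=_trunc_normal(rng, *self.k0),
            kg=_trunc_normal(rng, *self.kg),
            kl=_trunc_normal(rng, *self.kl),
            sigma=float(rng.uniform(*self.sigma_range)),
            kt=_trunc_normal(rng, *self.kt),
        )
        return mp, cp


@dataclass
class SubjectRecord:
    """One simulated subject: behaviour, optional recording, ground truth."""

    subject_id: int
    trials: pd.DataFrame
    truth: dict
    recording: RawRecording | None = None


def generate_cohort(
    n_subjects: int,
    priors: ParameterPriors | None = None,
    seed: int = 0,
    *,
    n_sessions: int = 3,
    design: QuizDesign | None = None,
    include_neural: bool = False,
    neural_config: NeuralConfig | None = None,
    rating_noise_sd: float = 0.1,
    mood_choice_coupling: float = DEFAULT_MOOD_CHOICE_COUPLING,
    kg_modulation: float | None = None,
) -> list[SubjectRecord]:
    """Draw subject parameters from the priors and simulate each subject."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    priors = priors or ParameterPriors()
    design = design or QuizDesign()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        mp, cp = priors.draw(rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        trials, truth = simulate_subject(
            design,
            mp,
            cp,
            rating_noise_sd=rating_noise_sd,
            n_sessions=n_sessions,
            seed=sub_seed,
            mood_choice_coupling=mood_choice_coupling,
            kg_modulation=kg_modulation,
        )
        rec = None
        if include_neural:
            rec = generate_ieeg(
                trials,
                truth["tml"],
                neural_config or NeuralConfig(),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        cohort.append(SubjectRecord(subject_id=i + 1, trials=trials, truth=truth, recording=rec))
    return cohort


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as TSV (header included)."""
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
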