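"""Mood dynamics: theoretical mood level (TML) model and its inversion.

The latent mood on trial t is an exponentially forgetting integration of
subjectively perceived quiz feedbacks plus a constant and a linear time
trend:

    TML_t = w0 + wf * sum_{j<=t} gamma^(t-j) * F_j + wt * t

with forgetting factor gamma in [0, 1].  Perception of feedback is in
turn biased by the mood carried from the previous trial,

    F_t = Feedback_t + delta * TML_{t-1},   Feedback_t in {+R, -1},

which makes the mood <-> feedback influence reciprocal; R > 0 allows an
asymmetric impact of positive versus negative feedback.  The model is
inverted per subject from sparse mood ratings (z-scored) by MAP with a
Laplace approximation of the model evidence, and compared to a null
model in which mood only drifts linearly with time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import special

from ._inversion import MapFitResult, map_laplace_fit

__all__ = [
    "MoodParams",
    "MoodTrajectory",
    "perceived_feedback",
    "compute_tml",
    "interpolate_ratings",
    "decompose_tml",
    "MoodModel",
    "MoodNullModel",
    "MoodResults",
    "compare_mood_models",
    "TmlDivergenceError",
]

#: |TML| beyond which the closed feedback<->mood loop is declared divergent
_DIVERGENCE_LIMIT = 1e6

#: heuristic closed-loop gain bound used to reject explosive parameter sets
_LOOP_GAIN_LIMIT = 1.5


class TmlDivergenceError(RuntimeError):
    """Raised when the mood recursion diverges for a parameter set."""


@dataclass(frozen=True)
class MoodParams:
    """Free parameters of the mood model.

    Attributes
    ----------
    w0 : constant (resting mood level, also the TML before any feedback)
    wf : weight of integrated feedback on mood
    wt : linear time drift per trial
    gamma : forgetting factor in [0, 1]
    delta : weight of previous mood on feedback perception
    R : magnitude of a positive feedback (negative feedback is -1); R > 0
    """

    w0: float = 0.0
    wf: float = 0.1
    wt: float = 0.0
    gamma: float = 0.69
    delta: float = 0.3
    R: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.R <= 0:
            raise ValueError(f"R must be positive, got {self.R}")

    def loop_gain(self) -> float:
        """Heuristic gain of the feedback<->mood loop; >= 1.5 is rejected."""
        return self.gamma * (1.0 + abs(self.wf * self.delta))


@dataclass(frozen=True)
class MoodTrajectory:
    """Trialwise series produced by the mood recursion."""

    tml: np.ndarray
    perceived_feedback: np.ndarray
    raw_feedback: np.ndarray

    def __len__(self) -> int:
        return self.tml.size


def perceived_feedback(feedback_sign: int, tml_prev: float, params: MoodParams) -> float:
    """Subjective perception of one feedback given the mood carried over.

    ``F = (R if positive else -1) + delta * TML_prev``.
    """
    if feedback_sign not in (+1, -1):
        raise ValueError(f"feedback_sign must be +1 or -1, got {feedback_sign}")
    raw = params.R if feedback_sign > 0 else -1.0
    return raw + params.delta * tml_prev


def compute_tml(feedback_signs, params: MoodParams) -> MoodTrajectory:
    """Run the mood recursion over a feedback sequence.

    The integrated-feedback state S obeys ``S_t = gamma * S_{t-1} + F_t``
    so that ``TML_t = w0 + wf * S_t + wt * t`` (t is 1-based).  TML_0 is
    initialised to w0, making F_1 well defined.
    """
    signs = np.asarray(feedback_signs)
    if signs.size == 0:
        raise ValueError("feedback series is empty")
    if not np.all(np.isin(signs, (-1, 1))):
        raise ValueError("feedback signs must be +/-1")
    raw = np.where(signs > 0, params.R, -1.0)
    n = signs.size
    tml = np.empty(n)
    perceived = np.empty(n)
    s = 0.0
    tml_prev = params.w0
    for t in range(n):
        f = raw[t] + params.delta * tml_prev
        s = params.gamma * s + f
        val = params.w0 + params.wf * s + params.wt * (t + 1)
        if not np.isfinite(val) or abs(val) > _DIVERGENCE_LIMIT:
            raise TmlDivergenceError(
                "TML diverged at trial "
                f"{t + 1} (gamma={params.gamma}, wf={params.wf}, delta={params.delta})"
            )
        perceived[t] = f
        tml[t] = val
        tml_prev = val
    return MoodTrajectory(tml=tml, perceived_feedback=perceived, raw_feedback=raw)


def interpolate_ratings(rated_trials, rating_values, n_trials: int) -> np.ndarray:
    """Linearly interpolate sparse ratings to one value per trial, z-scored.

    Before the first and after the last rated trial the nearest rating is
    held constant.  A constant rating series cannot be z-scored; it is
    returned as zeros with a warning.
    """
    idx = np.asarray(rated_trials, dtype=float)
    vals = np.asarray(rating_values, dtype=float)
    if idx.size < 2:
        raise ValueError("need at least two rated trials to interpolate")
    order = np.argsort(idx)
    dense = np.interp(np.arange(1, n_trials + 1, dtype=float), idx[order], vals[order])
    sd = dense.std()
    if sd == 0:
        warnings.warn("constant rating series; z-scored output set to zeros")
        return np.zeros(n_trials)
    return (dense - dense.mean()) / sd


def decompose_tml(feedback_signs, params: MoodParams):
    """Regressor pair (last feedback sign, previous-trial TML) per trial.

    At t=1 the previous TML is the initial value w0.  When the two
    regressors are numerically collinear (e.g. gamma = delta = 0, where
    TML_{t-1} is an affine function of the lagged feedback) a warning is
    emitted; downstream GLMs should then drop the pair.
    """
    traj = compute_tml(feedback_signs, params)
    signs = np.asarray(feedback_signs, dtype=float)
    prior = np.concatenate([[params.w0], traj.tml[:-1]])
    if signs.size >= 3:
        lagged = np.concatenate([[0.0], signs[:-1]])
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(lagged, prior)[0, 1]
        if np.isfinite(c) and abs(c) > 0.99:
            warnings.warn("last-feedback and prior-TML regressors are collinear")
    return signs, prior


# ---------------------------------------------------------------------------
# model inversion


def _unpack(x: np.ndarray, n_trials: int) -> tuple[MoodParams, float]:
    """Unconstrained vector -> (MoodParams, residual sd).

    Layout: (w0, wf, wt_scaled, logit gamma, delta, log R, log sd);
    the time drift is fitted on t/n and reported per trial.
    """
    w0, wf, wts, lg, delta, logR, logsd = x
    return (
        MoodParams(
            w0=w0,
            wf=wf,
            wt=wts / n_trials,
            gamma=float(special.expit(lg)),
            delta=delta,
            R=float(np.exp(logR)),
        ),
        float(np.exp(logsd)),
    )


@dataclass
class MoodResults:
    """Fitted mood (or null) model for one subject.

    Carries the MAP parameters, the Laplace log evidence, the residual
    noise sd, and the fitted trajectory (mood model only).
    """

    params: MoodParams | None
    log_evidence: float
    residual_sd: float
    fitted_tml: MoodTrajectory | None
    model: str
    n_rated: int
    map_fit: MapFitResult
    trend: tuple[float, float] | None = None  # (intercept, slope/trial) of null

    def predict(self, n_trials: int | None = None) -> np.ndarray:
        if self.model == "mood":
            return self.fitted_tml.tml
        a, b = self.trend
        return a + b * np.arange(1, n_trials + 1)

    def summary(self) -> str:
        lines = [
            f"Mood model results ({self.model})",
            "=" * 34,
            f"rated trials:  {self.n_rated}",
            f"log evidence:  {self.log_evidence:.2f}",
            f"residual sd:   {self.residual_sd:.3f}",
        ]
        if self.model == "mood":
            p = self.params
            lines += [
                f"w0    {p.w0:+.3f}",
                f"wf    {p.wf:+.3f}",
                f"wt    {p.wt:+.5f} per trial",
                f"gamma {p.gamma:.3f}",
                f"delta {p.delta:+.3f}",
                f"R     {p.R:.3f}",
            ]
        else:
            a, b = self.trend
            lines += [f"intercept {a:+.3f}", f"slope     {b:+.5f} per trial"]
        return "\n".join(lines)


class MoodModel:
    """Mood model bound to one subject's ratings and feedback sequence.

    Parameters
    ----------
    rated_trials : 1-based indices of trials carrying a mood rating
    ratings : the rating values (z-scored internally)
    feedback_signs : +/-1 feedback for every trial
    session_bounds : optional list of (start, end) 1-based inclusive trial
        spans; the recursion restarts at each session start.
    """

    def __init__(self, rated_trials, ratings, feedback_signs, session_bounds=None):
        self.rated_trials = np.asarray(rated_trials, dtype=int)
        ratings = np.asarray(ratings, dtype=float)
        if self.rated_trials.size < 4:
            raise ValueError("need at least 4 rated trials")
        self.feedback_signs = np.asarray(feedback_signs)
        n = self.feedback_signs.size
        if self.rated_trials.max() > n or self.rated_trials.min() < 1:
            raise ValueError("rated trial index outside feedback series")
        sd = ratings.std()
        self.ratings_z = (ratings - ratings.mean()) / sd if sd > 0 else np.zeros_like(ratings)
        self.n_trials = n
        if session_bounds is None:
            session_bounds = [(1, n)]
        self.session_bounds = list(session_bounds)

    @classmethod
    def from_trials(cls, trials) -> "MoodModel":
        """Build from a trial table (as produced by `moodrisk.simulate`)."""
        rated = trials[trials["has_rating"]]
        bounds = None
        if "session" in trials.columns:
            bounds = []
            for _, grp in trials.groupby("session", sort=True):
                lo = int(grp["trial_index_global"].min())
                hi = int(grp["trial_index_global"].max())
                bounds.append((lo, hi))
        return cls(
            rated["trial_index_global"].to_numpy()
            if "trial_index_global" in trials.columns
            else rated["trial_index"].to_numpy(),
            rated["mood_rating"].to_numpy(),
            trials["feedback"].to_numpy(),
            session_bounds=bounds,
        )

    def trajectory(self, params: MoodParams) -> MoodTrajectory:
        """TML over all trials, restarting the recursion at session starts."""
        tmls, fs, raws = [], [], []
        for lo, hi in self.session_bounds:
            traj = compute_tml(self.feedback_signs[lo - 1 : hi], params)
            tmls.append(traj.tml)
            fs.append(traj.perceived_feedback)
            raws.append(traj.raw_feedback)
        return MoodTrajectory(
            tml=np.concatenate(tmls),
            perceived_feedback=np.concatenate(fs),
            raw_feedback=np.concatenate(raws),
        )

    def _neg_log_lik(self, x: np.ndarray) -> float:
        params, sd = _unpack(x, self.n_trials)
        if params.loop_gain() >= _LOOP_GAIN_LIMIT:
            return np.inf
        try:
            traj = self.trajectory(params)
        except TmlDivergenceError:
            return np.inf
        pred = traj.tml[self.rated_trials - 1]
        resid = self.ratings_z - pred
        n = resid.size
        return 0.5 * np.sum(resid**2) / sd**2 + n * np.log(sd) + 0.5 * n * np.log(2 * np.pi)

    def fit(self, n_starts: int = 4, seed: int = 0) -> MoodResults:
        x0 = np.array([0.0, 0.1, 0.0, special.logit(0.69), 0.1, 0.0, np.log(0.5)])
        res = map_laplace_fit(self._neg_log_lik, x0, n_starts=n_starts, seed=seed)
        params, sd = _unpack(res.x, self.n_trials)
        return MoodResults(
            params=params,
            log_evidence=res.log_evidence,
            residual_sd=sd,
            fitted_tml=self.trajectory(params),
            model="mood",
            n_rated=self.rated_trials.size,
            map_fit=res,
        )


class MoodNullModel(MoodModel):
    """Control model: mood is a linear function of trial index only."""

    def __init__(self, rated_trials, ratings, n_trials: int):
        # feedback is irrelevant to the null model; a dummy series keeps the base ctor happy
        super().__init__(rated_trials, ratings, np.ones(n_trials, dtype=int))

    @classmethod
    def from_trials(cls, trials) -> "MoodNullModel":
        rated = trials[trials["has_rating"]]
        col = "trial_index_global" if "trial_index_global" in trials.columns else "trial_index"
        return cls(rated[col].to_numpy(), rated["mood_rating"].to_numpy(), len(trials))

    def _neg_log_lik_null(self, x: np.ndarray) -> float:
        a, bs, logsd = x
        sd = np.exp(logsd)
        pred = a + (bs / self.n_trials) * self.rated_trials
        resid = self.ratings_z - pred
        n = resid.size
        return 0.5 * np.sum(resid**2) / sd**2 + n * np.log(sd) + 0.5 * n * np.log(2 * np.pi)

    def fit(self, n_starts: int = 3, seed: int = 0) -> MoodResults:
        x0 = np.array([0.0, 0.0, np.log(0.5)])
        res = map_laplace_fit(self._neg_log_lik_null, x0, n_starts=n_starts, seed=seed)
        a, bs, logsd = res.x
        return MoodResults(
            params=None,
            log_evidence=res.log_evidence,
            residual_sd=float(np.exp(logsd)),
            fitted_tml=None,
            model="null",
            n_rated=self.rated_trials.size,
            map_fit=res,
            trend=(float(a), float(bs / self.n_trials)),
        )


def compare_mood_models(evidence_pairs, seed: int = 0):
    """Random-effects Bayesian comparison of mood vs. time-only model.

    Parameters
    ----------
    evidence_pairs : sequence of (log_evidence_mood, log_evidence_null)
        per subject.

    Returns
    -------
    BMSResult (from `moodrisk.stats`) over the 2-model space, plus the
    per-subject evidence-difference signs in ``delta_lme``.
    """
    from .stats import rfx_bms

    lme = np.asarray(evidence_pairs, dtype=float)
    if lme.ndim != 2 or lme.shape[1] != 2 or lme.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2) x 2 log evidences")
    if not np.all(np.isfinite(lme)):
        raise ValueError("non-finite log evidence")
    result = rfx_bms(lme, seed=seed)
    result.delta_lme = lme[:, 0] - lme[:, 1]
    return result
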