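"""Expected-utility model of risky challenge acceptance.

An offer combines a gain prospect g (euros), a loss prospect l (euros)
and a challenge difficulty expressed as a tolerated timing margin m
(seconds) around the 1-s target.  With a Gaussian model of the
subject's timing precision (sd sigma), the probability of succeeding is

    ps = Phi(m / sigma) - Phi(-m / sigma)

and the offer's utility and acceptance probability are

    u = k0 + ps * kg * g - (1 - ps) * kl * l
    p(accept) = 1 / (1 + exp(-(u + kt * t)))

with gain/loss weights kg, kl, bias k0 and a linear fatigue drift kt
over trial index t.  Inversion is MAP + Laplace evidence on the
Bernoulli likelihood, mirroring the mood-model machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from ._inversion import MapFitResult, map_laplace_fit

__all__ = [
    "Offer",
    "ChoiceParams",
    "success_probability",
    "invert_success_level",
    "difficulty_to_success",
    "calibrated_sigma",
    "expected_utility",
    "acceptance_probability",
    "ChoiceModel",
    "ChoiceResults",
    "regress_residuals",
    "fit_baseline_split",
]

#: theoretical success rates at the five nominal difficulty levels
LEVEL_SUCCESS = {1: 0.75, 2: 0.65, 3: 0.55, 4: 0.45, 5: 0.35}

_T_CAP = 1e6  # cap for t statistics on perfect fits


@dataclass(frozen=True)
class Offer:
    """One three-dimensional offer: gain, loss (euros) and timing margin (s)."""

    gain: float
    loss: float
    margin: float
    trial_index: int = 1

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass(frozen=True)
class ChoiceParams:
    """Free parameters of the expected-utility choice model."""

    k0: float = 0.0
    kg: float = 1.0
    kl: float = 1.0
    sigma: float = 0.1
    kt: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def success_probability(margin, sigma) -> np.ndarray | float:
    """Mass of the N(0, sigma^2) timing-error distribution within +/-margin."""
    margin = np.asarray(margin, dtype=float)
    if np.any(margin < 0):
        raise ValueError("margin must be non-negative")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    ps = special.erf(margin / (np.asarray(sigma) * np.sqrt(2.0)))
    return float(ps) if ps.ndim == 0 else ps


def invert_success_level(target_ps, sigma) -> np.ndarray | float:
    """Margin whose Gaussian success probability equals ``target_ps``.

    Closed-form quantile inversion: m = sigma * Phi^-1((1 + ps) / 2);
    round-trips with :func:`success_probability` to ~1e-12.
    """
    ps = np.asarray(target_ps, dtype=float)
    if np.any((ps <= 0) | (ps >= 1)):
        raise ValueError("target success probability must lie strictly in (0, 1)")
    m = np.asarray(sigma) * stats.norm.ppf((1.0 + ps) / 2.0)
    return float(m) if m.ndim == 0 else m


def difficulty_to_success(level) -> np.ndarray | float:
    """Map difficulty level in [1, 5] to theoretical success in [0.75, 0.35].

    The endpoints are the calibrated level-1 and level-5 rates; fractional
    levels interpolate linearly between them.
    """
    level = np.asarray(level, dtype=float)
    if np.any((level < 1) | (level > 5)):
        raise ValueError("difficulty level must lie in [1, 5]")
    ps = 0.75 - 0.10 * (level - 1.0)
    return float(ps) if ps.ndim == 0 else ps


def calibrated_sigma(margins, levels) -> float:
    """Timing precision implied by the margin/difficulty pairing.

    Margins are assigned by inverting the target success rate of each
    nominal difficulty level at the subject's training-calibrated
    precision, so ``margin / Phi^-1((1 + ps_level) / 2)`` recovers that
    precision.  The median across trials guards against any irregular
    pairs.
    """
    margins = np.asarray(margins, dtype=float)
    z = stats.norm.ppf((1.0 + difficulty_to_success(levels)) / 2.0)
    sig = float(np.median(margins / z))
    if not np.isfinite(sig) or sig <= 0:
        raise ValueError("margins and difficulty levels imply no valid precision")
    return sig


def expected_utility(offer: Offer, params: ChoiceParams) -> float:
    """u = k0 + ps*kg*gain - (1-ps)*kl*loss with ps from the offer margin."""
    ps = success_probability(offer.margin, params.sigma)
    return params.k0 + ps * params.kg * offer.gain - (1.0 - ps) * params.kl * offer.loss


def acceptance_probability(offer: Offer, params: ChoiceParams) -> float:
    """Softmax (logistic) of expected utility plus the fatigue drift."""
    u = expected_utility(offer, params) + params.kt * offer.trial_index
    return float(special.expit(u))


def _utility_vec(gain, loss, margin, t, params: ChoiceParams):
    ps = success_probability(margin, params.sigma)
    u = params.k0 + ps * params.kg * gain - (1.0 - ps) * params.kl * loss
    return u + params.kt * t


def _unpack(x: np.ndarray, n_trials: int) -> ChoiceParams:
    """(k0, kg, kl, log sigma, kt_scaled) -> ChoiceParams (kt per trial)."""
    k0, kg, kl, logsig, kts = x
    return ChoiceParams(k0=k0, kg=kg, kl=kl, sigma=float(np.exp(logsig)), kt=kts / n_trials)


@dataclass
class ChoiceResults:
    """Fitted choice model: parameters, evidence, per-trial fit quantities."""

    params: ChoiceParams
    log_evidence: float
    p_accept: np.ndarray
    residuals: np.ndarray
    map_fit: MapFitResult
    n_trials: int

    def summary(self) -> str:
        p = self.params
        acc = float(np.mean(self.p_accept))
        return "\n".join(
            [
                "Choice model results",
                "=" * 34,
                f"trials:        {self.n_trials}",
                f"log evidence:  {self.log_evidence:.2f}",
                f"mean p(accept) {acc:.3f}",
                f"k0    {p.k0:+.3f}",
                f"kg    {p.kg:+.3f}",
                f"kl    {p.kl:+.3f}",
                f"sigma {p.sigma:.4f} s",
                f"kt    {p.kt:+.5f} per trial",
            ]
        )


class ChoiceModel:
    """Choice model bound to one subject's offers and accept/reject data.

    ``gains``/``losses`` in euros, ``margins`` in seconds, ``choices`` as
    0/1 (reject/accept), ``trial_index`` 1-based.
    """

    def __init__(
        self,
        gains,
        losses,
        margins,
        choices,
        trial_index=None,
        min_trials: int = 20,
        sigma_ref: float | None = None,
    ):
        self.gains = np.asarray(gains, dtype=float)
        self.losses = np.asarray(losses, dtype=float)
        self.margins = np.asarray(margins, dtype=float)
        self.choices = np.asarray(choices, dtype=float)
        n = self.gains.size
        if not (self.losses.size == self.margins.size == self.choices.size == n):
            raise ValueError("input series lengths differ")
        if n < min_trials:
            raise ValueError(f"need at least {min_trials} choices to invert the model")
        for name, v in (("gain", self.gains), ("loss", self.losses), ("margin", self.margins)):
            if np.ptp(v) == 0:
                raise ValueError(f"no variation in {name}")
        self.t = (
            np.arange(1, n + 1, dtype=float)
            if trial_index is None
            else np.asarray(trial_index, dtype=float)
        )
        self.n_trials = n
        if sigma_ref is not None and sigma_ref <= 0:
            raise ValueError("sigma_ref must be positive")
        #: prior centre for the timing precision; the task margins are set
        #: from each subject's calibrated precision, so when difficulty
        #: levels are available ``from_trials`` recovers that calibration
        #: value and centres the (weak) sigma prior on it
        self.sigma_ref = 0.1 if sigma_ref is None else float(sigma_ref)
        if self.choices.min() == self.choices.max():
            warnings.warn("all choices identical; fit will be prior-dominated")

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, min_trials: int = 20) -> "ChoiceModel":
        col = "trial_index_global" if "trial_index_global" in trials.columns else "trial_index"
        sigma_ref = None
        if "difficulty_level" in trials.columns:
            sigma_ref = calibrated_sigma(
                trials["margin"].to_numpy(), trials["difficulty_level"].to_numpy()
            )
        return cls(
            trials["gain"].to_numpy(),
            trials["loss"].to_numpy(),
            trials["margin"].to_numpy(),
            trials["choice"].to_numpy(),
            trials[col].to_numpy(),
            min_trials=min_trials,
            sigma_ref=sigma_ref,
        )

    def _neg_log_lik(self, x: np.ndarray) -> float:
        params = _unpack(x, self.n_trials)
        u = _utility_vec(self.gains, self.losses, self.margins, self.t, params)
        # log-likelihood of Bernoulli with logit u, numerically stable
        return float(np.sum(np.logaddexp(0.0, u) - self.choices * u))

    def predict(self, params: ChoiceParams) -> np.ndarray:
        u = _utility_vec(self.gains, self.losses, self.margins, self.t, params)
        return special.expit(u)

    def fit(self, n_starts: int = 4, seed: int = 0, fix_kt: float | None = None) -> ChoiceResults:
        x0 = np.array([0.0, 0.5, 0.5, np.log(self.sigma_ref), 0.0])
        fixed = None if fix_kt is None else {4: fix_kt * self.n_trials}
        # priors: weakly-informative on the utility weights, and a
        # calibration-centred prior on log sigma -- the subject's timing
        # precision was measured during training to set the margins, so
        # the fitted (subjective) precision is expected near that value
        prior_mean = np.array([0.0, 0.0, 0.0, np.log(self.sigma_ref), 0.0])
        prior_sd = np.array([1.0, 2.0, 2.0, 0.25, 2.0])
        res = map_laplace_fit(
            self._neg_log_lik,
            x0,
            prior_mean=prior_mean,
            prior_sd=prior_sd,
            n_starts=n_starts,
            seed=seed,
            fixed=fixed,
        )
        params = _unpack(res.x, self.n_trials)
        if fix_kt is not None:
            # bypass the scale/unscale round-trip so kt is bitwise exact
            params = replace(params, kt=fix_kt)
        p = self.predict(params)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return ChoiceResults(
            params=params,
            log_evidence=res.log_evidence,
            p_accept=p,
            residuals=self.choices - p,
            map_fit=res,
            n_trials=self.n_trials,
        )


def regress_residuals(residuals, regressor):
    """OLS of choice residuals on a regressor (with intercept).

    Returns (slope, standard error, t statistic); t is capped at 1e6 for
    numerically perfect fits.
    """
    y = np.asarray(residuals, dtype=float)
    x = np.asarray(regressor, dtype=float)
    if y.size != x.size:
        raise ValueError("length mismatch")
    if y.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance regressor")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = np.sum(xc**2)
    slope = np.sum(xc * yc) / sxx
    resid = yc - slope * xc
    dof = y.size - 2
    s2 = np.sum(resid**2) / dof
    se = np.sqrt(s2 / sxx)
    tval = slope / se if se > 0 else np.sign(slope) * _T_CAP
    return float(slope), float(se), float(np.clip(tval, -_T_CAP, _T_CAP))


def fit_baseline_split(
    trials: pd.DataFrame,
    baseline_bga,
    base_fit: ChoiceResults,
    *,
    seed: int = 0,
    p_range=(2.0 / 7.0, 5.0 / 7.0),
    min_per_half: int = 10,
):
    """Refit the choice model separately on high vs. low baseline-activity trials.

    Trials are first restricted to those whose full-data modelled
    acceptance probability lies between ``p_range`` fractions of the
    subject's acceptance range (min..max of fitted p_accept) — i.e.
    undetermined choices — then median-split by ``baseline_bga``.  The
    fatigue drift kt is frozen at the full-data estimate while k0, kg,
    kl, sigma are free.  Diagnostics report mean (Welch t) and variance
    (Levene) equality tests of the offer dimensions across halves.
    """
    baseline = np.asarray(baseline_bga, dtype=float)
    p = base_fit.p_accept
    if len(trials) != p.size or baseline.size != p.size:
        raise ValueError("trials, baseline series and base fit sizes differ")
    lo, hi = p.min(), p.max()
    lo_cut = lo + p_range[0] * (hi - lo)
    hi_cut = lo + p_range[1] * (hi - lo)
    eligible = (p >= lo_cut) & (p <= hi_cut)
    if eligible.sum() < 2 * min_per_half:
        raise ValueError(
            f"only {int(eligible.sum())} eligible trials in the undetermined-choice band"
        )
    med = np.median(baseline[eligible])
    high_mask = eligible & (baseline > med)
    low_mask = eligible & (baseline <= med)
    if high_mask.sum() < min_per_half or low_mask.sum() < min_per_half:
        raise ValueError("fewer than 10 trials in one baseline half")

    def refit(mask):
        sub = trials[mask]
        model = ChoiceModel.from_trials(sub, min_trials=min_per_half)
        return model.fit(seed=seed, fix_kt=base_fit.params.kt)

    res_high = refit(high_mask)
    res_low = refit(low_mask)

    diagnostics = {"n_high": int(high_mask.sum()), "n_low": int(low_mask.sum())}
    for dim in ("gain", "loss", "difficulty_level"):
        a = trials.loc[high_mask, dim].to_numpy()
        b = trials.loc[low_mask, dim].to_numpy()
        t_mean, p_mean = stats.ttest_ind(a, b, equal_var=False)
        w, p_var = stats.levene(a, b)
        diagnostics[dim] = {"p_mean_equal": float(p_mean), "p_var_equal": float(p_var)}
    return res_high.params, res_low.params, diagnostics
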