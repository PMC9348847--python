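"""Trialwise GLMs on epoched power and the associated group statistics.

Three statistical layers:

* per-site, per-timepoint ordinary least squares of normalised power on
  behavioural regressors (mood, theoretical mood level, choice
  residuals, last feedback + carried-over mood);
* cluster-level permutation correction across a region of interest: the
  regressor/response pairing is shuffled a fixed number of times per
  site, random combinations of one shuffle per site build a null
  distribution of maximal sums of across-site t-values over contiguous
  supra-threshold samples;
* random-effects Bayesian model selection (variational Dirichlet
  scheme) over families of models scored per recording site, reporting
  expected frequencies and exceedance probabilities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats as sstats

from .envelopes import EnvelopeEpochs

__all__ = [
    "GLMResult",
    "ClusterResult",
    "BMSResult",
    "timepoint_glm",
    "dual_site_glm",
    "cluster_permutation",
    "conditional_glm",
    "extreme_selector",
    "median_split_selector",
    "baseline_extreme_selector",
    "band_model_family",
    "BAND_FAMILY_NAMES",
    "rfx_bms",
    "feedback_decomposition_glm",
    "group_random_effects",
]

_T_CAP = 1e6


@dataclass
class GLMResult:
    """Per-site, per-timepoint slope estimates and their t statistics."""

    betas: np.ndarray  # sites x time (or regressors x sites x time)
    tvalues: np.ndarray
    design: list
    n_trials: int
    times: np.ndarray | None = None
    site_labels: list | None = None


@dataclass
class BMSResult:
    """Random-effects model-selection posterior over a model space."""

    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    dirichlet_alpha: np.ndarray
    model_names: list | None = None
    delta_lme: np.ndarray | None = None

    def summary(self) -> str:
        names = self.model_names or [f"model {i + 1}" for i in range(self.dirichlet_alpha.size)]
        lines = ["Random-effects Bayesian model selection", "=" * 40]
        for n, ef, xp in zip(names, self.expected_frequencies, self.exceedance_probabilities):
            lines.append(f"{n:<24s} Ef={ef:6.3f}  Xp={xp:6.3f}")
        return "\n".join(lines)


@dataclass
class ClusterResult:
    """Observed temporal clusters and their permutation-corrected p-values."""

    clusters: list
    alpha: float
    n_shuffles: int
    n_combinations: int
    t_obs: np.ndarray
    times: np.ndarray | None
    null_max_masses: np.ndarray

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c["p_corr"] < 0.05]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant regressor")
    return (x - x.mean()) / sd


def _simple_slopes(Y: np.ndarray, x: np.ndarray):
    """OLS slope + t of Y[trial, ...] on x[trial] with intercept, vectorised."""
    n = x.size
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    Yc = Y - Y.mean(axis=0, keepdims=True)
    b = np.tensordot(xc, Yc, axes=(0, 0)) / sxx
    syy = np.sum(Yc**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.maximum(syy - b**2 * sxx, 0.0) / max(n - 2, 1)
        t = b / np.sqrt(s2 / sxx)
    return b, np.clip(np.nan_to_num(t, nan=0.0, posinf=_T_CAP, neginf=-_T_CAP), -_T_CAP, _T_CAP)


def timepoint_glm(epochs: EnvelopeEpochs, regressor, normalize: bool = True) -> GLMResult:
    """Regress power on a trial regressor at every site and time sample."""
    x = np.asarray(regressor, dtype=float)
    if x.size != epochs.n_trials:
        raise ValueError("regressor length does not match trial count")
    if normalize:
        x = _zscore(x)
    elif np.ptp(x) == 0:
        raise ValueError("constant regressor")
    b, t = _simple_slopes(epochs.data, x)
    return GLMResult(
        betas=b,
        tvalues=t,
        design=["regressor"],
        n_trials=epochs.n_trials,
        times=epochs.times,
        site_labels=epochs.site_labels,
    )


def _multi_ols(y: np.ndarray, X: np.ndarray):
    """OLS of y on X (with intercept prepended): (betas, t) per column of X."""
    n = y.size
    A = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = max(n - A.shape[1], 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
    t = coef / se
    return coef[1:], np.clip(t[1:], -_T_CAP, _T_CAP)


def dual_site_glm(tml, bga_a, bga_b, collinearity_limit: float = 0.99):
    """Regress the mood level on the power of two sites jointly.

    ``bga_a``/``bga_b`` may be trial series (n,) or trial x time arrays;
    returns (beta1, beta2, t1, t2) as scalars or per-timepoint arrays.
    Numerically collinear regressor pairs are rejected.
    """
    y = np.asarray(tml, dtype=float)
    a = np.atleast_2d(np.asarray(bga_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(bga_b, dtype=float).T).T
    if a.shape != b.shape or a.shape[0] != y.size:
        raise ValueError("shape mismatch between tml and site power")
    r = np.corrcoef(a.mean(axis=1), b.mean(axis=1))[0, 1]
    if abs(r) > collinearity_limit:
        raise ValueError(f"site pair collinear (|r|={abs(r):.3f}); skip this pair")
    T = a.shape[1]
    b1 = np.empty(T)
    b2 = np.empty(T)
    t1 = np.empty(T)
    t2 = np.empty(T)
    for j in range(T):
        coef, t = _multi_ols(y, np.column_stack([a[:, j], b[:, j]]))
        b1[j], b2[j] = coef
        t1[j], t2[j] = t
    if T == 1:
        return b1[0], b2[0], t1[0], t2[0]
    return b1, b2, t1, t2


def _max_cluster_masses(T: np.ndarray, tcrit: float) -> np.ndarray:
    """Maximal |sum of t| over contiguous same-sign supra-threshold runs.

    ``T`` is (draws x time); returns one mass per draw (0 where no
    sample exceeds the threshold).
    """
    pos = T > tcrit
    neg = T < -tcrit
    n = T.shape[0]
    run_p = np.zeros(n)
    run_n = np.zeros(n)
    best = np.zeros(n)
    for j in range(T.shape[1]):
        tj = T[:, j]
        run_p = np.where(pos[:, j], run_p + tj, 0.0)
        run_n = np.where(neg[:, j], run_n + tj, 0.0)
        best = np.maximum(best, np.maximum(run_p, -run_n))
    return best


def _clusters_from_t(t_obs: np.ndarray, tcrit: float, times) -> list:
    out = []
    for sign in (+1, -1):
        mask = (sign * t_obs) > tcrit
        j = 0
        n = mask.size
        while j < n:
            if mask[j]:
                k = j
                while k + 1 < n and mask[k + 1]:
                    k += 1
                out.append(
                    {
                        "start_idx": j,
                        "end_idx": k,
                        "start_s": float(times[j]) if times is not None else float(j),
                        "end_s": float(times[k]) if times is not None else float(k),
                        "mass": float(t_obs[j : k + 1].sum()),
                        "sign": sign,
                    }
                )
                j = k + 1
            else:
                j += 1
    out.sort(key=lambda c: c["start_idx"])
    return out


def _site_null_betas(Y: np.ndarray, x: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Slope series for each permutation of the regressor. Y: trials x T."""
    Xp = x[perms]  # K x trials
    Xc = Xp - Xp.mean(axis=1, keepdims=True)
    sxx = np.sum(Xc**2, axis=1)  # K
    Yc = Y - Y.mean(axis=0, keepdims=True)
    return (Xc @ Yc) / sxx[:, None]  # K x T


def cluster_permutation(
    epochs: EnvelopeEpochs,
    regressor,
    alpha: float = 0.05,
    n_shuffles: int = 300,
    n_combinations: int = 60_000,
    seed: int = 0,
    exhaustive: bool = False,
    chunk: int = 1000,
) -> ClusterResult:
    """Cluster-corrected test of a trialwise effect across an ROI's sites.

    Observed statistic: per time sample, a two-sided one-sample t across
    the sites' OLS slopes; clusters are maximal contiguous runs of
    same-sign supra-threshold t (pointwise p < ``alpha``), scored by the
    sum of t.  Null: ``n_shuffles`` trial-label permutations of the
    regressor are pre-computed per site; each of ``n_combinations``
    draws picks one shuffle per site and records the maximal absolute
    cluster mass.  Corrected p-values use the add-one convention
    ``(1 + #null >= |mass|) / (1 + n_combinations)``.

    ``regressor`` may be a single trial series shared by all sites or a
    sites x trials array (one regressor per site, e.g. when sites come
    from different subjects).  With ``exhaustive=True`` all
    ``n_shuffles ** n_sites`` combinations are enumerated instead of
    sampled (small problems only; used by the brute-force oracle tests).
    """
    data = epochs.data  # trials x sites x T
    n_trials, n_sites, T = data.shape
    if n_sites < 2:
        raise ValueError("ROI needs at least 2 sites")
    if n_combinations < 100 and not exhaustive:
        warnings.warn("fewer than 100 combinations gives a coarse p-value resolution")
    reg = np.asarray(regressor, dtype=float)
    if reg.ndim == 1:
        reg = np.tile(reg, (n_sites, 1))
    if reg.shape != (n_sites, n_trials):
        raise ValueError("regressor must be (n_trials,) or (n_sites, n_trials)")
    reg = np.array([_zscore(r) for r in reg])

    rng = np.random.default_rng(seed)
    # observed across-site t series
    betas_obs = np.empty((n_sites, T))
    for s in range(n_sites):
        betas_obs[s], _ = _simple_slopes(data[:, s, :], reg[s])
    tcrit = float(sstats.t.ppf(1.0 - alpha / 2.0, df=n_sites - 1))
    t_obs = _across_site_t(betas_obs[None])[0]
    clusters = _clusters_from_t(t_obs, tcrit, epochs.times)

    # per-site null slope series
    perms = np.array([rng.permutation(n_trials) for _ in range(n_shuffles)])
    betas_null = np.empty((n_sites, n_shuffles, T))
    for s in range(n_sites):
        betas_null[s] = _site_null_betas(data[:, s, :], reg[s], perms)

    if exhaustive:
        combos = np.array(list(itertools.product(range(n_shuffles), repeat=n_sites)))
    else:
        combos = rng.integers(0, n_shuffles, size=(n_combinations, n_sites))
    n_comb = combos.shape[0]
    null_max = np.empty(n_comb)
    site_ix = np.arange(n_sites)
    for a in range(0, n_comb, chunk):
        idx = combos[a : a + chunk]  # C x S
        b = betas_null[site_ix[None, :], idx]  # C x S x T
        tser = _across_site_t(b)
        null_max[a : a + idx.shape[0]] = _max_cluster_masses(tser, tcrit)

    for c in clusters:
        c["p_corr"] = float((1 + np.sum(null_max >= abs(c["mass"]))) / (1 + n_comb))
    return ClusterResult(
        clusters=clusters,
        alpha=alpha,
        n_shuffles=n_shuffles,
        n_combinations=n_comb,
        t_obs=t_obs,
        times=epochs.times,
        null_max_masses=null_max,
    )


def _across_site_t(b: np.ndarray) -> np.ndarray:
    """One-sample t across axis 1 of (draws x sites x T)."""
    S = b.shape[1]
    m = b.mean(axis=1)
    sd = b.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(S))
    return np.clip(np.nan_to_num(t, nan=0.0, posinf=_T_CAP, neginf=-_T_CAP), -_T_CAP, _T_CAP)


# ---------------------------------------------------------------------------
# conditional (trial-subset) regressions


def extreme_selector(values, frac: float, side: str) -> np.ndarray:
    """Mask of the ``frac`` highest (side='high') or lowest trials by value."""
    v = np.asarray(values, dtype=float)
    k = int(round(frac * v.size))
    order = np.argsort(v)
    idx = order[-k:] if side == "high" else order[:k]
    mask = np.zeros(v.size, dtype=bool)
    mask[idx] = True
    return mask


def median_split_selector(values, side: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    return v > med if side == "high" else v <= med


def baseline_extreme_selector(
    baseline, frac: float, side: str, response_times=None, rt_cutoff: float = 1.6
) -> np.ndarray:
    """40 %-extremes split by baseline activity with fast-response exclusion."""
    b = np.asarray(baseline, dtype=float)
    keep = np.ones(b.size, dtype=bool)
    if response_times is not None:
        keep &= np.asarray(response_times, dtype=float) >= rt_cutoff
    sub = np.where(keep)[0]
    mask = np.zeros(b.size, dtype=bool)
    k = int(round(frac * sub.size))
    order = sub[np.argsort(b[sub])]
    mask[order[-k:] if side == "high" else order[:k]] = True
    return mask


def conditional_glm(epochs: EnvelopeEpochs, regressor, selector) -> GLMResult:
    """Timepoint GLM restricted to a trial subset.

    ``selector`` is a boolean trial mask or a callable producing one.
    """
    mask = selector(np.asarray(regressor)) if callable(selector) else np.asarray(selector)
    mask = mask.astype(bool)
    if mask.size != epochs.n_trials:
        raise ValueError("selector mask length mismatch")
    if mask.sum() < 10:
        raise ValueError("selector keeps fewer than 10 trials")
    sub = EnvelopeEpochs(
        data=epochs.data[mask],
        times=epochs.times,
        site_labels=epochs.site_labels,
        sampling_rate=epochs.sampling_rate,
        zscored=epochs.zscored,
    )
    return timepoint_glm(sub, np.asarray(regressor, dtype=float)[mask])


# ---------------------------------------------------------------------------
# frequency-band model family + random-effects BMS

_EXTRA_BANDS = ("gamma", "beta", "alpha", "theta")

#: the 16 candidate models: baseline broadband gamma plus every subset of
#: the lower bands
BAND_FAMILY_NAMES = ["bga"] + [
    "bga+" + "+".join(combo)
    for r in range(1, 5)
    for combo in itertools.combinations(_EXTRA_BANDS, r)
]


def _gaussian_lme(y: np.ndarray, X: np.ndarray) -> float:
    """BIC-style log model evidence of a Gaussian linear model."""
    n = y.size
    A = np.column_stack([np.ones(n), X])
    k = A.shape[1]
    if np.linalg.matrix_rank(A) < k:
        return -np.inf
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ coef) ** 2))
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return loglik - 0.5 * (k + 1) * np.log(n)


def band_model_family(band_powers: dict, tml) -> np.ndarray:
    """Log evidences of the 16 band GLMs for one recording site.

    ``band_powers`` maps band name (bga, gamma, beta, alpha, theta) to a
    baseline-averaged trial series.  Rank-deficient designs score -inf.
    """
    y = np.asarray(tml, dtype=float)
    for name in ("bga",) + _EXTRA_BANDS:
        if name not in band_powers:
            raise ValueError(f"missing band series {name!r}")
    lmes = np.empty(len(BAND_FAMILY_NAMES))
    for i, model in enumerate(BAND_FAMILY_NAMES):
        cols = [np.asarray(band_powers[b], dtype=float) for b in model.split("+")]
        lmes[i] = _gaussian_lme(y, np.column_stack(cols))
    return lmes


def rfx_bms(
    log_evidences,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_samples: int = 100_000,
    seed: int = 0,
    model_names=None,
) -> BMSResult:
    """Random-effects Bayesian model selection (variational Dirichlet).

    Treats the model identity per site/subject as a random effect with a
    Dirichlet population prior; iterates posterior model assignments and
    Dirichlet counts to convergence, then estimates exceedance
    probabilities (probability each model is the most frequent) by
    Monte-Carlo sampling of the Dirichlet posterior.
    """
    lme = np.asarray(log_evidences, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("need (>=2 sites) x (>=2 models) log evidences")
    keep = np.all(np.isfinite(lme), axis=0)
    if not np.all(keep):
        # models flagged unusable on some site (e.g. rank-deficient designs)
        raise ValueError("non-finite log evidence; drop unusable models first")
    n, K = lme.shape
    alpha = np.full(K, float(alpha0))
    for _ in range(max_iter):
        log_u = lme + (special.digamma(alpha) - special.digamma(alpha.sum()))[None, :]
        g = np.exp(log_u - log_u.max(axis=1, keepdims=True))
        g /= g.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        raise RuntimeError("RFX-BMS did not converge")
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=K) / n_samples
    return BMSResult(
        expected_frequencies=alpha / alpha.sum(),
        exceedance_probabilities=xp,
        dirichlet_alpha=alpha,
        model_names=list(model_names) if model_names is not None else None,
    )


def feedback_decomposition_glm(bga, feedback_signs, prior_tml):
    """Regress power on (last feedback, previous-trial TML) jointly.

    ``bga`` may be a trial series (e.g. averaged over a cluster window)
    or a trials x time array; returns a GLMResult with two slope rows.
    """
    y = np.asarray(bga, dtype=float)
    X = np.column_stack(
        [np.asarray(feedback_signs, dtype=float), np.asarray(prior_tml, dtype=float)]
    )
    r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
    if np.isfinite(r) and abs(r) > 0.99:
        warnings.warn("last-feedback and prior-TML regressors are collinear")
    if y.ndim == 1:
        coef, t = _multi_ols(y, X)
        betas = coef[:, None]
        tv = t[:, None]
    else:
        T = y.shape[1]
        betas = np.empty((2, T))
        tv = np.empty((2, T))
        for j in range(T):
            betas[:, j], tv[:, j] = _multi_ols(y[:, j], X)
    return GLMResult(
        betas=betas,
        tvalues=tv,
        design=["last_feedback", "prior_tml"],
        n_trials=X.shape[0],
    )


def group_random_effects(site_values, subject_ids):
    """Average site-level estimates within subject, then one-sample t.

    Returns (t, p, n_subjects, subject_means).
    """
    v = np.asarray(site_values, dtype=float)
    ids = np.asarray(subject_ids)
    if v.size != ids.size:
        raise ValueError("length mismatch")
    uniq = np.unique(ids)
    means = np.array([v[ids == u].mean() for u in uniq])
    if means.size < 3:
        raise ValueError("need at least 3 subjects")
    if means.std(ddof=1) == 0:
        t = np.sign(means.mean()) * _T_CAP
        return float(t), 0.0 if means.mean() != 0 else 1.0, means.size, means
    t, p = sstats.ttest_1samp(means, 0.0)
    return float(np.clip(t, -_T_CAP, _T_CAP)), float(p), means.size, means
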