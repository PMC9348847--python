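"""MAP estimation with Laplace model evidence.

Shared machinery for inverting the behavioural models: maximum a
posteriori estimation over unconstrained parameters (bounded parameters
enter through logistic / log transforms chosen by the caller), with the
log model evidence approximated at the mode,

    log p(y | model) ~= log p(y | theta*) + log p(theta*)
                        + d/2 * log(2*pi) - 1/2 * log det H,

where H is the Hessian of the negative log joint at the mode theta*.
This is the same accuracy/complexity trade-off a variational-Laplace
scheme reports, computed from a finite-difference Hessian instead of an
iterated variational update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["MapFitResult", "map_laplace_fit", "gaussian_log_prior", "numeric_hessian"]

#: penalty returned to the optimizer where the model is numerically invalid
_BAD = 1e10


def gaussian_log_prior(x: np.ndarray, mean=0.0, sd=2.0) -> float:
    """Independent Gaussian log prior on the unconstrained parameter vector.

    ``mean`` and ``sd`` may be scalars or per-parameter arrays.
    """
    x = np.asarray(x, float)
    mean = np.broadcast_to(np.asarray(mean, float), x.shape)
    sd = np.broadcast_to(np.asarray(sd, float), x.shape)
    z = (x - mean) / sd
    return float(
        -0.5 * np.sum(z**2) - x.size * 0.5 * np.log(2 * np.pi) - np.sum(np.log(sd))
    )


def numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    x = np.asarray(x, float)
    d = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fpp = f(x + ei)
                fmm = f(x - ei)
                H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
            else:
                fpp = f(x + ei + ej)
                fpm = f(x + ei - ej)
                fmp = f(x - ei + ej)
                fmm = f(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


@dataclass
class MapFitResult:
    """Outcome of a multistart MAP fit on the unconstrained scale."""

    x: np.ndarray
    neg_log_joint: float
    log_evidence: float
    hessian: np.ndarray
    cov: np.ndarray
    converged: bool
    n_starts: int
    messages: list = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        """Laplace standard errors on the unconstrained scale."""
        d = np.diag(self.cov)
        return np.sqrt(np.where(d > 0, d, np.nan))


def map_laplace_fit(
    neg_log_lik,
    x0: np.ndarray,
    *,
    prior_mean=0.0,
    prior_sd=2.0,
    n_starts: int = 4,
    start_scale: float = 1.0,
    seed: int = 0,
    fixed: dict[int, float] | None = None,
) -> MapFitResult:
    """Multistart MAP fit with Laplace log evidence.

    Parameters
    ----------
    neg_log_lik
        Callable mapping the full unconstrained parameter vector to the
        negative log likelihood.  May return non-finite values for
        pathological parameters; these are treated as a large penalty.
    x0
        Initial parameter vector (also the first start).
    n_starts
        Total number of optimisation starts; starts beyond the first are
        Gaussian perturbations of ``x0`` with scale ``start_scale``,
        drawn from a generator seeded with ``seed``.
    fixed
        Map of parameter index -> frozen value.  Frozen parameters do
        not count as free dimensions in the evidence (used e.g. when a
        drift weight is pinned to a previously fitted value).
    """
    x0 = np.asarray(x0, float)
    fixed = fixed or {}
    free_idx = np.array([i for i in range(x0.size) if i not in fixed], dtype=int)
    pm_free = np.broadcast_to(np.asarray(prior_mean, float), x0.shape)[free_idx]
    psd_free = np.broadcast_to(np.asarray(prior_sd, float), x0.shape)[free_idx]

    def embed(xf: np.ndarray) -> np.ndarray:
        full = x0.copy()
        full[free_idx] = xf
        for i, v in fixed.items():
            full[i] = v
        return full

    def nlj(xf: np.ndarray) -> float:
        full = embed(xf)
        nll = neg_log_lik(full)
        if not np.isfinite(nll):
            return _BAD
        return float(nll) - gaussian_log_prior(xf, pm_free, psd_free)

    rng = np.random.default_rng(seed)
    starts = [x0[free_idx]]
    for _ in range(n_starts - 1):
        starts.append(x0[free_idx] + start_scale * rng.standard_normal(free_idx.size))

    best = None
    messages = []
    for s in starts:
        res = optimize.minimize(nlj, s, method="L-BFGS-B")
        messages.append(str(res.message))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= _BAD / 2:
        raise RuntimeError(
            "MAP optimisation failed on all starts; best incumbent: "
            f"{None if best is None else best.x}"
        )

    xf = best.x
    d = xf.size
    H = numeric_hessian(nlj, xf)
    # regularise a non-positive-definite Hessian (flat directions) with jitter
    jitter = 0.0
    for _ in range(12):
        sign, logdet = np.linalg.slogdet(H + jitter * np.eye(d))
        if sign > 0:
            break
        jitter = max(jitter * 10, 1e-8)
    Hreg = H + jitter * np.eye(d)
    sign, logdet = np.linalg.slogdet(Hreg)
    cov = np.linalg.inv(Hreg)
    log_evidence = -best.fun + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet

    full = embed(xf)
    full_cov = np.zeros((x0.size, x0.size))
    full_cov[np.ix_(free_idx, free_idx)] = cov
    return MapFitResult(
        x=full,
        neg_log_joint=float(best.fun),
        log_evidence=float(log_evidence),
        hessian=Hreg,
        cov=full_cov,
        converged=bool(best.success),
        n_starts=n_starts,
        messages=messages,
    )
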