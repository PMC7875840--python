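"""Maximum-likelihood fits of number-line responses under scalar variability.

Responses ``R_k`` to numerosities ``N_k`` are modelled as Gaussian around a
predicted mean with SD proportional to that mean (scalar variability, i.e. a
constant coefficient of variation ``sigma_n``):

* linear model:  ``mu_k = intercept + slope * N_k``,  ``sd_k = sigma_n * mu_k``
* power model:   ``mu_k = scale * N_k**exponent``,    ``sd_k = sigma_n * mu_k``

All three parameters are estimated jointly by maximising the likelihood over
trials, which handles unbalanced designs (conditions with few trials) better
than per-numerosity summary statistics.  Summary-level SD-vs-N power fits and
coefficient-of-variation measures are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LinearMLEFit",
    "PowerFit",
    "NoiseSummary",
    "FitError",
    "negloglik_linear",
    "negloglik_power",
    "fit_linear_mle",
    "fit_power_mle",
    "fit_sd_power",
    "compute_noise_summary",
]

# Large finite penalty returned when a parameter vector implies a
# non-positive predicted mean/SD; keeps the optimizer inside the valid region
# without NaNs.
_PENALTY = 1e10

_LOG_2PI = float(np.log(2.0 * np.pi))


class FitError(RuntimeError):
    """Raised when the optimizer fails to converge from every restart."""


@dataclass
class LinearMLEFit:
    """Joint MLE of a linear number-line mapping with scalar variability."""

    intercept: float
    slope: float
    sigma_n: float
    log_likelihood: float
    n_trials: int
    converged: bool = True


@dataclass
class PowerFit:
    """Joint MLE of a power-law number-line mapping with scalar variability."""

    scale: float
    exponent: float
    sigma_n: float
    log_likelihood: float
    n_trials: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.exponent <= 1.5):
            warnings.warn(
                f"power exponent {self.exponent:.3f} outside the typical "
                "(0, 1.5] range for number-line mapping",
                stacklevel=2,
            )


@dataclass
class NoiseSummary:
    """Per-condition response-noise summaries.

    ``internal_noise`` is the SD of response/numerosity ratios;
    ``cv`` averages SD(R|N)/N over numerosities; ``sd_by_numerosity``
    holds the sample SD of responses at each numerosity with >= 2 trials.
    """

    internal_noise: float
    cv: float
    sd_by_numerosity: dict[float, float] = field(default_factory=dict)


def _neg_log_gauss(resid: np.ndarray, sd: np.ndarray) -> float:
    return float(0.5 * np.sum(_LOG_2PI + 2.0 * np.log(sd) + (resid / sd) ** 2))


def negloglik_linear(intercept, slope, sigma_n, n_list, r_list) -> float:
    """Negative log-likelihood of the linear scalar-variability model.

    ``-sum_k log Normal(R_k; mu_k, sigma_n * mu_k)`` with
    ``mu_k = intercept + slope * N_k``.  Returns a large finite penalty if
    any predicted mean (hence SD) is non-positive.
    """
    n = np.asarray(n_list, dtype=float)
    r = np.asarray(r_list, dtype=float)
    if n.size == 0 or n.size != r.size:
        raise ValueError("N and R must be equal-length, non-empty")
    mu = intercept + slope * n
    sd = sigma_n * mu
    if sigma_n <= 0 or np.any(mu <= 0):
        return _PENALTY
    return _neg_log_gauss(r - mu, sd)


def negloglik_power(scale, exponent, sigma_n, n_list, r_list) -> float:
    """Negative log-likelihood of the power scalar-variability model
    (``mu_k = scale * N_k**exponent``)."""
    n = np.asarray(n_list, dtype=float)
    r = np.asarray(r_list, dtype=float)
    if n.size == 0 or n.size != r.size:
        raise ValueError("N and R must be equal-length, non-empty")
    if sigma_n <= 0 or scale <= 0:
        return _PENALTY
    mu = scale * n ** exponent
    sd = sigma_n * mu
    return _neg_log_gauss(r - mu, sd)


def _check_fit_inputs(n: np.ndarray, r: np.ndarray) -> None:
    if n.size < 10:
        raise ValueError(f"need at least 10 trials, got {n.size}")
    if np.unique(n).size < 3:
        raise ValueError("need at least 3 distinct numerosities")


_LINEAR_BOUNDS = ((-10.0, 20.0), (1e-6, 5.0), (1e-4, 2.0))
_POWER_BOUNDS = ((1e-6, 5.0), (1e-6, 2.0), (1e-4, 2.0))


def _minimize_multistart(objective, x0_list, bounds):
    best = None
    for x0 in x0_list:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if not res.success:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= _PENALTY:
        raise FitError("optimizer failed to converge from every restart")
    return best


def _starts(rng: np.random.Generator, center: np.ndarray, bounds, n_restarts: int):
    """Deterministic start list: a data-driven centre plus random points."""
    starts = [center]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(n_restarts):
        starts.append(lo + rng.random(len(bounds)) * (hi - lo))
    return starts


def fit_linear_mle(
    n_list,
    r_list,
    init=None,
    bounds=_LINEAR_BOUNDS,
    n_restarts: int = 10,
    seed: int = 0,
) -> LinearMLEFit:
    """Fit intercept, slope and sigma_n jointly by maximum likelihood.

    Uses bounded quasi-Newton (L-BFGS-B) from a least-squares-informed start
    plus ``n_restarts`` random restarts within the bounds.
    """
    n = np.asarray(n_list, dtype=float)
    r = np.asarray(r_list, dtype=float)
    _check_fit_inputs(n, r)

    if init is None:
        # ordinary least squares for the mean, moment estimate for sigma_n
        slope, intercept = np.polyfit(n, r, 1)
        mu = np.clip(intercept + slope * n, 1e-6, None)
        sig = float(np.std((r - mu) / mu, ddof=1)) if n.size > 1 else 0.1
        init = np.array([
            float(np.clip(intercept, bounds[0][0], bounds[0][1])),
            float(np.clip(slope, bounds[1][0], bounds[1][1])),
            float(np.clip(sig, bounds[2][0] * 10, bounds[2][1])),
        ])
    rng = np.random.default_rng(seed)

    def objective(p):
        return negloglik_linear(p[0], p[1], p[2], n, r)

    best = _minimize_multistart(objective, _starts(rng, np.asarray(init, float), bounds, n_restarts), bounds)
    return LinearMLEFit(
        intercept=float(best.x[0]),
        slope=float(best.x[1]),
        sigma_n=float(best.x[2]),
        log_likelihood=-float(best.fun),
        n_trials=int(n.size),
        converged=bool(best.success),
    )


def fit_power_mle(
    n_list,
    r_list,
    init=None,
    bounds=_POWER_BOUNDS,
    n_restarts: int = 10,
    seed: int = 0,
) -> PowerFit:
    """Fit scale, exponent and sigma_n of the power mapping by maximum
    likelihood (same machinery as :func:`fit_linear_mle`)."""
    n = np.asarray(n_list, dtype=float)
    r = np.asarray(r_list, dtype=float)
    _check_fit_inputs(n, r)

    if init is None:
        # log-log regression start (responses <= 0 clipped away)
        pos = r > 0
        expn, logs = np.polyfit(np.log(n[pos]), np.log(r[pos]), 1)
        scale = float(np.exp(logs))
        mu = np.clip(scale * n ** expn, 1e-6, None)
        sig = float(np.std((r - mu) / mu, ddof=1)) if n.size > 1 else 0.1
        init = np.array([
            float(np.clip(scale, bounds[0][0], bounds[0][1])),
            float(np.clip(expn, bounds[1][0], bounds[1][1])),
            float(np.clip(sig, bounds[2][0] * 10, bounds[2][1])),
        ])
    rng = np.random.default_rng(seed)

    def objective(p):
        return negloglik_power(p[0], p[1], p[2], n, r)

    best = _minimize_multistart(objective, _starts(rng, np.asarray(init, float), bounds, n_restarts), bounds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # soft exponent-range warning handled by caller
        fit = PowerFit(
            scale=float(best.x[0]),
            exponent=float(best.x[1]),
            sigma_n=float(best.x[2]),
            log_likelihood=-float(best.fun),
            n_trials=int(n.size),
            converged=bool(best.success),
        )
    return fit


def fit_sd_power(sd_by_numerosity: dict[float, float]) -> tuple[float, float]:
    """Least-squares power fit ``SD(N) = scale * N**exponent`` in log-log space.

    Numerosities with zero SD are excluded (with a warning); at least three
    usable numerosities are required.  Returns ``(scale, exponent)``.
    """
    items = sorted(dict(sd_by_numerosity).items())
    n = np.array([k for k, _ in items], dtype=float)
    sd = np.array([v for _, v in items], dtype=float)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} numerosities with zero SD from power fit",
            stacklevel=2,
        )
    n, sd = n[keep], sd[keep]
    if n.size < 3:
        raise ValueError("need SDs at >= 3 numerosities")
    exponent, log_scale = np.polyfit(np.log(n), np.log(sd), 1)
    return float(np.exp(log_scale)), float(exponent)


def compute_noise_summary(trials: pd.DataFrame) -> dict[str, NoiseSummary]:
    """Per-condition noise summaries from a trial table.

    For each condition: ``internal_noise`` = sample SD of R/N over trials;
    ``cv`` = mean over numerosities of SD(R|N)/N; ``sd_by_numerosity`` maps
    each numerosity with >= 2 trials to the sample SD of its responses.
    Conditions with fewer than 2 trials are omitted with a warning.
    """
    out: dict[str, NoiseSummary] = {}
    for cond, grp in trials.groupby("condition", observed=True):
        if len(grp) < 2:
            warnings.warn(f"condition {cond!r} has < 2 trials; omitted", stacklevel=2)
            continue
        ratios = grp["response"].to_numpy(float) / grp["numerosity"].to_numpy(float)
        internal_noise = float(np.std(ratios, ddof=1))
        sd_by_n: dict[float, float] = {}
        cv_terms = []
        for n_val, sub in grp.groupby("numerosity"):
            if len(sub) >= 2:
                s = float(np.std(sub["response"].to_numpy(float), ddof=1))
                sd_by_n[float(n_val)] = s
                cv_terms.append(s / float(n_val))
        cv = float(np.mean(cv_terms)) if cv_terms else float("nan")
        out[str(cond)] = NoiseSummary(
            internal_noise=internal_noise, cv=cv, sd_by_numerosity=sd_by_n
        )
    return out
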