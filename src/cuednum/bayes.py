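"""Central-tendency (regression-to-the-mean) observer model.

The observer encodes a presented numerosity ``N`` as a Gaussian likelihood
centred on ``N`` with magnitude-dependent width ``sigma_R(N) = k * N**a``,
and combines it with a Gaussian prior over the number line (mean ``P̄``,
SD ``sigma_P``).  The predicted response is the posterior mean,

    R̂(N) = (P̄ * sigma_R² + N * sigma_P²) / (sigma_R² + sigma_P²),

a precision-weighted average that shrinks estimates toward the prior mean.
Because sensory noise grows with magnitude, shrinkage is stronger for large
numerosities, producing the compressive (power exponent < 1) number-line
mapping characteristic of central tendency.

Equivalently the posterior mean can be written as a weighted sum
``W_L * N + (1 - W_L) * P̄`` with likelihood weight

    W_L = sigma_P² / (x² * WF² + sigma_P²)

when sensory noise follows Weber scaling ``sigma_R = x * WF``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "BayesObserver",
    "MappingPrediction",
    "WeightCurve",
    "sigma_r",
    "posterior_mean",
    "likelihood_weight",
    "predict_mapping",
    "fit_prior",
    "nonlinearity_vs_noise_curve",
]


@dataclass(frozen=True)
class BayesObserver:
    """Parameters of the central-tendency observer.

    Parameters
    ----------
    prior_mean
        Centre of the Gaussian prior on the number line (dots).
    prior_sd
        SD of the prior (dots); larger values mean a flatter prior and
        less central tendency.
    noise_k
        Constant ``k`` of the sensory-noise law ``sigma_R = k * N**a``.
    noise_exponent
        Exponent ``a`` of the sensory-noise law: 0 gives constant noise,
        0.5 square-root scaling, 1 Weber's law.
    response_jitter_sd
        Amplitude of trial-to-trial Gaussian readout jitter added to the
        posterior mean when simulating responses; the jitter SD scales
        with numerosity as ``response_jitter_sd * N**noise_exponent``.
        Zero gives deterministic responses.
    """

    prior_mean: float = 15.0
    prior_sd: float = 5.0
    noise_k: float = 0.5
    noise_exponent: float = 0.5
    response_jitter_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.prior_sd <= 0:
            raise ValueError(f"prior_sd must be > 0, got {self.prior_sd}")
        if self.noise_k <= 0:
            raise ValueError(f"noise_k must be > 0, got {self.noise_k}")
        if self.response_jitter_sd < 0:
            raise ValueError(
                f"response_jitter_sd must be >= 0, got {self.response_jitter_sd}"
            )

    def sigma_r(self, numerosity):
        return sigma_r(numerosity, self.noise_k, self.noise_exponent)

    def jitter_sd(self, numerosity):
        return self.response_jitter_sd * np.asarray(numerosity, dtype=float) ** self.noise_exponent

    def predicted_response(self, numerosity):
        return posterior_mean(
            numerosity, self.prior_mean, self.prior_sd, self.sigma_r(numerosity)
        )


@dataclass
class MappingPrediction:
    """Predicted number-line mapping R̂(N) for one observer."""

    numerosities: np.ndarray
    predicted_response: np.ndarray
    params: BayesObserver
    r_squared: float | None = None


@dataclass
class WeightCurve:
    """Likelihood weight W_L as a function of magnitude for a fixed
    Weber fraction and prior width."""

    wf: float
    x_values: np.ndarray
    weights: np.ndarray = field(init=False)
    prior_sd: float = 17.0

    def __post_init__(self) -> None:
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.weights = likelihood_weight(self.x_values, self.wf, self.prior_sd)


def sigma_r(numerosity, noise_k: float, noise_exponent: float):
    """Sensory-noise SD ``k * N**a`` for numerosity ``N``.

    Scalar in, scalar out; array in, array out.
    """
    n = np.asarray(numerosity, dtype=float)
    if np.any(n < 1):
        raise ValueError("numerosity must be >= 1")
    if noise_k <= 0:
        raise ValueError("noise_k must be > 0")
    out = noise_k * n ** noise_exponent
    return out.item() if np.isscalar(numerosity) else out


def posterior_mean(numerosity, prior_mean: float, prior_sd: float, sigma_R):
    """Posterior mean of the Gaussian prior × Gaussian likelihood product.

    Equals ``numerosity`` when ``sigma_R == 0`` (noiseless likelihood) and
    approaches ``prior_mean`` as ``sigma_R`` grows.
    """
    n = np.asarray(numerosity, dtype=float)
    s_r = np.asarray(sigma_R, dtype=float)
    if prior_sd < 0 or np.any(s_r < 0):
        raise ValueError("standard deviations must be non-negative")
    if prior_sd == 0 and np.any((s_r == 0) & (n != prior_mean)):
        raise ValueError(
            "posterior mean undefined: both prior_sd and sigma_R are zero "
            "while N != prior_mean"
        )
    if prior_sd == 0:
        out = np.full_like(n, float(prior_mean))
    else:
        # shrinkage form of (P̄ σR² + N σP²)/(σR² + σP²): exact at N == P̄
        # and at σR == 0
        out = prior_mean + (n - prior_mean) * (prior_sd**2 / (s_r**2 + prior_sd**2))
    return out.item() if np.isscalar(numerosity) and np.isscalar(sigma_R) else out


def likelihood_weight(x, wf: float, prior_sd: float):
    """Weight of the sensory evidence in the posterior mean.

    ``W_L = sigma_P² / (x² WF² + sigma_P²)``; in (0, 1], equal to 1 for a
    noiseless likelihood (``wf = 0``) and decreasing in magnitude ``x``.
    Consistency with :func:`posterior_mean`:
    ``posterior_mean(x, P̄, sigma_P, x*wf) == W_L*x + (1-W_L)*P̄``.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    if wf < 0:
        raise ValueError("wf must be >= 0")
    xv = np.asarray(x, dtype=float)
    if np.any(xv <= 0):
        raise ValueError("x must be > 0")
    out = prior_sd**2 / (xv**2 * wf**2 + prior_sd**2)
    return out.item() if np.isscalar(x) else out


def predict_mapping(observer: BayesObserver, numerosities) -> MappingPrediction:
    """Predicted number-line responses R̂(N) for each numerosity."""
    n = np.asarray(numerosities, dtype=float)
    if n.size == 0:
        raise ValueError("numerosities must be non-empty")
    pred = observer.predicted_response(n)
    return MappingPrediction(numerosities=n, predicted_response=np.asarray(pred), params=observer)


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    rss = float(np.sum((observed - predicted) ** 2))
    tss = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - rss / tss


def fit_prior(
    mean_responses_by_n: dict[float, float],
    sigma_r_spec: tuple[float, float] | dict[float, float],
    prior_mean_mode: str = "fixed_value",
    prior_mean_value: float = 15.0,
    prior_sd_bounds: tuple[float, float] = (0.1, 100.0),
) -> tuple[BayesObserver, float]:
    """Fit the prior width (and optionally the prior mean) to mean responses.

    Parameters
    ----------
    mean_responses_by_n
        Mapping numerosity -> mean observed response.
    sigma_r_spec
        Either ``(noise_k, noise_exponent)`` defining ``sigma_R = k N**a``,
        or a mapping numerosity -> sigma_R.
    prior_mean_mode
        ``"fixed_value"`` pins the prior mean at ``prior_mean_value``;
        ``"fixed_midpoint"`` pins it at the midpoint of the tested
        numerosities; ``"free"`` estimates it jointly with the width.

    Returns
    -------
    (observer, r_squared)
        Fitted observer (with the fitted prior SD) and the variance
        explained, R² = 1 − RSS/TSS.
    """
    items = sorted(dict(mean_responses_by_n).items())
    if len(items) < 4:
        raise ValueError("need mean responses for at least 4 numerosities")
    n = np.array([k for k, _ in items], dtype=float)
    r = np.array([v for _, v in items], dtype=float)
    if np.allclose(r, r[0]):
        raise ValueError("degenerate data: all mean responses are equal")

    if isinstance(sigma_r_spec, dict):
        s_r = np.array([sigma_r_spec[k] for k, _ in items], dtype=float)
        noise_k, noise_exp = float(np.mean(s_r)), 0.0
    else:
        noise_k, noise_exp = sigma_r_spec
        s_r = sigma_r(n, noise_k, noise_exp)

    if prior_mean_mode == "fixed_value":
        p_mean = float(prior_mean_value)
    elif prior_mean_mode == "fixed_midpoint":
        p_mean = float((n.min() + n.max()) / 2.0)
    elif prior_mean_mode == "free":
        p_mean = None
    else:
        raise ValueError(f"unknown prior_mean_mode: {prior_mean_mode!r}")

    def rss(params: np.ndarray) -> float:
        sd = params[0]
        mean = params[1] if p_mean is None else p_mean
        pred = posterior_mean(n, mean, sd, s_r)
        return float(np.sum((r - pred) ** 2))

    if p_mean is None:
        res = optimize.minimize(
            rss,
            x0=np.array([5.0, float(np.mean(r))]),
            bounds=[prior_sd_bounds, (float(n.min()) - 10, float(n.max()) + 10)],
            method="L-BFGS-B",
        )
        best_sd, best_mean = float(res.x[0]), float(res.x[1])
    else:
        res = optimize.minimize_scalar(
            lambda sd: rss(np.array([sd])), bounds=prior_sd_bounds, method="bounded",
            options={"xatol": 1e-8},
        )
        best_sd, best_mean = float(res.x), p_mean

    observer = BayesObserver(
        prior_mean=best_mean,
        prior_sd=best_sd,
        noise_k=max(noise_k, 1e-12),
        noise_exponent=noise_exp,
        response_jitter_sd=0.0,
    )
    pred = posterior_mean(n, best_mean, best_sd, s_r)
    return observer, _r_squared(r, pred)


def nonlinearity_vs_noise_curve(
    prior_sd: float,
    wf_grid,
    numerosities,
    n_sim: int = 1000,
    seed: int = 0,
    prior_mean: float = 15.0,
    line_bounds: tuple[float, float] = (1.0, 35.0),
) -> list[tuple[float, float]]:
    """Model curve relating internal noise to number-line nonlinearity.

    For each Weber fraction ``WF`` in ``wf_grid``, simulate ``n_sim``
    responses per numerosity from an ideal observer with sensory noise
    ``sigma_R = N * WF`` (Weber scaling) and prior ``(prior_mean,
    prior_sd)``: the response is the posterior mean plus Gaussian noise of
    SD ``sigma_R``, clamped to the number line.  Internal noise is the SD
    of response/numerosity ratios and nonlinearity is the fitted power
    exponent of mean response vs numerosity.

    Returns a list of ``(internal_noise, power_exponent)`` pairs, one per
    Weber fraction, ordered as ``wf_grid``.
    """
    from .estimation import fit_power_mle

    wf_grid = np.atleast_1d(np.asarray(wf_grid, dtype=float))
    if np.any(wf_grid < 0):
        raise ValueError("wf_grid must be non-negative")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    n = np.asarray(numerosities, dtype=float)
    rng = np.random.default_rng(seed)

    curve: list[tuple[float, float]] = []
    for wf in wf_grid:
        s_r = n * wf
        pred = posterior_mean(n, prior_mean, prior_sd, s_r)
        n_rep = np.repeat(n, n_sim)
        mu_rep = np.repeat(pred, n_sim)
        sd_rep = np.repeat(s_r, n_sim)
        resp = mu_rep + rng.standard_normal(n_rep.size) * sd_rep
        resp = np.clip(resp, line_bounds[0], line_bounds[1])
        internal_noise = float(np.std(resp / n_rep, ddof=1))
        fit = fit_power_mle(n_rep, resp)
        curve.append((internal_noise, fit.exponent))
    return curve
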