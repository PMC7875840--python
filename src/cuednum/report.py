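"""End-to-end analysis pipeline over a trial table.

Chains the stages — simulate (or load), clean, fit, model — and collects
the study's desk-scale summary surface: per-condition precision (sigma_n,
CV), accuracy (power exponents), the pooled SD-vs-numerosity power fit,
per-condition Bayesian central-tendency fits, reaction-time means, and the
correlation between number-line nonlinearity and internal noise across
subject-condition points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes, estimation, preprocessing, synthetic

__all__ = [
    "StudyReport",
    "fit_subjects",
    "correlate_nonlinearity_noise",
    "run_pipeline",
]


@dataclass
class StudyReport:
    """Aggregated results of one pipeline run."""

    per_condition: dict[str, dict[str, float]]
    sd_power_pooled: tuple[float, float]
    bayes: dict[str, dict[str, float]]
    nonlinearity_noise_correlation: dict[str, float | int | None]
    cleaning: preprocessing.CleaningReport
    subject_fits: pd.DataFrame = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "per_condition": self.per_condition,
            "sd_power_pooled": {
                "scale": self.sd_power_pooled[0],
                "exponent": self.sd_power_pooled[1],
            },
            "bayes": self.bayes,
            "nonlinearity_noise_correlation": self.nonlinearity_noise_correlation,
            "cleaning": {
                "n_input": self.cleaning.n_input,
                "n_training_dropped": self.cleaning.n_training_dropped,
                "n_outliers_dropped_per_condition": self.cleaning.n_outliers_dropped_per_condition,
                "n_rt_dropped": self.cleaning.n_rt_dropped,
                "n_output": self.cleaning.n_output,
            },
            "schema_version": 1,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)


def fit_subjects(trials: pd.DataFrame, n_restarts: int = 3) -> pd.DataFrame:
    """Per subject x condition fits of the power mapping plus noise measures.

    Returns one row per (subject, condition) with the fitted power exponent,
    scale, sigma_n, the internal noise (SD of R/N), CV, mean RT after the
    150-ms floor, and trial count.  Groups too small to fit are skipped with
    a warning.
    """
    rows = []
    for (subj, cond), grp in trials.groupby(["subject_id", "condition"], sort=True):
        n = grp["numerosity"].to_numpy(float)
        r = grp["response"].to_numpy(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = estimation.fit_power_mle(n, r, n_restarts=n_restarts)
        except (ValueError, estimation.FitError) as exc:
            warnings.warn(f"skipping {subj}/{cond}: {exc}", stacklevel=2)
            continue
        ratios = r / n
        rt_trials = preprocessing.filter_rt(grp)
        rows.append(
            {
                "subject_id": subj,
                "condition": cond,
                "exponent": fit.exponent,
                "scale": fit.scale,
                "sigma_n": fit.sigma_n,
                "log_likelihood": fit.log_likelihood,
                "converged": fit.converged,
                "internal_noise": float(np.std(ratios, ddof=1)),
                "mean_rt": float(rt_trials["rt"].mean()) if len(rt_trials) else float("nan"),
                "n_trials": len(grp),
            }
        )
    return pd.DataFrame(rows)


def correlate_nonlinearity_noise(subject_fits: pd.DataFrame) -> tuple[float | None, int]:
    """Pearson correlation between internal noise and nonlinearity.

    Nonlinearity is ``1 - exponent`` so that a positive r means noisier
    subject-condition points show more compressed number-line mappings.
    Returns ``(r, n_points)``; ``r`` is ``None`` (undefined) when fewer than
    3 points are available or either variable has zero variance.
    """
    pts = subject_fits.dropna(subset=["exponent", "internal_noise"])
    n = len(pts)
    if n < 3:
        return None, n
    x = pts["internal_noise"].to_numpy(float)
    y = 1.0 - pts["exponent"].to_numpy(float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return None, n
    r, _ = stats.pearsonr(x, y)
    return float(r), n


def run_pipeline(config: dict | None = None) -> StudyReport:
    """Run the whole analysis and return a :class:`StudyReport`.

    ``config`` keys (all optional):

    - ``trials_csv``: path to an existing trial table; otherwise a
      synthetic experiment is generated.
    - ``n_subjects`` (default 15), ``seed`` (default 0),
      ``subject_noise_spread``: simulation settings.
    - ``design``: keyword overrides for :class:`synthetic.SessionDesign`.
    - ``prior_mean`` / ``prior_mean_mode``: Bayesian-fit settings.
    - ``fit_restarts``: optimizer restarts per subject-condition fit.

    Deterministic given the same config (including seed).
    """
    config = dict(config or {})
    design = synthetic.SessionDesign(**config.get("design", {}))
    seed = int(config.get("seed", 0))

    if "trials_csv" in config:
        trials = pd.read_csv(config["trials_csv"])
    else:
        trials = synthetic.generate_experiment(
            n_subjects=int(config.get("n_subjects", 15)),
            design=design,
            seed=seed,
            subject_noise_spread=float(config.get("subject_noise_spread", 0.25)),
        )

    cleaned, cleaning = preprocessing.clean(trials, n_training=design.n_training)
    rt_branch = preprocessing.filter_rt(cleaned)
    cleaning.n_rt_dropped = len(cleaned) - len(rt_branch)

    subject_fits = fit_subjects(cleaned, n_restarts=int(config.get("fit_restarts", 3)))
    noise = estimation.compute_noise_summary(cleaned)

    # pooled SD-vs-N power fit (all conditions together, per the more
    # robust collapsed analysis)
    pooled_sd = {
        float(n_val): float(np.std(sub["response"].to_numpy(float), ddof=1))
        for n_val, sub in cleaned.groupby("numerosity")
        if len(sub) >= 2
    }
    sd_power_pooled = estimation.fit_sd_power(pooled_sd)

    per_condition: dict[str, dict[str, float]] = {}
    bayes_fits: dict[str, dict[str, float]] = {}
    prior_mean = float(config.get("prior_mean", 15.0))
    prior_mode = str(config.get("prior_mean_mode", "fixed_value"))
    for cond in synthetic.CONDITIONS:
        cond_fits = subject_fits[subject_fits["condition"] == cond]
        cond_trials = cleaned[cleaned["condition"] == cond]
        if cond_fits.empty or cond not in noise:
            per_condition[cond] = {"present": 0.0}
            continue
        per_condition[cond] = {
            "present": 1.0,
            "sigma_n": float(cond_fits["sigma_n"].mean()),
            "power_exponent": float(cond_fits["exponent"].mean()),
            "cv": noise[cond].cv,
            "internal_noise": noise[cond].internal_noise,
            "mean_rt": float(cond_fits["mean_rt"].mean()),
            "n_trials": int(cond_trials.shape[0]),
        }
        # Bayesian central-tendency fit to the condition's mean responses,
        # with the sensory-noise constant set by the condition CV and
        # square-root scaling
        mean_by_n = {
            float(n_val): float(sub["response"].mean())
            for n_val, sub in cond_trials.groupby("numerosity")
        }
        if len(mean_by_n) >= 4:
            try:
                obs, r2 = bayes.fit_prior(
                    mean_by_n,
                    sigma_r_spec=(max(noise[cond].cv, 1e-6) * np.sqrt(design.n_max), 0.5),
                    prior_mean_mode=prior_mode,
                    prior_mean_value=prior_mean,
                )
            except ValueError as exc:
                warnings.warn(f"Bayesian fit skipped for {cond}: {exc}", stacklevel=2)
            else:
                bayes_fits[cond] = {
                    "prior_mean": obs.prior_mean,
                    "prior_sd": obs.prior_sd,
                    "noise_k": obs.noise_k,
                    "noise_exponent": obs.noise_exponent,
                    "r_squared": r2,
                }

    r, n_pts = correlate_nonlinearity_noise(subject_fits)
    return StudyReport(
        per_condition=per_condition,
        sd_power_pooled=sd_power_pooled,
        bayes=bayes_fits,
        nonlinearity_noise_correlation={"r": r, "n": n_pts},
        cleaning=cleaning,
        subject_fits=subject_fits,
    )
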