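"""Synthetic cued-enumeration experiment generator.

Emulates a cue-validity number-line estimation study: on each trial a dot
array of numerosity N (uniform on 5..30) appears at a cued or uncued
location — valid same location (VSL, 75% of trials), invalid same object
(IS, 12.5%) or invalid different object (ID, 12.5%) — and the simulated
observer reports a position on a 1-35 number line.  Responses come from a
central-tendency Bayesian observer (posterior mean plus readout jitter,
clamped to the line); attentional condition modulates the observer's sensory
noise constant (VSL < IS < ID), which the prior converts into stronger
compression for noisier conditions.  Reaction times are drawn from a shifted
log-normal with condition-dependent means echoing the cue-validity ordering
(valid fastest).

Dot-array geometry generation (positions and diameters satisfying
non-overlap, minimum-gap and size/area-equating constraints) is included so
stimulus-level properties can be tested without rendering anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import BayesObserver

__all__ = [
    "CONDITIONS",
    "TRIAL_COLUMNS",
    "SessionDesign",
    "RTParams",
    "TrialRecord",
    "StimulusSpec",
    "PackingError",
    "default_observers",
    "default_rt_models",
    "generate_rt",
    "generate_session",
    "generate_experiment",
    "generate_dot_array",
]

CONDITIONS = ("VSL", "IS", "ID")

TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "trial_index",
    "condition",
    "numerosity",
    "response",
    "rt",
    "area_control",
    "is_training",
]


@dataclass(frozen=True)
class SessionDesign:
    """Generative description of the experiment.

    Defaults mirror the study design: four sessions of 150 trials, a
    75/12.5/12.5 condition split, numerosities 5-30 on a 1-35 number line,
    and 20 leading training trials per session.
    """

    n_sessions: int = 4
    trials_per_session: int = 150
    p_vsl: float = 0.75
    p_is: float = 0.125
    p_id: float = 0.125
    n_min: int = 5
    n_max: int = 30
    line_min: float = 1.0
    line_max: float = 35.0
    n_training: int = 20

    def __post_init__(self) -> None:
        if self.n_sessions <= 0 or self.trials_per_session <= 0:
            raise ValueError("session and trial counts must be positive")
        probs = (self.p_vsl, self.p_is, self.p_id)
        if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError(
                f"condition probabilities must be non-negative and sum to 1, got {probs}"
            )
        if self.n_min < 1 or self.n_max <= self.n_min:
            raise ValueError("need 1 <= n_min < n_max")
        if self.line_min > self.n_min or self.line_max < self.n_max:
            raise ValueError("number line must cover the numerosity range")
        if self.n_training < 0:
            raise ValueError("n_training must be >= 0")

    @property
    def condition_probs(self) -> tuple[float, float, float]:
        return (self.p_vsl, self.p_is, self.p_id)


@dataclass(frozen=True)
class RTParams:
    """Shifted log-normal reaction-time model for one condition.

    ``location`` is the distribution mean in seconds; ``scale`` the SD of
    the underlying log-normal on the log scale (``scale == 0`` collapses to
    a point mass at ``location``); ``shift`` the strictly positive floor.
    """

    location: float
    scale: float = 0.35
    shift: float = 0.3

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError(f"scale must be >= 0, got {self.scale}")
        if self.shift < 0:
            raise ValueError(f"shift must be >= 0, got {self.shift}")
        if self.location <= self.shift:
            raise ValueError("location (mean RT) must exceed shift")


@dataclass(frozen=True)
class TrialRecord:
    """One cued-enumeration trial."""

    subject_id: str
    session: int
    trial_index: int
    condition: str
    numerosity: int
    response: float
    rt: float
    area_control: bool
    is_training: bool


def default_observers() -> dict[str, BayesObserver]:
    """Per-condition central-tendency observers.

    Sensory noise follows square-root scaling (exponent 0.5) with the prior
    at (15, 5); the noise constant increases as attention is withdrawn
    (VSL < IS < ID), so invalid-different-object trials are both noisier
    and more compressed.  Readout jitter matches the sensory noise constant
    so that simulated response SDs inherit the same scaling.
    """
    spec = {"VSL": 0.5, "IS": 0.6, "ID": 1.0}
    return {
        cond: BayesObserver(
            prior_mean=15.0,
            prior_sd=5.0,
            noise_k=k,
            noise_exponent=0.5,
            response_jitter_sd=k,
        )
        for cond, k in spec.items()
    }


def default_rt_models() -> dict[str, RTParams]:
    """Condition RT means 1.07 s (VSL) < 1.13 s (IS) < 1.27 s (ID)."""
    return {
        "VSL": RTParams(location=1.07),
        "IS": RTParams(location=1.13),
        "ID": RTParams(location=1.27),
    }


def generate_rt(condition: str, rt_model: dict[str, RTParams], rng: np.random.Generator) -> float:
    """Draw one reaction time (seconds) for a condition.

    Shifted log-normal parameterised by its mean: always > 0, and exactly
    ``location`` when ``scale == 0``.
    """
    params = rt_model[condition]
    if params.scale == 0.0:
        return params.location
    mu = math.log(params.location - params.shift) - params.scale**2 / 2.0
    return params.shift + float(np.exp(mu + params.scale * rng.standard_normal()))


def generate_session(
    design: SessionDesign,
    observers: dict[str, BayesObserver] | None = None,
    rt_model: dict[str, RTParams] | None = None,
    seed: int = 0,
    subject_id: str = "S01",
    session: int = 1,
) -> pd.DataFrame:
    """Simulate one session of trials.

    Conditions are drawn i.i.d. per trial with the design's probabilities
    (75% of 150 is not an integer, so exact within-session counts are not
    enforced).  Numerosity is uniform on the design's range; the response
    is the condition observer's posterior mean plus Gaussian readout jitter,
    clamped to the number line; the first ``n_training`` trials are flagged
    as training.  Identical arguments (including seed) give identical
    output.
    """
    observers = default_observers() if observers is None else observers
    rt_model = default_rt_models() if rt_model is None else rt_model
    rng = np.random.default_rng(seed)

    n_trials = design.trials_per_session
    conds = rng.choice(CONDITIONS, size=n_trials, p=design.condition_probs)
    numerosities = rng.integers(design.n_min, design.n_max + 1, size=n_trials)

    rows = []
    for i in range(n_trials):
        cond = str(conds[i])
        n_val = int(numerosities[i])
        obs = observers[cond]
        mean = obs.predicted_response(n_val)
        jitter_sd = float(obs.jitter_sd(n_val))
        resp = mean + (jitter_sd * rng.standard_normal() if jitter_sd > 0 else 0.0)
        resp = float(np.clip(resp, design.line_min, design.line_max))
        rows.append(
            (
                subject_id,
                session,
                i + 1,
                cond,
                n_val,
                resp,
                generate_rt(cond, rt_model, rng),
                bool(rng.random() < 0.5),
                i < design.n_training,
            )
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_experiment(
    n_subjects: int = 15,
    design: SessionDesign | None = None,
    observers: dict[str, BayesObserver] | None = None,
    rt_model: dict[str, RTParams] | None = None,
    seed: int = 0,
    subject_noise_spread: float = 0.25,
) -> pd.DataFrame:
    """Simulate a full multi-subject experiment.

    Each subject receives their own noise constants: the per-condition
    defaults scaled by a subject-specific log-normal factor
    (``exp(Normal(0, subject_noise_spread))``), preserving the
    VSL < IS < ID ordering within subject while creating the
    between-subject noise heterogeneity that the nonlinearity-vs-noise
    analyses rely on.
    """
    design = SessionDesign() if design is None else design
    base = default_observers() if observers is None else observers
    rng = np.random.default_rng(seed)

    frames = []
    for s in range(n_subjects):
        factor = float(np.exp(subject_noise_spread * rng.standard_normal()))
        subj_obs = {
            cond: BayesObserver(
                prior_mean=o.prior_mean,
                prior_sd=o.prior_sd,
                noise_k=o.noise_k * factor,
                noise_exponent=o.noise_exponent,
                response_jitter_sd=o.response_jitter_sd * factor,
            )
            for cond, o in base.items()
        }
        for sess in range(1, design.n_sessions + 1):
            frames.append(
                generate_session(
                    design,
                    subj_obs,
                    rt_model,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    subject_id=f"S{s + 1:02d}",
                    session=sess,
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# dot-array geometry


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place all dots."""


@dataclass
class StimulusSpec:
    """Dot-array geometry in degrees of visual angle.

    Positions are centred on a circular field; all dots lie fully inside
    the field with pairwise edge-to-edge gaps of at least ``min_gap``.
    """

    positions: np.ndarray
    diameters: np.ndarray
    field_radius: float
    mode: str
    min_gap: float = 0.15

    def pairwise_gaps(self) -> np.ndarray:
        """Edge-to-edge gaps for every dot pair (empty for a single dot)."""
        pos = np.asarray(self.positions, dtype=float)
        radii = np.asarray(self.diameters, dtype=float) / 2.0
        n = len(radii)
        gaps = []
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.hypot(*(pos[i] - pos[j])))
                gaps.append(d - radii[i] - radii[j])
        return np.asarray(gaps)

    def total_area(self) -> float:
        return float(np.sum(np.pi * (np.asarray(self.diameters) / 2.0) ** 2))


DEFAULT_DOT_DIAMETER = 0.25  # degrees
DIAMETER_VARIABILITY = 0.31  # +/- fraction around the base diameter
DEFAULT_FIELD_RADIUS = 2.0  # 4-degree circular stimulus region
MIN_DOT_GAP = 0.15  # degrees, edge to edge
# cumulative-area target in area-equated mode: the area of a mid-range
# (15-dot) array at the default diameter, constant across numerosities
DEFAULT_TARGET_AREA = 15 * math.pi * (DEFAULT_DOT_DIAMETER / 2.0) ** 2


def generate_dot_array(
    n_dots: int,
    mode: str = "size_equated",
    field_radius: float = DEFAULT_FIELD_RADIUS,
    seed: int = 0,
    target_area: float | None = None,
    max_attempts: int = 10_000,
) -> StimulusSpec:
    """Place ``n_dots`` non-overlapping dots in a circular field.

    ``size_equated`` draws each diameter uniformly within +/-31% of the
    0.25-degree default.  ``area_equated`` draws the same relative
    variability around the diameter implied by splitting ``target_area``
    equally among the dots, then rescales jointly so the cumulative area
    matches the target; arrays of different numerosity generated with the
    same target therefore have equal total dot area.

    Placement is rejection sampling with an attempt cap; deterministic for
    a given seed.  Raises :class:`PackingError` if the dots cannot be
    placed, and ``ValueError`` for invalid inputs.
    """
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    if mode not in ("size_equated", "area_equated"):
        raise ValueError(f"unknown mode: {mode!r}")
    rng = np.random.default_rng(seed)

    if mode == "size_equated":
        base = DEFAULT_DOT_DIAMETER
    else:
        target = DEFAULT_TARGET_AREA if target_area is None else float(target_area)
        if target <= 0:
            raise ValueError("target_area must be positive")
        base = 2.0 * math.sqrt(target / (n_dots * math.pi))

    lo, hi = base * (1 - DIAMETER_VARIABILITY), base * (1 + DIAMETER_VARIABILITY)
    diameters = rng.uniform(lo, hi, size=n_dots)
    if mode == "area_equated":
        # joint rescale to hit the cumulative target exactly; preserves the
        # relative (between-dot) variability
        current = np.sum(np.pi * (diameters / 2.0) ** 2)
        diameters = diameters * math.sqrt(target / current)

    positions = np.empty((n_dots, 2))
    placed = 0
    attempts = 0
    radii = diameters / 2.0
    while placed < n_dots:
        if attempts >= max_attempts:
            raise PackingError(
                f"packing failed: placed {placed}/{n_dots} dots after "
                f"{max_attempts} attempts (field radius {field_radius})"
            )
        attempts += 1
        # uniform point in the disc shrunk by the dot radius
        r_max = field_radius - radii[placed]
        if r_max <= 0:
            raise PackingError(
                f"dot diameter {diameters[placed]:.3f} does not fit in field "
                f"of radius {field_radius}"
            )
        rad = r_max * math.sqrt(rng.random())
        ang = 2.0 * math.pi * rng.random()
        cand = np.array([rad * math.cos(ang), rad * math.sin(ang)])
        ok = True
        for j in range(placed):
            gap = float(np.hypot(*(cand - positions[j]))) - radii[placed] - radii[j]
            if gap < MIN_DOT_GAP:
                ok = False
                break
        if ok:
            positions[placed] = cand
            placed += 1
    return StimulusSpec(
        positions=positions,
        diameters=diameters,
        field_radius=field_radius,
        mode=mode,
        min_gap=MIN_DOT_GAP,
    )
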