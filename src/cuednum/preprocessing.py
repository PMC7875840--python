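"""Trial-table cleaning rules applied before any model fitting.

Three rules, in the order the analysis applies them:

1. the first ``n_training`` trials of each session are treated as training
   and dropped;
2. within each condition (per subject), responses more than ``k_sd``
   standard deviations from the condition mean are removed — a single pass,
   with the mean and SD computed once on the pre-removal group, and
   boundary cases at exactly ``k_sd`` SDs kept;
3. for the reaction-time analyses only, trials faster than 150 ms are
   excluded (exactly 150 ms is kept).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = ["CleaningReport", "drop_training", "remove_outliers", "filter_rt", "clean"]


@dataclass
class CleaningReport:
    """Bookkeeping for one cleaning pass over a trial table."""

    n_input: int = 0
    n_training_dropped: int = 0
    n_outliers_dropped_per_condition: dict[str, dict[str, float]] = dc_field(
        default_factory=dict
    )
    n_rt_dropped: int = 0
    n_output: int = 0
    warnings: list[str] = dc_field(default_factory=list)

    @property
    def n_outliers_dropped(self) -> int:
        return sum(int(v["count"]) for v in self.n_outliers_dropped_per_condition.values())

    def validate(self) -> None:
        drops = self.n_training_dropped + self.n_outliers_dropped + self.n_rt_dropped
        if self.n_output != self.n_input - drops:
            raise ValueError("cleaning report counts are inconsistent")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_training_dropped": self.n_training_dropped,
                    "n_outliers_dropped_per_condition": self.n_outliers_dropped_per_condition,
                    "n_rt_dropped": self.n_rt_dropped,
                    "n_output": self.n_output,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def drop_training(trials: pd.DataFrame, n_training: int = 20) -> pd.DataFrame:
    """Remove the first ``n_training`` trials of each (subject, session).

    Order within a session is preserved.  Sessions shorter than
    ``n_training`` lose all their trials, with a warning.
    """
    if n_training == 0:
        return trials.copy()
    keep_parts = []
    for (subj, sess), grp in trials.groupby(["subject_id", "session"], sort=False):
        if len(grp) <= n_training:
            warnings.warn(
                f"session {sess} of subject {subj} has only {len(grp)} trials; "
                f"all dropped as training (n_training={n_training})",
                stacklevel=2,
            )
            continue
        keep_parts.append(grp.iloc[n_training:])
    if not keep_parts:
        return trials.iloc[0:0].copy()
    return pd.concat(keep_parts).sort_index()


def remove_outliers(
    trials: pd.DataFrame,
    k_sd: float = 2.0,
    per_subject: bool = True,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove responses more than ``k_sd`` SDs from their condition mean.

    The mean and sample (n-1) SD are computed once per group before any
    removal (single pass, not iterated); responses exactly at the boundary
    are kept.  Groups with fewer than two trials pass through untouched.
    Grouping is per condition within subject by default; set
    ``per_subject=False`` to pool subjects.
    """
    report = CleaningReport(n_input=len(trials))
    if trials.empty:
        report.n_output = 0
        return trials.copy(), report

    group_cols = ["subject_id", "condition"] if per_subject else ["condition"]
    keep_mask = pd.Series(True, index=trials.index)
    cond_counts: dict[str, int] = {}
    cond_totals: dict[str, int] = {}
    for key, grp in trials.groupby(group_cols, sort=False):
        cond = key[-1] if isinstance(key, tuple) else key
        cond_totals[cond] = cond_totals.get(cond, 0) + len(grp)
        if len(grp) < 2:
            msg = f"group {key} has < 2 trials; outlier rule skipped"
            warnings.warn(msg, stacklevel=2)
            report.warnings.append(msg)
            continue
        resp = grp["response"].to_numpy(float)
        mean, sd = resp.mean(), resp.std(ddof=1)
        out = np.abs(resp - mean) > k_sd * sd
        keep_mask.loc[grp.index[out]] = False
        cond_counts[cond] = cond_counts.get(cond, 0) + int(out.sum())
    for cond, total in cond_totals.items():
        count = cond_counts.get(cond, 0)
        report.n_outliers_dropped_per_condition[str(cond)] = {
            "count": count,
            "fraction": count / total if total else 0.0,
        }
    cleaned = trials[keep_mask].copy()
    report.n_output = len(cleaned)
    return cleaned, report


def filter_rt(trials: pd.DataFrame, min_rt: float = 0.150) -> pd.DataFrame:
    """Drop trials faster than ``min_rt`` seconds (exactly ``min_rt`` kept).

    Applied only on the reaction-time analysis branch, not before response
    fitting.
    """
    if min_rt < 0:
        raise ValueError("min_rt must be >= 0")
    kept = trials[trials["rt"] >= min_rt].copy()
    if len(trials) and kept.empty:
        warnings.warn("all trials removed by the RT floor (100% removal)", stacklevel=2)
    return kept


def clean(
    trials: pd.DataFrame,
    n_training: int = 20,
    k_sd: float = 2.0,
    per_subject: bool = True,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Training-trial exclusion followed by the single-pass outlier rule.

    RT filtering is not applied here; use :func:`filter_rt` on the RT
    analysis branch.
    """
    n_input = len(trials)
    after_training = drop_training(trials, n_training)
    cleaned, report = remove_outliers(after_training, k_sd=k_sd, per_subject=per_subject)
    report.n_input = n_input
    report.n_training_dropped = n_input - len(after_training)
    report.validate()
    return cleaned, report
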