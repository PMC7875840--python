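"""Apply the exclusion rules to the simulated trial table.

Drops the first 20 trials of each session (training) and, per subject and
condition, responses more than 2 SDs from the condition mean (single
pass).  Writes results/trials_clean.csv and the cleaning report.
"""

from pathlib import Path

import pandas as pd

from cuednum import clean

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = pd.read_csv(RESULTS / "trials.csv")
    cleaned, report = clean(trials)
    cleaned.to_csv(RESULTS / "trials_clean.csv", index=False)
    report.to_json(RESULTS / "cleaning_report.json")
    print(f"{report.n_input} trials in, {report.n_output} out")
    print(f"training dropped: {report.n_training_dropped}")
    for cond, stats in sorted(report.n_outliers_dropped_per_condition.items()):
        print(f"outliers {cond}: {stats['count']} ({100 * stats['fraction']:.2f}%)")


if __name__ == "__main__":
    main()
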