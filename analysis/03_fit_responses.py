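"""Fit the cleaned responses: per-subject power MLE and SD-vs-N scaling.

For every subject x condition, fits the power mapping R = scale * N**beta
with scalar variability by maximum likelihood; summarises the mean
exponent, sigma_n, CV and RT per condition; and fits the pooled
SD-vs-numerosity power function.  Writes results/subject_fits.csv and
results/condition_summary.csv.
"""

from pathlib import Path

import pandas as pd

from cuednum import compute_noise_summary, fit_sd_power, fit_subjects

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cleaned = pd.read_csv(RESULTS / "trials_clean.csv")
    fits = fit_subjects(cleaned)
    fits.to_csv(RESULTS / "subject_fits.csv", index=False)

    noise = compute_noise_summary(cleaned)
    summary = fits.groupby("condition")[
        ["exponent", "sigma_n", "internal_noise", "mean_rt", "n_trials"]
    ].mean()
    summary["cv"] = [noise[c].cv for c in summary.index]
    summary = summary.loc[["VSL", "IS", "ID"]]
    summary.to_csv(RESULTS / "condition_summary.csv")

    pooled_sd = {
        float(n): float(g["response"].std(ddof=1))
        for n, g in cleaned.groupby("numerosity")
        if len(g) >= 2
    }
    scale, exponent = fit_sd_power(pooled_sd)

    print("per-condition means (VSL should be most linear, ID most compressed):")
    print(summary.round(3).to_string())
    print(f"pooled SD-vs-N power fit: SD(N) = {scale:.3f} * N^{exponent:.3f}")
    print("(square-root scaling of precision corresponds to exponent 0.5)")


if __name__ == "__main__":
    main()
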