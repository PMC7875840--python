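"""Plot the analysis surface: mapping curves, SD scaling, noise scatter.

Writes three PNGs under results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from cuednum import BayesObserver, predict_mapping

RESULTS = Path(__file__).resolve().parents[1] / "results"
COLORS = {"VSL": "tab:green", "IS": "tab:blue", "ID": "tab:red"}


def main() -> None:
    figdir = RESULTS / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    cleaned = pd.read_csv(RESULTS / "trials_clean.csv")
    import json

    bayes_fits = json.loads((RESULTS / "bayes_fits.json").read_text())

    # mean responses with Bayesian mapping curves
    fig, ax = plt.subplots(figsize=(5, 4))
    n_grid = np.arange(5, 31)
    for cond, grp in cleaned.groupby("condition"):
        means = grp.groupby("numerosity")["response"].mean()
        ax.plot(means.index, means.values, "o", ms=3, color=COLORS[cond], label=cond)
        bf = bayes_fits[cond]
        obs = BayesObserver(prior_mean=bf["prior_mean"], prior_sd=bf["prior_sd"],
                            noise_k=bf["noise_k"], noise_exponent=0.5,
                            response_jitter_sd=0.0)
        ax.plot(n_grid, predict_mapping(obs, n_grid).predicted_response,
                "--", color=COLORS[cond])
    ax.plot([5, 30], [5, 30], "k:", lw=0.8)
    ax.set_xlabel("numerosity N")
    ax.set_ylabel("mean number-line response")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "mapping_curves.png", dpi=150)

    # SD vs numerosity, log-log
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, grp in cleaned.groupby("condition"):
        sds = grp.groupby("numerosity")["response"].std()
        ax.loglog(sds.index, sds.values, "o-", ms=3, lw=0.8, color=COLORS[cond], label=cond)
    ax.set_xlabel("numerosity N")
    ax.set_ylabel("response SD")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "sd_scaling.png", dpi=150)

    # nonlinearity vs internal noise with model curve
    fits = pd.read_csv(RESULTS / "subject_fits.csv")
    curve = pd.read_csv(RESULTS / "nonlinearity_curve.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, grp in fits.groupby("condition"):
        ax.plot(grp["internal_noise"], grp["exponent"], "s", ms=4,
                color=COLORS[cond], label=cond)
    ax.plot(curve["internal_noise"], curve["exponent"], "-", color="gray",
            label="model (prior SD 17)")
    ax.set_xlabel("internal noise  SD(R/N)")
    ax.set_ylabel("power exponent")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "nonlinearity_vs_noise.png", dpi=150)
    print(f"wrote figures to {figdir}")


if __name__ == "__main__":
    main()
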