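#!/usr/bin/env python
"""Parameter-recovery calibration of the introgression estimator.

Simulates sinks at the study design (135 loci; 60 historical, 500
contemporary, 200 source fish; n = 6 generations) across the range of
estimated rates, refits each, and tabulates posterior-mean error and
95% credible-interval coverage.
"""

from pathlib import Path

import pandas as pd

from straysink.experiments import recovery_replicates

SEED = 0
N_REPLICATES = 12
RATES = (0.0, 0.011, 0.06, 0.26)
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    frames = [recovery_replicates(m, N_REPLICATES, seed=SEED) for m in RATES]
    df = pd.concat(frames, ignore_index=True)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "recovery_calibration.tsv", sep="\t", index=False)

    summary = (
        df.assign(abs_error=(df.posterior_mean - df.m_true).abs())
        .groupby("m_true")
        .agg(
            mean_estimate=("posterior_mean", "mean"),
            max_abs_error=("abs_error", "max"),
            coverage=("covered", "mean"),
            worst_rhat=("rhat", "max"),
        )
        .round(4)
    )
    print(summary.to_string())
    print(
        "\nnote: at m=0 the truth sits on the parameter boundary, where an"
        " equal-tailed interval over [0,1] cannot cover it; recovery there"
        " is judged by the posterior mean."
    )


if __name__ == "__main__":
    main()
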