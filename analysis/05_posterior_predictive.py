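#!/usr/bin/env python
"""Posterior predictive check: re-simulate each subject from their fitted
winning-model parameters and compare behavioral summaries.

Reads results/cohort/ and results/fits/estimates.csv; writes
results/ppc/simulated_summaries.csv and prints the group-by-cue pattern in
the real (simulated-cohort) and posterior-predictive data side by side.
"""

from pathlib import Path

import pandas as pd

import socialhgf as sh
from socialhgf.inversion import to_native
from socialhgf.validation import posterior_predictive

SEED = 20260924
N_REP = 10
COHORT = Path("results/cohort")
OUT = Path("results/ppc")


class _Refit:
    def __init__(self, params_native):
        self.spec = sh.ModelSpec("hgf", 1)
        self.params_native = params_native


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(COHORT / "subjects.csv")
    est = pd.read_csv(Path("results/fits") / "estimates.csv")
    fits, experiments, schedules = [], [], []
    for _, row in est.iterrows():
        i = int(row["subject"])
        experiment, _ = sh.read_trial_table(
            COHORT / "trial_tables" / f"subject_{i:03d}.csv"
        )
        variant = meta.loc[meta.subject == i, "schedule"].item()
        schedules.append(sh.build_schedule(variant=variant))
        experiments.append(experiment)
        params_est = {
            c[:-4]: row[c] for c in est.columns if c.endswith("_est")
        }
        fits.append(_Refit(to_native(params_est)))
    ppc = posterior_predictive(fits, experiments, schedules, n_rep=N_REP, seed=SEED)
    ppc.simulations.to_csv(OUT / "simulated_summaries.csv", index=False)
    print(f"{len(fits)} subjects x {N_REP} replicates = "
          f"{ppc.n_simulations} simulated datasets")

    real = pd.read_csv(COHORT / "behavior_summary.csv")
    sim = ppc.per_subject.merge(real[["subject", "group"]], on="subject")
    for label, df in (("observed cohort", real), ("posterior predictive", sim)):
        pref = (
            (df["hp_gaze_stable"] + df["hp_gaze_volatile"]) / 2
            - (df["hp_card_stable"] + df["hp_card_volatile"]) / 2
        )
        print(f"\n{label}: mean gaze-minus-card accuracy by group")
        print(pref.groupby(df["group"]).mean().round(3))


if __name__ == "__main__":
    main()
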