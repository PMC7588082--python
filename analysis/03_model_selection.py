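#!/usr/bin/env python
"""Random-effects Bayesian model selection over the cohort's LME table.

Reads results/fits/lme.csv and writes results/bms.csv with expected posterior
probabilities (EXP_R), exceedance probabilities (XP), protected exceedance
probabilities (PXP) and the Bayes omnibus risk, plus the within-subject
best-model counts.
"""

from pathlib import Path

import pandas as pd

from socialhgf.response import MODEL_SPACE
from socialhgf.selection import rfx_bms, within_subject_best

SEED = 20260922
OUT = Path("results")


def main():
    lme_df = pd.read_csv(OUT / "fits" / "lme.csv")
    labels = [m.label for m in MODEL_SPACE]
    lme = lme_df[labels].to_numpy()
    res = rfx_bms(lme, mc_samples=1_000_000, seed=SEED, model_labels=labels)
    table = pd.DataFrame(
        {"model": labels, "exp_r": res.exp_r, "xp": res.xp, "pxp": res.pxp}
    ).round(4)
    table["bor"] = round(res.bor, 4)
    table.to_csv(OUT / "bms.csv", index=False)
    best = within_subject_best(lme)
    counts = pd.Series(best.counts, index=labels, name="n_subjects_best")
    counts.to_csv(OUT / "within_subject_best.csv")
    print(table.to_string(index=False))
    print(f"\nBayes omnibus risk: {res.bor:.4f}")
    print("\nwithin-subject best-model counts:")
    print(counts[counts > 0].to_string())


if __name__ == "__main__":
    main()
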