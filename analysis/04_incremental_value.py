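#!/usr/bin/env python
"""Incremental prognostic value of the miRNA over the nested clinical models.

Fits the crude association and models 1-3 (clinical factor sets of increasing
depth, model 3 adding log NT-proBNP), then asks whether the miRNA still helps
once each model is in place: Harrell's c-index with and without the marker,
the bootstrap delta c-index, and cNRI/IDI at the 2-year horizon.  Writes
results/incremental_value.json.
"""

import json
from pathlib import Path

import numpy as np

from mirisk import (
    MODEL_COVARIATES,
    cnri_idi,
    delta_cindex,
    fit_cox,
    harrell_cindex,
    mirna_association,
)
from mirisk.io import CohortSchema, read_cohort

SEED = 20234
OUT = Path(__file__).resolve().parent.parent / "results"
MIR = "log_mir133a"


def main() -> None:
    cohort, _ = read_cohort(OUT / "cohort_analysis.csv", CohortSchema())
    df = cohort.data
    out: dict = {}

    crude = mirna_association(df, MIR)
    j = crude.covariates.index(MIR)
    ci = crude.confidence_intervals()[j]
    out["crude"] = {"HR": crude.hazard_ratios[j], "ci": list(ci),
                    "p": crude.p_values[j]}
    print(f"crude HR per log-unit miRNA: {crude.hazard_ratios[j]:.3f} "
          f"({ci[0]:.3f}-{ci[1]:.3f})")

    for mid in (1, 2, 3):
        covs = MODEL_COVARIATES[mid]
        fit = mirna_association(df, MIR, model=mid)
        j = fit.covariates.index(MIR)
        ci = fit.confidence_intervals()[j]

        sub = df[["time", "event"] + covs + [MIR]].dropna()
        t, e = sub["time"].to_numpy(), sub["event"].to_numpy()
        base_fit = fit_cox(sub, covs)
        base_scores = base_fit.linear_predictor(sub[covs].to_numpy(float))
        aug_scores = fit.linear_predictor(sub[covs + [MIR]].to_numpy(float))
        dc = delta_cindex(base_scores, aug_scores, t, e, n_boot=300, seed=SEED + mid)
        rec = cnri_idi(sub, covs, covs + [MIR], horizon=2.0,
                       n_resample=300, seed=SEED + mid)
        out[f"model_{mid}"] = {
            "HR": fit.hazard_ratios[j], "ci": list(ci), "p": fit.p_values[j],
            "c_base": dc.c_base, "c_augmented": dc.c_augmented,
            "delta_c": dc.delta, "delta_c_ci": [dc.ci_low, dc.ci_high],
            "cNRI": rec.cnri, "cNRI_ci": list(rec.cnri_ci), "cNRI_p": rec.cnri_p,
            "IDI": rec.idi, "IDI_ci": list(rec.idi_ci), "IDI_p": rec.idi_p,
        }
        print(f"model {mid}: HR {fit.hazard_ratios[j]:.3f} "
              f"({ci[0]:.3f}-{ci[1]:.3f}), c {dc.c_base:.3f} -> "
              f"{dc.c_augmented:.3f}, cNRI {rec.cnri:+.3f} "
              f"[{rec.cnri_ci[0]:+.3f}, {rec.cnri_ci[1]:+.3f}], "
              f"IDI {rec.idi:+.4f}")

    def _clean(o):
        if isinstance(o, dict):
            return {k: _clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    (OUT / "incremental_value.json").write_text(
        json.dumps(_clean(out), indent=2, sort_keys=True)
    )
    print(f"wrote incremental_value.json -> {OUT}")


if __name__ == "__main__":
    main()
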