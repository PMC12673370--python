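"""Citrate synthase activities and ddCt expression of the cohort.

Writes results/cs_activity.csv and results/qpcr_folds.csv; prints the CS
activity summary, the reference-gene stability check, and the per-group fold
changes of the mitochondrial-dynamics panel.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import study  # noqa: E402

import mitoflux as mf  # noqa: E402


def main():
    rows = []
    for group in study.GROUPS:
        for i in range(study.N_PER_GROUP):
            rec = mf.CsAssayRecord.from_csv(study.DATA / "cs" / f"{group}_{i}.csv")
            out = mf.analyze_cs_assay(rec)
            rows.append({"group": group, "animal": i, **out})
    cs = pd.DataFrame(rows)
    study.RESULTS.mkdir(exist_ok=True)
    cs.to_csv(study.RESULTS / "cs_activity.csv", index=False)
    print("CS activity (IU/mg wet mass), mean +/- SD per group:")
    print(cs.groupby("group")["v_iu_per_mg"].agg(["mean", "std"]).round(4).to_string())

    ct = pd.read_csv(study.DATA / "qpcr" / "ct.csv")
    stability = mf.reference_stability(ct)
    print("\nreference gene (Actb) Ct per group:")
    print(stability.round(2).to_string(index=False))

    per_sample, per_group = mf.delta_delta_ct(ct, control_group="Ctrl")
    per_sample.to_csv(study.RESULTS / "qpcr_folds.csv", index=False)
    per_group.to_csv(study.RESULTS / "qpcr_group_folds.csv", index=False)
    print("\nfold change vs Ctrl (mean +/- SD):")
    print(per_group.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
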