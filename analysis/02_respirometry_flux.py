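"""Per-state O2 fluxes of the cohort at both O2 regimes.

Reads the simulated traces and CS assays, runs the full flux pipeline
(state windows, Rox correction, mass- and CS-specific normalization, control
ratios) per animal, and writes results/flux_{air,normoxic}.csv. Prints the
group medians of the Rox-corrected mass-specific flux per state.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import study  # noqa: E402

import mitoflux as mf  # noqa: E402


def cs_units_for(group, i):
    rec = mf.CsAssayRecord.from_csv(study.DATA / "cs" / f"{group}_{i}.csv")
    fit = mf.fit_absorbance_slope(rec)
    v = mf.cs_activity(max(fit.r_a_per_min, 0.0), rec)
    return mf.chamber_cs_units(v, study.SAMPLE_MASS_MG)


def main():
    for regime in ("air", "normoxic"):
        suffix = "_o2" if regime == "normoxic" else ""
        rows = []
        for group in study.GROUPS:
            for i in range(study.N_PER_GROUP):
                trace = mf.RespirometryTrace.from_csv(
                    study.DATA / regime / f"{group}_{i}{suffix}.csv",
                    study.DATA / regime / f"{group}_{i}{suffix}_events.yaml",
                    chamber_volume_ml=study.CHAMBER_VOLUME_ML,
                    sample_mass_mg=study.SAMPLE_MASS_MG,
                )
                res = mf.analyze_trace(trace, cs_units_iu=cs_units_for(group, i))
                for state in res.corrected.states:
                    rows.append({
                        "group": group, "animal": i, "state": state,
                        "j_mass": res.corrected.data.loc[state, "j_mass"],
                        "j_cs": res.corrected.data.loc[state, "j_cs"],
                        "fcr": res.ratios.fcr[state],
                    })
                rows.append({
                    "group": group, "animal": i, "state": "E-P efficiency",
                    "j_mass": res.ratios.e_p_efficiency,
                })
                rows.append({
                    "group": group, "animal": i, "state": "P-L efficiency",
                    "j_mass": res.ratios.p_l_efficiency,
                })
        df = pd.DataFrame(rows)
        study.RESULTS.mkdir(exist_ok=True)
        df.to_csv(study.RESULTS / f"flux_{regime}.csv", index=False)
        medians = (
            df[~df["state"].str.contains("efficiency")]
            .pivot_table(index="state", columns="group", values="j_mass", aggfunc="median")
            .round(1)
        )
        print(f"\n{regime}: median Rox-corrected J_mass (pmol O2/s/mg)")
        print(medians.to_string())


if __name__ == "__main__":
    main()
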