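"""Generate the raw instrument data of the in-silico study.

Writes, under scratch/data/ (regenerable, not part of the deliverable):
  * respirometry traces + event schedules for 6 animals x 2 groups at air
    saturation, and the same cohort at tissue normoxia with the AmR channel
    (plus paired AmR-free runs);
  * CS-assay absorbance series per animal;
  * the qPCR Ct table;
  * stained-cell images (3 cells x 4 coverslips x 3 conditions).

A small manifest of what was generated goes to results/simulation_manifest.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import study  # noqa: E402

import mitoflux as mf  # noqa: E402


def main():
    manifest = {"traces": 0, "cs_assays": 0, "images": 0}

    for regime, sched_fn, with_amr in (
        ("air", study.respirometry_schedule, False),
        ("normoxic", study.ros_schedule, True),
    ):
        outdir = study.DATA / regime
        outdir.mkdir(parents=True, exist_ok=True)
        for group in study.GROUPS:
            for i in range(study.N_PER_GROUP):
                truth = study.animal_truth(group, i, regime)
                trace = mf.simulate_respirometry_trace(
                    sched_fn(), truth, o2_regime=regime,
                    chamber_volume_ml=study.CHAMBER_VOLUME_ML,
                    sample_mass_mg=study.SAMPLE_MASS_MG,
                )
                if with_amr:
                    # separate paired AmR-free O2 run from the same sample
                    paired = mf.simulate_respirometry_trace(
                        study.respirometry_schedule(), truth, o2_regime=regime,
                        chamber_volume_ml=study.CHAMBER_VOLUME_ML,
                        sample_mass_mg=study.SAMPLE_MASS_MG,
                    )
                    paired.to_csv(outdir / f"{group}_{i}_o2.csv",
                                  outdir / f"{group}_{i}_o2_events.yaml")
                    trace = mf.simulate_amr_channel(trace, truth)
                    manifest["traces"] += 1
                trace.to_csv(outdir / f"{group}_{i}.csv",
                             outdir / f"{group}_{i}_events.yaml")
                manifest["traces"] += 1

    csdir = study.DATA / "cs"
    csdir.mkdir(parents=True, exist_ok=True)
    for group in study.GROUPS:
        for i in range(study.N_PER_GROUP):
            rec = mf.simulate_cs_absorbance(
                study.cs_truth(group, i), noise_sd=0.002,
                seed=hash(("cs-noise", group, i)) % 100000,
            )
            pd.DataFrame({"time_s": rec.time_s, "absorbance": rec.absorbance}).to_csv(
                csdir / f"{group}_{i}.csv", index=False
            )
            manifest["cs_assays"] += 1

    ct = mf.simulate_qpcr(study.QPCR_FOLDS, study.QPCR_N, ct_noise_sd=0.25, seed=99)
    (study.DATA / "qpcr").mkdir(parents=True, exist_ok=True)
    ct.to_csv(study.DATA / "qpcr" / "ct.csv", index=False)

    imgdir = study.DATA / "images"
    for cond, fusion in study.FUSION.items():
        for cs_i in range(study.COVERSLIPS):
            for cell_i in range(study.CELLS_PER_COVERSLIP):
                seed = hash(("img", cond, cs_i, cell_i)) % 100000
                n_rods = int(np.random.default_rng(seed).integers(38, 53))
                cell = mf.render_cell_image(
                    mf.ImageGroundTruth(
                        n_particles=n_rods, fusion_degree=fusion, seed=seed
                    )
                )
                mf.synthetic_images.save_rendered(
                    cell, imgdir / cond, f"cs{cs_i}_cell{cell_i}"
                )
                manifest["images"] += 1

    study.RESULTS.mkdir(exist_ok=True)
    (study.RESULTS / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"generated {manifest['traces']} traces, {manifest['cs_assays']} CS assays, "
          f"{manifest['images']} cell images, 1 qPCR table -> {study.DATA}")


if __name__ == "__main__":
    main()
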