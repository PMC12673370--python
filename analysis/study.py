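"""Shared configuration of the in-silico preconditioning study.

Defines the simulated cohort: two groups (Ctrl, HPC) of six animals, each
measured by high-resolution respirometry at air saturation and at tissue
normoxia (the latter with the AmR H2O2 channel), plus CS assays, a qPCR
panel and stained-cell images at three conditions. Group effects follow the
qualitative directions of the biology being emulated: preconditioned tissue
respires less at effectively hyperoxic air saturation but more at tissue
normoxia, releases somewhat more H2O2, and cells shift toward fusion
immediately after hypoxia.
"""

from pathlib import Path

import numpy as np

import mitoflux as mf

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

N_PER_GROUP = 6
GROUPS = ("Ctrl", "HPC")
CHAMBER_VOLUME_ML = 2.0
SAMPLE_MASS_MG = 2.0

#: multiplicative group effect on mitochondrial O2 flux, by regime
O2_EFFECT = {"air": {"Ctrl": 1.0, "HPC": 0.85}, "normoxic": {"Ctrl": 1.0, "HPC": 1.3}}
#: group effect on H2O2 release (kept moderate so the simulated rise stays
#: within the ~2% physiological J_H2O2/J_O2 envelope)
H2O2_EFFECT = {"Ctrl": 1.0, "HPC": 1.25}
#: between-animal coefficient of variation of flux scale
ANIMAL_CV = 0.15
#: extra animal-level CV of H2O2 release beyond what tracks mitochondrial scale
H2O2_EXTRA_CV = 0.10
CS_ACTIVITY_MEAN = 0.1  # IU per mg wet mass

QPCR_FOLDS = {
    "Ctrl": {"Mfn1": 1.0, "Mfn2": 1.0, "Opa1": 1.0, "Drp1": 1.0},
    "rapid_HPC": {"Mfn1": 1.1, "Mfn2": 1.2, "Opa1": 1.1, "Drp1": 0.6},
    "delayed_HPC": {"Mfn1": 1.3, "Mfn2": 1.4, "Opa1": 1.2, "Drp1": 0.9},
}
QPCR_N = {"Ctrl": 8, "rapid_HPC": 6, "delayed_HPC": 8}

#: fusion degree of the rendered cells per condition
FUSION = {"Ctrl": 0.15, "rapid_HPC": 0.55, "delayed_HPC": 0.30}
COVERSLIPS = 4
CELLS_PER_COVERSLIP = 3


def animal_truth(group: str, index: int, regime: str, *, seed_base: int = 0):
    """Ground truth for one animal's chamber run in one regime."""
    seed = seed_base + hash((group, index, regime)) % 100000
    rng = np.random.default_rng(seed)
    scale = float(np.exp(rng.normal(0.0, ANIMAL_CV))) * O2_EFFECT[regime][group]
    # H2O2 release tracks the animal's mitochondrial scale, with a little
    # extra scatter on top of the group effect
    h_scale = scale * float(np.exp(rng.normal(0.0, H2O2_EXTRA_CV))) * H2O2_EFFECT[group]
    base = mf.TraceGroundTruth()
    return mf.TraceGroundTruth(
        j_o2_mass={k: v * scale for k, v in base.j_o2_mass.items()},
        j_h2o2_mass={k: v * h_scale for k, v in base.j_h2o2_mass.items()},
        j_rox_mass=base.j_rox_mass * scale,
        j_endogenous_mass=base.j_endogenous_mass * scale,
        seed=seed,
    )


def cs_truth(group: str, index: int) -> float:
    rng = np.random.default_rng(hash(("cs", group, index)) % 100000)
    return CS_ACTIVITY_MEAN * float(np.exp(rng.normal(0.0, 0.1)))


def respirometry_schedule():
    return mf.build_suit028_schedule()


def ros_schedule():
    return mf.build_suit028_schedule(
        sample_time_s=420.0,
        pre_sample_titrations=(120.0, 200.0, 280.0),
        h2o2_titration_interval_s=1200.0,
    )
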