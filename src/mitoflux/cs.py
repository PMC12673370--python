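"""Citrate synthase (CS) activity from the DTNB/TNB 412 nm assay.

CS activity is measured spectrophotometrically: CoA-SH released by the citrate
synthase reaction reduces DTNB to TNB, whose absorbance at 412 nm grows
linearly in time. Specific activity follows from the slope via Beer-Lambert:

    v = r_A / (l * eps_B * v_B) * (V_cuvette / V_sample) / rho

with v in IU per mg wet mass (1 IU = 1 umol citrate per min), r_A the
absorbance slope per minute, l the optical path (cm), eps_B the TNB extinction
coefficient (13.6 mM^-1 cm^-1 at pH 8.1), v_B the stoichiometric number (1),
and rho the sample mass concentration (mg/mL). CS activity serves as a
mitochondrial-content marker: respiration divided by the CS units present in
the chamber gives mitochondria-specific flux.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CsAssayRecord:
    """One cuvette: the 412 nm absorbance series plus assay parameters."""

    time_s: np.ndarray
    absorbance: np.ndarray
    path_length_cm: float = 1.0
    extinction_mM_cm: float = 13.6
    stoichiometric_number: float = 1.0
    cuvette_volume_ml: float = 1.0
    sample_volume_ul: float = 50.0
    mass_concentration_mg_ml: float = 2.0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time_s.shape != self.absorbance.shape or self.time_s.ndim != 1:
            raise ValueError("time/absorbance must be matching 1-D arrays")
        if self.time_s.size < 5:
            raise ValueError("need at least 5 absorbance points")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("absorbance series must be time-ordered")
        for name in (
            "path_length_cm", "extinction_mM_cm", "stoichiometric_number",
            "cuvette_volume_ml", "sample_volume_ul", "mass_concentration_mg_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_csv(cls, path: str | Path, **params) -> "CsAssayRecord":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["absorbance"].to_numpy(), **params)


@dataclass
class SlopeFit:
    r_a_per_min: float
    r_squared: float
    stderr_per_min: float
    declining: bool = False  # reaction-not-proceeding warning flag
    blank_corrected: bool = False


def fit_absorbance_slope(record: CsAssayRecord, blank: CsAssayRecord | None = None) -> SlopeFit:
    """Least-squares slope of A(t), in min^-1, optionally blank-subtracted.

    A declining overall trend sets ``declining`` (reaction not proceeding)
    rather than raising: zero-activity series are legitimate.
    """
    res = stats.linregress(record.time_s, record.absorbance)
    slope_s, stderr_s = res.slope, res.stderr
    if blank is not None:
        bres = stats.linregress(blank.time_s, blank.absorbance)
        slope_s -= bres.slope
        stderr_s = float(np.hypot(stderr_s, bres.stderr))
    return SlopeFit(
        r_a_per_min=slope_s * 60.0,
        r_squared=float(res.rvalue**2),
        stderr_per_min=stderr_s * 60.0,
        declining=bool(slope_s < 0),
        blank_corrected=blank is not None,
    )


def cs_activity(r_a_per_min: float, record: CsAssayRecord) -> float:
    """Specific CS activity v in IU per mg wet mass.

    Cuvette and sample volumes are brought to a common unit (mL) before
    forming their ratio.
    """
    if r_a_per_min < 0:
        raise ValueError("r_A must be >= 0")
    sample_volume_ml = record.sample_volume_ul / 1000.0
    return (
        r_a_per_min
        / (record.path_length_cm * record.extinction_mM_cm * record.stoichiometric_number)
        * (record.cuvette_volume_ml / sample_volume_ml)
        / record.mass_concentration_mg_ml
    )


def chamber_cs_units(activity_iu_per_mg: float, mass_in_chamber_mg: float) -> float:
    """CS units (IU) present in the respirometer chamber: v * mass."""
    if activity_iu_per_mg <= 0:
        raise ValueError("zero/negative CS activity: CS normalization impossible")
    if mass_in_chamber_mg <= 0:
        raise ValueError("chamber sample mass must be > 0")
    return activity_iu_per_mg * mass_in_chamber_mg


def analyze_cs_assay(
    record: CsAssayRecord, blank: CsAssayRecord | None = None
) -> dict:
    """Full assay: slope fit + specific activity, as a JSON-ready dict."""
    fit = fit_absorbance_slope(record, blank)
    r_a = max(fit.r_a_per_min, 0.0)
    return {
        "r_A_per_min": fit.r_a_per_min,
        "v_iu_per_mg": cs_activity(r_a, record),
        "r_squared": fit.r_squared,
        "declining": fit.declining,
        "blank_corrected": fit.blank_corrected,
    }


def write_cs_json(result: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result, indent=2))
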