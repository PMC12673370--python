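"""Amplex UltraRed H2O2 flux calibration and analysis.

The fluorimetric channel reports F(t) = background(t) + s(t) * C(t), where C
is the cumulative H2O2 converted by horseradish peroxidase and s the reagent
sensitivity (V per uM), which drifts as the fluorophore and reagents age. Two
calibration layers recover C(t):

* a pre-sample calibration (reagents only, no biology) jointly fits the
  chemical background (intercept + linear drift) and the initial sensitivity
  s0 from the known 0.1 uM titration steps;
* in-run 0.1 uM titrations re-measure the sensitivity as step height / 0.1,
  giving time-stamped knots; between knots the sensitivity is interpolated
  linearly, outside them the nearest knot value is used.

H2O2 flux on a state window is then the slope of C(t) scaled exactly like the
O2 flux (x1000 x V/m, or x V/IU for the mitochondria-specific flux), and
J_H2O2/J_O2 is formed against an AmR-free paired O2 measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .respirometry import FluxTable, SuitState, UM_PER_S_TO_PMOL_S_ML
from .trace import RespirometryTrace


@dataclass
class AmrCalibration:
    background_intercept_v: float
    background_drift_v_per_s: float
    knot_times_s: np.ndarray
    knot_sens_v_per_um: np.ndarray
    residual_sd_v: float = 0.0
    span_s: tuple = (0.0, np.inf)

    def __post_init__(self):
        self.knot_times_s = np.atleast_1d(np.asarray(self.knot_times_s, dtype=float))
        self.knot_sens_v_per_um = np.atleast_1d(
            np.asarray(self.knot_sens_v_per_um, dtype=float)
        )
        if self.knot_times_s.shape != self.knot_sens_v_per_um.shape:
            raise ValueError("knot arrays must match")
        if np.any(np.diff(self.knot_times_s) <= 0):
            raise ValueError("sensitivity knots must be time-ordered")
        if np.any(self.knot_sens_v_per_um <= 0):
            raise ValueError("all sensitivity values must be > 0")

    def background(self, t_s) -> np.ndarray:
        return self.background_intercept_v + self.background_drift_v_per_s * np.asarray(t_s)

    def sensitivity(self, t_s) -> np.ndarray:
        """Piecewise-linear between knots, nearest-knot outside them."""
        return np.interp(np.asarray(t_s), self.knot_times_s, self.knot_sens_v_per_um)

    def with_knots(self, times, sens) -> "AmrCalibration":
        t = np.concatenate([self.knot_times_s, np.asarray(times, dtype=float)])
        s = np.concatenate([self.knot_sens_v_per_um, np.asarray(sens, dtype=float)])
        order = np.argsort(t)
        return AmrCalibration(
            self.background_intercept_v,
            self.background_drift_v_per_s,
            t[order],
            s[order],
            self.residual_sd_v,
            self.span_s,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "background_intercept_v": self.background_intercept_v,
                    "background_drift_v_per_s": self.background_drift_v_per_s,
                    "knot_times_s": self.knot_times_s.tolist(),
                    "knot_sens_v_per_um": self.knot_sens_v_per_um.tolist(),
                    "residual_sd_v": self.residual_sd_v,
                    "span_s": list(self.span_s),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AmrCalibration":
        d = json.loads(Path(path).read_text())
        d["knot_times_s"] = np.asarray(d["knot_times_s"])
        d["knot_sens_v_per_um"] = np.asarray(d["knot_sens_v_per_um"])
        d["span_s"] = tuple(d["span_s"])
        return cls(**d)


def _titration_times(trace: RespirometryTrace) -> np.ndarray:
    return np.array(sorted(e.time_s for e in trace.events if e.substance == "H2O2"))


def fit_background_calibration(
    trace: RespirometryTrace,
    *,
    sample_time_s: float | None = None,
    titration_step_um: float = 0.1,
) -> AmrCalibration:
    """Fit chemical background and initial sensitivity from the pre-sample segment.

    The pre-sample fluorescence is modelled as
    F(t) = a + b*t + s(t) * cum(t) with cum(t) = 0.1 uM x number of
    titrations so far and s(t) = s0 * (1 + g*t) a first-order sensitivity
    drift; a, b, s0 and g come from one joint least-squares fit (equivalent
    to regressing step height on added H2O2 while fitting the chemical drift
    between steps, but immune to sensitivity decay leaking into the chemical
    drift term). Requires at least two pre-sample titration steps. The fitted
    s0 becomes the t = 0 anchor knot of the sensitivity track.
    """
    if trace.fluo_v is None:
        raise ValueError("trace has no fluorescence channel")
    if sample_time_s is None:
        sample_time_s = trace.sample_time()
    if sample_time_s is None:
        raise ValueError("no sample-addition event; pass sample_time_s explicitly")
    tit = _titration_times(trace)
    tit = tit[tit < sample_time_s]
    if tit.size < 2:
        raise ValueError(
            f"background calibration needs >= 2 pre-sample titration steps, found {tit.size}"
        )
    m = trace.mask_window(trace.time_s[0], sample_time_s)
    m &= trace.time_s < sample_time_s
    t = trace.time_s[m]
    f = trace.fluo_v[m]
    cum = titration_step_um * np.searchsorted(tit, t, side="right")
    design = np.column_stack([np.ones_like(t), t, cum, cum * t])
    coef, *_ = np.linalg.lstsq(design, f, rcond=None)
    if not np.all(np.isfinite(coef)):
        design = design[:, :3]
        coef, *_ = np.linalg.lstsq(design, f, rcond=None)
    a, b, s0 = (float(x) for x in coef[:3])
    if s0 <= 0:
        raise ValueError("fitted AmR sensitivity is non-positive; calibration invalid")
    resid = f - design @ coef
    dof = max(resid.size - design.shape[1], 1)
    return AmrCalibration(
        background_intercept_v=a,
        background_drift_v_per_s=b,
        knot_times_s=np.array([0.0]),
        knot_sens_v_per_um=np.array([s0]),
        residual_sd_v=float(np.sqrt((resid**2).sum() / dof)),
        span_s=(float(trace.time_s[0]), float(trace.time_s[-1])),
    )


def update_sensitivity(
    trace: RespirometryTrace,
    calibration: AmrCalibration,
    *,
    titration_step_um: float = 0.1,
    pre_window_s: float = 30.0,
    post_gap_s: float = 12.0,
    post_window_s: float = 20.0,
) -> AmrCalibration:
    """Add sensitivity knots from the in-run 0.1 uM H2O2 titrations.

    Each step height is measured against a local linear fit of the
    pre-titration fluorescence extrapolated across the masked mixing
    transient, so chemical drift and the metabolic H2O2 ramp cancel.
    """
    if trace.fluo_v is None:
        raise ValueError("trace has no fluorescence channel")
    sample_time = trace.sample_time()
    tit = _titration_times(trace)
    if sample_time is not None:
        tit = tit[tit > sample_time]
    times, sens = [], []
    for te in tit:
        pre = trace.mask_window(te - pre_window_s, te - 1e-9)
        post = trace.mask_window(te + post_gap_s, te + post_gap_s + post_window_s)
        if pre.sum() < 3 or post.sum() < 3:
            raise ValueError(f"titration at t={te:.0f} s: not enough clean samples around the step")
        coef = np.polyfit(trace.time_s[pre], trace.fluo_v[pre], 1)
        height = float(np.mean(trace.fluo_v[post] - np.polyval(coef, trace.time_s[post])))
        if height <= 0:
            raise ValueError(
                f"titration at t={te:.0f} s: non-positive step height ({height:.4g} V)"
            )
        times.append(float(te))
        sens.append(height / titration_step_um)
    return calibration.with_knots(times, sens)


@dataclass
class H2o2FluxTable:
    """Per-state H2O2 fluxes (volume-, mass- and CS-specific)."""

    data: pd.DataFrame

    def mass_flux(self, state: str) -> float:
        return float(self.data.loc[state, "j_mass"])

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "state", out.index)
        out.to_csv(path, index=False)


def h2o2_flux(
    trace: RespirometryTrace,
    windows: list[SuitState],
    calibration: AmrCalibration,
    *,
    cs_units_iu: float | None = None,
) -> H2o2FluxTable:
    """H2O2 fluxes per state window.

    The fluorescence is converted to concentration,
    c(t) = (F(t) - background(t)) / s(t), and the flux is the slope of c on
    the window scaled by 1000 * V/m (mass-specific) and * V/IU (CS-specific).
    """
    if trace.fluo_v is None:
        raise ValueError("trace has no fluorescence channel")
    rows = {}
    for w in windows:
        if w.start_s < calibration.span_s[0] or w.end_s > calibration.span_s[1]:
            raise ValueError(
                f"window for {w.label} [{w.start_s:.0f}, {w.end_s:.0f}] s lies outside "
                f"the calibration span {calibration.span_s}"
            )
        m = trace.mask_window(w.start_s, w.end_s)
        if m.sum() < 10:
            raise ValueError(f"window for {w.label} has {int(m.sum())} samples; need >= 10")
        t = trace.time_s[m]
        conc = (trace.fluo_v[m] - calibration.background(t)) / calibration.sensitivity(t)
        slope = np.polyfit(t, conc, 1)[0]
        j_v = slope * UM_PER_S_TO_PMOL_S_ML
        rows[w.label] = {
            "j_v": j_v,
            "j_mass": j_v * trace.chamber_volume_ml / trace.sample_mass_mg,
            "j_cs": j_v * trace.chamber_volume_ml / cs_units_iu if cs_units_iu else np.nan,
            "window_start": w.start_s,
            "window_end": w.end_s,
        }
    return H2o2FluxTable(pd.DataFrame.from_dict(rows, orient="index"))


def flux_ratio(h2o2: H2o2FluxTable, paired_o2) -> pd.DataFrame:
    """J_H2O2/J_O2 per state: H2O2 produced per O2 consumed.

    ``paired_o2`` is the Rox-corrected mass-specific O2 flux from the paired
    AmR-free measurement (a FluxTable or a {state: flux} mapping); the with-
    AmR O2 channel is never used. States with J_O2 <= 0 get a missing ratio.
    """
    if isinstance(paired_o2, FluxTable):
        o2 = {s: paired_o2.mass_flux(s) for s in paired_o2.states}
    else:
        o2 = dict(paired_o2)
    rows = {}
    for state in h2o2.data.index:
        if state not in o2:
            continue
        j_h = float(h2o2.data.loc[state, "j_mass"])
        j_o = float(o2[state])
        ratio = j_h / j_o if j_o > 0 else np.nan
        rows[state] = {
            "j_h2o2_mass": j_h,
            "j_o2_mass": j_o,
            "ratio": ratio,
            "ratio_pct": ratio * 100.0 if np.isfinite(ratio) else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
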