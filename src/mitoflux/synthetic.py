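"""Synthetic instrument data with recorded ground truth.

Every input the analysis chain consumes can be generated here: SUIT-protocol
O2 traces at two O2 regimes, the Amplex UltraRed fluorescence channel with
chemical background drift and decaying sensitivity, CS-assay absorbance
series, and qPCR Ct tables. Fluxes are imposed per state (piecewise-constant
metabolic model), not mechanistic. All generators are deterministic for a
fixed seed and are exactly inverted by their analysis counterparts in the
noiseless limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cs import CsAssayRecord
from .events import (
    Event,
    O2Regime,
    REGIMES,
    run_end_time,
    validate_events,
)
from .trace import RespirometryTrace, TRANSIENT_LABEL

__all__ = [
    "TraceGroundTruth",
    "simulate_respirometry_trace",
    "simulate_amr_channel",
    "simulate_cs_absorbance",
    "simulate_qpcr",
]

#: default mass-specific mitochondrial O2 fluxes (pmol O2 s^-1 mg^-1), already
#: Rox-corrected truth, representative of mouse brain homogenate
DEFAULT_J_O2 = {"N_L": 12.0, "N_P": 60.0, "NS_P": 90.0, "NS_E": 110.0, "S_E": 60.0}

#: physiological preset for H2O2 release (pmol H2O2 s^-1 mg^-1); chosen so
#: J_H2O2/J_O2 stays below the ~2% physiological ceiling in every state, with
#: the LEAK state showing the highest fractional release as in tissue
DEFAULT_J_H2O2 = {
    "N_L": 0.15,
    "N_P": 0.30,
    "NS_P": 0.55,
    "NS_E": 0.60,
    "S_E": 0.35,
    "ROX": 0.02,
}


@dataclass
class TraceGroundTruth:
    """Generative parameters of one simulated chamber run.

    ``j_o2_mass`` holds the true mitochondrial (Rox-corrected) mass-specific
    flux per SUIT state; the generator adds ``j_rox_mass`` to every
    post-sample state so the analysis-side Rox correction has something real
    to remove.
    """

    j_o2_mass: dict = field(default_factory=lambda: dict(DEFAULT_J_O2))
    j_rox_mass: float = 4.0
    j_endogenous_mass: float = 8.0
    j_h2o2_mass: dict = field(default_factory=lambda: dict(DEFAULT_J_H2O2))
    cytc_effect: float = 0.05
    uncoupler_profile: tuple = (0.93, 1.0, 0.97)
    sensitivity_v_per_um: float = 1.0
    sensitivity_decay_per_h: float = 0.10
    background_intercept_v: float = 0.05
    background_slope_v_per_s: float = 2e-6
    o2_noise_um: float = 0.5
    fluo_noise_v: float = 0.002
    seed: int = 0

    def __post_init__(self):
        for k, v in self.j_o2_mass.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite true flux for state {k}")
        if self.j_rox_mass < 0:
            raise ValueError("Rox-state true flux must be >= 0")
        if self.sensitivity_v_per_um <= 0:
            raise ValueError("AmR sensitivity must be positive")
        if not 0 <= self.sensitivity_decay_per_h < 1:
            raise ValueError("sensitivity decay must be a fraction per hour in [0, 1)")
        if self.o2_noise_um < 0 or self.fluo_noise_v < 0:
            raise ValueError("noise SDs must be >= 0")

    def noiseless(self) -> "TraceGroundTruth":
        return replace(self, o2_noise_um=0.0, fluo_noise_v=0.0)

    def sensitivity_at(self, t_s: float | np.ndarray) -> np.ndarray:
        """AmR sensitivity s(t) in V/uM, decaying exponentially."""
        frac = 1.0 - self.sensitivity_decay_per_h
        return self.sensitivity_v_per_um * np.power(frac, np.asarray(t_s) / 3600.0)


# ---------------------------------------------------------------------------
# state timeline


def _state_timeline(events, truth: TraceGroundTruth, end_s: float):
    """Metabolic segments (state, t0, t1, j_o2_total_mass, j_h2o2_mass).

    H2O2 titrations and reoxygenations are not metabolic boundaries; only
    SUIT injections change state. Total O2 flux is mitochondrial + Rox.
    """
    rox = truth.j_rox_mass
    boundaries = []  # (time, state, j_total, j_h2o2)
    h2 = truth.j_h2o2_mass or {}
    n_u = 0
    for e in events:
        if e.substance == "sample":
            boundaries.append((e.time_s, "endogenous", truth.j_endogenous_mass + rox, 0.0))
        elif e.substance == "G":
            boundaries.append((e.time_s, "N_L", truth.j_o2_mass["N_L"] + rox, h2.get("N_L", 0.0)))
        elif e.substance == "D":
            boundaries.append((e.time_s, "N_P", truth.j_o2_mass["N_P"] + rox, h2.get("N_P", 0.0)))
        elif e.substance == "c":
            j = truth.j_o2_mass["N_P"] * (1.0 + truth.cytc_effect)
            boundaries.append((e.time_s, "N_P_c", j + rox, h2.get("N_P", 0.0)))
        elif e.substance == "S":
            boundaries.append((e.time_s, "NS_P", truth.j_o2_mass["NS_P"] + rox, h2.get("NS_P", 0.0)))
        elif e.substance == "U":
            mult = truth.uncoupler_profile[min(n_u, len(truth.uncoupler_profile) - 1)]
            n_u += 1
            j = truth.j_o2_mass["NS_E"] * mult
            boundaries.append((e.time_s, f"NS_E_step{n_u}", j + rox, h2.get("NS_E", 0.0)))
        elif e.substance == "Rot":
            boundaries.append((e.time_s, "S_E", truth.j_o2_mass["S_E"] + rox, h2.get("S_E", 0.0)))
        elif e.substance == "Ama":
            boundaries.append((e.time_s, "ROX", rox, h2.get("ROX", 0.0)))
    segments = []
    prev = (0.0, "pre", 0.0, 0.0)
    for b in boundaries:
        if b[0] > prev[0]:
            segments.append((prev[1], prev[0], b[0], prev[2], prev[3]))
        prev = b
    if end_s > prev[0]:
        segments.append((prev[1], prev[0], end_s, prev[2], prev[3]))
    return segments


_CANONICAL = ("N_L", "N_P", "NS_P", "S_E", "ROX")


def simulate_respirometry_trace(
    events,
    truth: TraceGroundTruth,
    *,
    o2_regime: str | O2Regime = "air",
    chamber_volume_ml: float = 2.0,
    sample_mass_mg: float = 2.0,
    dt_s: float = 2.0,
    end_time_s: float | None = None,
    auto_reoxygenate: bool = True,
    transient_s: float = 10.0,
    transient_amp_um: float = 2.0,
) -> RespirometryTrace:
    """Simulate one SUIT chamber run.

    The clean O2 concentration integrates -J_V/1000 uM/s within each
    piecewise-constant state (1 uM = 1000 pmol/mL). Reoxygenation (scheduled,
    or automatic when the regime floor is reached) steps the concentration
    back to the regime ceiling. Each injection leaves a 10 s mixing transient
    whose samples are labelled ``transient`` and carry a spike artifact.
    Gaussian noise of SD ``truth.o2_noise_um`` is added last.
    """
    regime = REGIMES[o2_regime] if isinstance(o2_regime, str) else o2_regime
    events = validate_events(events)
    end_s = end_time_s if end_time_s is not None else run_end_time(events)
    segments = _state_timeline(events, truth, end_s)

    for state, t0, t1, _, _ in segments:
        base = state.split("_step")[0]
        if (base in _CANONICAL or base == "NS_E") and (t1 - t0) < 120.0:
            raise ValueError(f"state plateau for {state} is {t1 - t0:.0f} s; need >= 120 s")

    mass_per_vol = sample_mass_mg / chamber_volume_ml
    sched_reox = sorted(e.time_s for e in events if e.substance == "reoxygenation")

    # clean concentration as linear pieces (t0, t1, c0, slope_um_per_s)
    pieces = []
    auto_events: list[Event] = []
    c = regime.ceiling_um
    for state, t0, t1, j_mass, _ in segments:
        slope = j_mass * mass_per_vol / 1000.0  # uM consumed per s
        t_cur = t0
        while True:
            # next forced jump inside this segment?
            nxt = next((ts for ts in sched_reox if t_cur < ts <= t1), None)
            seg_end = nxt if nxt is not None else t1
            if auto_reoxygenate and slope > 0:
                t_floor = t_cur + (c - regime.floor_um) / slope
                if t_floor < seg_end:
                    pieces.append((t_cur, t_floor, c, slope))
                    c = regime.ceiling_um
                    auto_events.append(Event(round(t_floor, 6), "reoxygenation"))
                    t_cur = t_floor
                    continue
            c_end = c - slope * (seg_end - t_cur)
            if c_end < 0:
                raise ValueError(
                    f"O2 concentration driven below 0 in state {state!r}: "
                    f"flux too high for regime {regime.name!r}"
                )
            pieces.append((t_cur, seg_end, c, slope))
            c = c_end
            if nxt is not None:
                c = regime.ceiling_um
                t_cur = nxt
            else:
                break

    t = np.arange(0.0, end_s + dt_s / 2, dt_s)
    o2 = np.empty_like(t)
    labels = np.empty(t.size, dtype=object)
    starts = np.array([p[0] for p in pieces])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(pieces) - 1)
    for i, p in enumerate(pieces):
        sel = idx == i
        o2[sel] = p[2] - p[3] * (t[sel] - p[0])
    seg_starts = np.array([s[1] for s in segments])
    sidx = np.clip(np.searchsorted(seg_starts, t, side="right") - 1, 0, len(segments) - 1)
    for i, s in enumerate(segments):
        labels[sidx == i] = s[0]

    all_events = validate_events(list(events) + auto_events)
    for e in all_events:
        m = (t > e.time_s) & (t <= e.time_s + transient_s)
        labels[m] = TRANSIENT_LABEL
        o2[m] += transient_amp_um * np.exp(-(t[m] - e.time_s) / (transient_s / 3.0))

    rng = np.random.default_rng(truth.seed)
    if truth.o2_noise_um > 0:
        o2 = o2 + rng.normal(0.0, truth.o2_noise_um, size=o2.size)

    return RespirometryTrace(
        time_s=t,
        o2_um=o2,
        events=all_events,
        chamber_volume_ml=chamber_volume_ml,
        sample_mass_mg=sample_mass_mg,
        state_label=labels,
        segments=[(s[0], s[1], s[2]) for s in segments],
    )


def simulate_amr_channel(
    trace: RespirometryTrace,
    truth: TraceGroundTruth,
    *,
    titration_times: list[float] | None = None,
    titration_step_um: float = 0.1,
    transient_s: float = 10.0,
    transient_amp_v: float = 0.02,
) -> RespirometryTrace:
    """Append the Amplex UltraRed fluorescence channel to a simulated trace.

    F(t) = background(t) + s(t) * C(t), where C(t) is the cumulative H2O2 in
    the chamber (metabolic release integrated per state, plus the 0.1 uM
    calibration titrations as instantaneous steps) and s(t) decays by
    ``truth.sensitivity_decay_per_h`` per hour. The chemical background is
    linear in time.

    ``titration_times``, if given, adds H2O2 calibration events to the trace
    (on top of any already in the schedule); calibration steps must precede
    the sample-addition event to serve the background calibration.
    """
    events = list(trace.events)
    if titration_times:
        events += [Event(ts, "H2O2", titration_step_um, "uM") for ts in titration_times]
    events = validate_events(events)
    trace.events = events

    t = trace.time_s
    mass_per_vol = trace.sample_mass_mg / trace.chamber_volume_ml

    # cumulative metabolic H2O2 (uM), piecewise linear over the state segments
    seg = trace.segments
    if not seg:
        raise ValueError("trace has no recorded state segments; generate it with simulate_respirometry_trace")
    timeline = _state_timeline(events, truth, float(t[-1]))
    cum = np.zeros_like(t)
    acc = 0.0
    for state, t0, t1, _, j_h2o2 in timeline:
        rate = j_h2o2 * mass_per_vol / 1000.0  # uM/s
        m = (t >= t0) & (t <= t1)
        cum[m] = acc + rate * (t[m] - t0)
        acc += rate * (t1 - t0)
    tit_times = np.array(sorted(e.time_s for e in events if e.substance == "H2O2"))
    if tit_times.size:
        cum = cum + titration_step_um * np.searchsorted(tit_times, t, side="right")

    f = (
        truth.background_intercept_v
        + truth.background_slope_v_per_s * t
        + truth.sensitivity_at(t) * cum
    )
    labels = trace.state_label
    for e in events:
        m = (t > e.time_s) & (t <= e.time_s + transient_s)
        f[m] += transient_amp_v * np.exp(-(t[m] - e.time_s) / (transient_s / 3.0))
        labels[m] = TRANSIENT_LABEL

    rng = np.random.default_rng(truth.seed + 1)
    if truth.fluo_noise_v > 0:
        f = f + rng.normal(0.0, truth.fluo_noise_v, size=f.size)
    trace.fluo_v = f
    return trace


# ---------------------------------------------------------------------------
# CS assay


def simulate_cs_absorbance(
    true_activity_iu_per_mg: float,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 13,
    dt_s: float = 10.0,
    baseline_absorbance: float = 0.1,
    **assay_params,
) -> CsAssayRecord:
    """Absorbance series (412 nm, 10 s cadence) implied by a CS activity.

    The slope is obtained by inverting the specific-activity equation at the
    configured assay parameters, so the analysis round-trip is exact in the
    noiseless limit.
    """
    if true_activity_iu_per_mg < 0:
        raise ValueError("activity must be >= 0")
    t = np.arange(n_points) * dt_s
    ref = CsAssayRecord(t, np.zeros_like(t), **assay_params)
    r_a_per_min = (
        true_activity_iu_per_mg
        * ref.path_length_cm * ref.extinction_mM_cm * ref.stoichiometric_number
        * ref.mass_concentration_mg_ml
        * (ref.sample_volume_ul / 1000.0) / ref.cuvette_volume_ml
    )
    a = baseline_absorbance + (r_a_per_min / 60.0) * t
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=a.size)
    return CsAssayRecord(t, a, **assay_params)


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    group_fold_changes: dict,
    n_per_group: int | dict,
    *,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "Actb",
    reference_ct_mean: float = 20.0,
    reference_ct_sd: float = 0.7,
    base_delta_ct: float | dict = 5.0,
) -> pd.DataFrame:
    """Long-format Ct table (sample_id, group, gene, ct).

    Target Ct = reference Ct + baseline dCt - log2(fold change) + noise; the
    reference-gene Ct is drawn independently of group (the housekeeping
    assumption), so run-to-run offsets cancel through dCt. Defaults put the
    reference near Ct 20 with SD 0.7, the stability reported for beta-actin.

    Parameters
    ----------
    group_fold_changes : dict
        ``{group: {gene: fold}}``; all folds must be > 0. Use fold 1.0 for
        the control group.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, folds in group_fold_changes.items():
        for f in folds.values():
            if f <= 0:
                raise ValueError("fold changes must be > 0")
        n = n_per_group[group] if isinstance(n_per_group, dict) else n_per_group
        for i in range(n):
            sid = f"{group}_{i + 1}"
            ct_ref = reference_ct_mean + rng.normal(0.0, reference_ct_sd)
            rows.append((sid, group, reference_gene, ct_ref))
            for gene, fold in folds.items():
                base = base_delta_ct[gene] if isinstance(base_delta_ct, dict) else base_delta_ct
                ct = ct_ref + base - math.log2(fold)
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append((sid, group, gene, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
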