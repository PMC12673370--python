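"""SUIT respirometry flux analysis.

Turns an O2 concentration trace plus its titration schedule into per-state
fluxes and the derived coupling-control quantities:

* state windows are marked on the plateaus of the SUIT-028 sequence
  (N_L -> N_P -> NS_P -> NS_E -> S_E -> ROX), excluding injection transients;
* volume-specific flux J_V is the negative least-squares slope of c(t) on a
  window (1 uM/s = 1000 pmol s^-1 mL^-1), normalized per wet mass (J_V * V/m)
  and per CS unit (J_V * V/IU, the mitochondria-specific flux);
* all states are baseline-corrected by the residual O2 consumption (Rox)
  measured after antimycin A;
* flux control ratios express each state relative to maximal ET capacity
  (NS_E), and the coupling-control efficiencies are
  E-P = 1 - NS_P/NS_E and P-L = 1 - N_L/N_P.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import Event
from .trace import RespirometryTrace

SUIT_STATE_ORDER = ("N_L", "N_P", "NS_P", "NS_E", "S_E", "ROX")

UM_PER_S_TO_PMOL_S_ML = 1000.0  # 1 uM = 1000 pmol/mL


@dataclass(frozen=True)
class WindowPolicy:
    """How plateau windows are selected.

    The default takes the latest 120 s of the cleanest sub-segment of each
    plateau, ending 30 s before the next injection, with the first 10 s after
    any injection (the mixing transient) excluded. Reoxygenations carry no
    pre-event pipetting artifact, so only a short guard is kept before them.
    """

    window_s: float = 120.0
    pre_event_gap_s: float = 30.0
    pre_reox_gap_s: float = 4.0
    transient_s: float = 10.0
    min_window_s: float = 30.0
    min_fragment_samples: int = 6


@dataclass(frozen=True)
class SuitState:
    label: str
    start_s: float
    end_s: float
    defining_event: Event | None = None


class FluxFit(NamedTuple):
    j_v: float            # pmol O2 s^-1 mL^-1
    se: float             # standard error of J_V
    n: int
    window: tuple


def compute_volume_flux(trace: RespirometryTrace, window) -> FluxFit:
    """Volume-specific O2 flux on a window: -slope of the linear fit of c(t)."""
    if isinstance(window, SuitState):
        start, end = window.start_s, window.end_s
    else:
        start, end = window
    m = trace.mask_window(start, end)
    if int(m.sum()) < 10:
        raise ValueError(
            f"window [{start:.0f}, {end:.0f}] s has {int(m.sum())} samples; need >= 10"
        )
    res = stats.linregress(trace.time_s[m], trace.o2_um[m])
    return FluxFit(
        j_v=-res.slope * UM_PER_S_TO_PMOL_S_ML,
        se=res.stderr * UM_PER_S_TO_PMOL_S_ML,
        n=int(m.sum()),
        window=(float(start), float(end)),
    )


# ---------------------------------------------------------------------------
# window marking


def _last_event(events, substance):
    out = [e for e in events if e.substance == substance]
    return out[-1] if out else None


def _clean_fragments(trace, t0, t1, policy, *, end_is_event=True):
    """Usable (start, end) stretches inside (t0, t1), between internal events.

    Each fragment starts after the mixing transient of the event opening it
    and ends before the next event: 30 s early for injections (pipetting
    artifact guard), only a short guard for reoxygenations.
    """
    internal = sorted(
        (e.time_s, e.substance) for e in trace.events if t0 < e.time_s < t1
    )
    bounds = [(t0, None)] + internal + [(t1, "injection" if end_is_event else None)]
    fragments = []
    for i in range(len(bounds) - 1):
        (a0, _), (a1, nxt_sub) = bounds[i], bounds[i + 1]
        start = a0 + policy.transient_s
        if nxt_sub is None:
            end = a1
        elif nxt_sub == "reoxygenation":
            end = a1 - policy.pre_reox_gap_s
        else:
            end = a1 - policy.pre_event_gap_s
        if end > start:
            fragments.append((start, end))
    return fragments


def _window_in_span(trace, t0, t1, policy, *, end_is_event=True):
    """Single best clean window inside (t0, t1).

    Prefers the latest fragment that holds a full ``window_s`` window; when
    reoxygenations/titrations fragment the plateau below that, the longest
    clean fragment of at least ``min_window_s`` is used instead (short late
    fragments carry too little slope information).
    """
    fragments = _clean_fragments(trace, t0, t1, policy, end_is_event=end_is_event)
    if not fragments:
        return None
    for start, end in reversed(fragments):
        if end - start >= policy.window_s:
            return (end - policy.window_s, end)
    start, end = max(fragments, key=lambda w: w[1] - w[0])
    if end - start >= policy.min_window_s:
        return (start, end)
    return None


def compute_state_flux(
    trace: RespirometryTrace,
    span: tuple,
    policy: WindowPolicy | None = None,
    *,
    end_is_event: bool = True,
) -> FluxFit:
    """Plateau flux pooled over all clean fragments of a state's span.

    A reoxygenation shifts the O2 level but not the metabolic flux, so the
    slope is shared across fragments while each fragment keeps its own
    intercept (within-fragment demeaned least squares). Falls back to the
    information of whatever fragments exist; equivalent to the plain
    single-window fit when the plateau is uninterrupted.
    """
    policy = policy or WindowPolicy()
    fragments = _clean_fragments(trace, span[0], span[1], policy, end_is_event=end_is_event)
    sxx = sxy = sse_base = 0.0
    n_tot = 0
    used = []
    parts = []
    for start, end in fragments:
        m = trace.mask_window(start, end)
        if int(m.sum()) < policy.min_fragment_samples:
            continue
        t = trace.time_s[m]
        y = trace.o2_um[m]
        tc = t - t.mean()
        yc = y - y.mean()
        sxx += float(tc @ tc)
        sxy += float(tc @ yc)
        n_tot += t.size
        used.append((start, end))
        parts.append((tc, yc))
    if n_tot < 10 or sxx == 0.0:
        raise ValueError(
            f"span [{span[0]:.0f}, {span[1]:.0f}] s has {n_tot} clean samples; need >= 10"
        )
    slope = sxy / sxx
    sse = sum(float((yc - slope * tc) @ (yc - slope * tc)) for tc, yc in parts)
    dof = max(n_tot - 2 * len(used), 1)
    se = np.sqrt(sse / dof / sxx)
    return FluxFit(
        j_v=-slope * UM_PER_S_TO_PMOL_S_ML,
        se=se * UM_PER_S_TO_PMOL_S_ML,
        n=n_tot,
        window=(used[0][0], used[-1][1]),
    )


@dataclass(frozen=True)
class StateSpans:
    """Full plateau spans of the SUIT-028 states (before window selection)."""

    spans: dict          # label -> (t0, t1, end_is_event)
    u_steps: list        # [(event, t0, t1)] for the uncoupler titration
    defining: dict       # label -> Event


def state_spans(trace: RespirometryTrace) -> StateSpans:
    """Plateau span per state from the event schedule.

    Raises if a defining event is missing, naming the state that cannot be
    marked.
    """
    ev = trace.events
    t_end = float(trace.time_s[-1])
    pgm = _last_event(ev, "G") or _last_event(ev, "M") or _last_event(ev, "P")
    d = _last_event(ev, "D")
    c = _last_event(ev, "c")
    s = _last_event(ev, "S")
    u_steps = [e for e in ev if e.substance == "U"]
    rot = _last_event(ev, "Rot")
    ama = _last_event(ev, "Ama")
    for state, e in {"N_L": pgm, "N_P": d, "NS_P": s, "S_E": rot, "ROX": ama}.items():
        if e is None:
            raise ValueError(f"{state} unmarkable: defining event missing from schedule")
    if not u_steps:
        raise ValueError("NS_E unmarkable: no uncoupler (U) titration steps in schedule")
    spans = {
        "N_L": (pgm.time_s, d.time_s, True),
        "N_P": (d.time_s, (c.time_s if c is not None else s.time_s), True),
        "NS_P": (s.time_s, u_steps[0].time_s, True),
        "S_E": (rot.time_s, ama.time_s, True),
        "ROX": (ama.time_s, t_end, False),
    }
    steps = []
    for i, u in enumerate(u_steps):
        nxt = u_steps[i + 1].time_s if i + 1 < len(u_steps) else rot.time_s
        steps.append((u, u.time_s, nxt))
    defining = {"N_L": pgm, "N_P": d, "NS_P": s, "S_E": rot, "ROX": ama}
    return StateSpans(spans, steps, defining)


def mark_state_windows(
    trace: RespirometryTrace, policy: WindowPolicy | None = None
) -> list[SuitState]:
    """Mark one analysis window per SUIT-028 state.

    For the stepwise uncoupler titration the NS_E window is the step with
    maximal flux (see :func:`uncoupler_optimum`).
    """
    policy = policy or WindowPolicy()
    sp = state_spans(trace)

    def span_window(state, t0, t1, e0, *, end_is_event=True):
        w = _window_in_span(trace, t0, t1, policy, end_is_event=end_is_event)
        if w is None:
            raise ValueError(f"{state} unmarkable: no clean segment of >= "
                             f"{policy.min_window_s:.0f} s in its plateau")
        return SuitState(state, w[0], w[1], e0)

    states = []
    for label in ("N_L", "N_P", "NS_P"):
        t0, t1, eie = sp.spans[label]
        states.append(span_window(label, t0, t1, sp.defining[label], end_is_event=eie))

    step_fluxes = [
        compute_state_flux(trace, (t0, t1), policy).j_v for _, t0, t1 in sp.u_steps
    ]
    opt = uncoupler_optimum(step_fluxes)
    u_ev, t0, t1 = sp.u_steps[opt.step_index - 1]
    states.append(span_window("NS_E", t0, t1, u_ev))

    for label in ("S_E", "ROX"):
        t0, t1, eie = sp.spans[label]
        states.append(span_window(label, t0, t1, sp.defining[label], end_is_event=eie))
    return states


def cytochrome_c_windows(
    trace: RespirometryTrace, policy: WindowPolicy | None = None
) -> tuple[SuitState, SuitState]:
    """Windows before/after the cytochrome c addition (N_P plateau vs c plateau)."""
    policy = policy or WindowPolicy()
    d = _last_event(trace.events, "D")
    c = _last_event(trace.events, "c")
    s = _last_event(trace.events, "S")
    if d is None or c is None or s is None:
        raise ValueError("cytochrome c test needs D, c and S events")
    before = _window_in_span(trace, d.time_s, c.time_s, policy)
    after = _window_in_span(trace, c.time_s, s.time_s, policy)
    if before is None or after is None:
        raise ValueError("cytochrome c test: no clean window around the c event")
    return (
        SuitState("N_P", *before, defining_event=d),
        SuitState("N_P_c", *after, defining_event=c),
    )


class UncouplerOptimum(NamedTuple):
    step_index: int       # 1-based titration step
    flux: float
    under_titration: bool  # optimum at the last step: flux may still rise


def uncoupler_optimum(step_fluxes: Sequence[float]) -> UncouplerOptimum:
    """Select the uncoupler step with maximal flux.

    Ties break toward the lower concentration (earlier step). If the maximum
    sits on the last step the titration may not have reached the true
    optimum, which is flagged as possible under-titration.
    """
    fluxes = np.asarray(step_fluxes, dtype=float)
    if fluxes.size == 0:
        raise ValueError("need at least one uncoupler step")
    i = int(np.argmax(fluxes))
    return UncouplerOptimum(i + 1, float(fluxes[i]), i == fluxes.size - 1 and fluxes.size > 1)


class CytochromeCResult(NamedTuple):
    relative_increase: float
    intact: bool
    threshold: float


def cytochrome_c_test(
    flux_before: float, flux_after: float, threshold_fraction: float = 0.15
) -> CytochromeCResult:
    """Outer-membrane integrity: relative flux increase after cytochrome c."""
    if flux_before <= 0:
        raise ValueError("flux before cytochrome c must be > 0")
    rel = (flux_after - flux_before) / flux_before
    return CytochromeCResult(rel, rel <= threshold_fraction, threshold_fraction)


# ---------------------------------------------------------------------------
# flux tables and control ratios


@dataclass
class FluxTable:
    """Per-state fluxes under the three normalizations.

    ``data`` is indexed by state with columns ``j_v`` (pmol s^-1 mL^-1),
    ``j_mass`` (pmol s^-1 mg^-1), ``j_cs`` (pmol s^-1 IU^-1), the slope
    standard error and the window diagnostics.
    """

    data: pd.DataFrame
    rox_corrected: bool = False
    negative_states: tuple = ()

    COLUMNS = ("j_v", "j_mass", "j_cs", "j_v_se", "window_start", "window_end", "n")

    def __post_init__(self):
        for col in self.COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        self.data = self.data[list(self.COLUMNS)]

    @classmethod
    def from_mass_fluxes(cls, j_mass: dict, *, rox_corrected: bool = False) -> "FluxTable":
        """Build a table directly from mass-specific fluxes (J_V set equal,
        i.e. a unit chamber-volume-per-mass convention)."""
        df = pd.DataFrame(
            {"j_v": list(j_mass.values()), "j_mass": list(j_mass.values())},
            index=list(j_mass.keys()),
        )
        return cls(df, rox_corrected=rox_corrected)

    @property
    def states(self) -> list[str]:
        return list(self.data.index)

    def mass_flux(self, state: str) -> float:
        return float(self.data.loc[state, "j_mass"])

    def to_csv(self, path: str | Path, extra: pd.DataFrame | None = None) -> None:
        out = self.data.copy()
        out.insert(0, "state", out.index)
        out["rox_corrected"] = self.rox_corrected
        out["negative_after_rox"] = [s in self.negative_states for s in out.index]
        if extra is not None:
            out = out.join(extra)
        out.to_csv(path, index=False)


def normalize_fluxes(
    fits: dict,
    *,
    chamber_volume_ml: float,
    sample_mass_mg: float,
    cs_units_iu: float | None = None,
) -> FluxTable:
    """Per-state flux table from volume-specific fits.

    J_mass = J_V * V/m; J_CS = J_V * V/IU (mitochondria-specific flux, using
    the CS units present in the chamber).
    """
    if chamber_volume_ml <= 0 or sample_mass_mg <= 0:
        raise ValueError("chamber volume and sample mass must be > 0")
    if cs_units_iu is not None and cs_units_iu <= 0:
        raise ValueError("CS units in chamber must be > 0")
    rows = {}
    for state, fit in fits.items():
        if isinstance(fit, FluxFit):
            j_v, se, n, window = fit
        else:
            j_v, se, n, window = float(fit), np.nan, np.nan, (np.nan, np.nan)
        rows[state] = {
            "j_v": j_v,
            "j_mass": j_v * chamber_volume_ml / sample_mass_mg,
            "j_cs": j_v * chamber_volume_ml / cs_units_iu if cs_units_iu else np.nan,
            "j_v_se": se,
            "window_start": window[0],
            "window_end": window[1],
            "n": n,
        }
    return FluxTable(pd.DataFrame.from_dict(rows, orient="index"))


def rox_correct(table: FluxTable) -> FluxTable:
    """Subtract the Rox baseline from every state under every normalization.

    The ROX entry becomes exactly 0. States falling below Rox keep their
    negative corrected value but are flagged in ``negative_states``
    (idempotent: correcting twice changes nothing).
    """
    if "ROX" not in table.data.index:
        raise ValueError("flux table has no ROX state; cannot Rox-correct")
    if table.rox_corrected:
        return FluxTable(table.data.copy(), rox_corrected=True,
                         negative_states=table.negative_states)
    df = table.data.copy()
    for col in ("j_v", "j_mass", "j_cs"):
        rox = df.loc["ROX", col]
        if pd.notna(rox):
            df[col] = df[col] - rox
        df.loc["ROX", col] = 0.0 if pd.notna(rox) else np.nan
    negative = tuple(
        s for s in df.index if s != "ROX" and pd.notna(df.loc[s, "j_mass"]) and df.loc[s, "j_mass"] < 0
    )
    return FluxTable(df, rox_corrected=True, negative_states=negative)


@dataclass(frozen=True)
class ControlRatios:
    """Flux control ratios (state / NS_E) and coupling-control efficiencies."""

    fcr: dict
    e_p_efficiency: float
    p_l_efficiency: float


class Efficiencies(NamedTuple):
    e_p: float  # 1 - NS_P/NS_E: phosphorylation-system limitation
    p_l: float  # 1 - N_L/N_P:   coupling tightness


def control_efficiencies(table: FluxTable) -> Efficiencies:
    """E-P = 1 - NS_P/NS_E and P-L = 1 - N_L/N_P on the corrected table.

    0 for E-P means OXPHOS capacity is not limited by the phosphorylation
    system; P-L of 1 indicates a fully coupled system, 0 no coupling.
    """
    for st in ("NS_P", "NS_E", "N_L", "N_P"):
        if st not in table.data.index:
            raise ValueError(f"control efficiencies need state {st}")
    ns_e = table.mass_flux("NS_E")
    n_p = table.mass_flux("N_P")
    if ns_e <= 0:
        raise ValueError("E-P efficiency undefined: NS_E flux must be > 0")
    if n_p <= 0:
        raise ValueError("P-L efficiency undefined: N_P flux must be > 0")
    return Efficiencies(
        e_p=1.0 - table.mass_flux("NS_P") / ns_e,
        p_l=1.0 - table.mass_flux("N_L") / n_p,
    )


def flux_control_ratios(table: FluxTable) -> ControlRatios:
    """FCR(state) = J(state)/J(NS_E); identical under all normalizations."""
    if "NS_E" not in table.data.index:
        raise ValueError("flux control ratios need an NS_E state")
    ns_e = table.mass_flux("NS_E")
    if ns_e <= 0:
        raise ValueError("FCR undefined: NS_E flux must be > 0")
    fcr = {s: table.mass_flux(s) / ns_e for s in table.states}
    eff = control_efficiencies(table)
    return ControlRatios(fcr=fcr, e_p_efficiency=eff.e_p, p_l_efficiency=eff.p_l)


# ---------------------------------------------------------------------------
# one-call pipeline


@dataclass
class RespirometryResult:
    windows: list
    table: FluxTable
    corrected: FluxTable
    ratios: ControlRatios
    uncoupler: UncouplerOptimum
    cytochrome_c: CytochromeCResult | None


def analyze_trace(
    trace: RespirometryTrace,
    *,
    cs_units_iu: float | None = None,
    policy: WindowPolicy | None = None,
    cytc_threshold: float = 0.15,
) -> RespirometryResult:
    """Windows -> fluxes -> normalizations -> Rox correction -> ratios.

    State fluxes are estimated with the fragment-pooled plateau fit
    (:func:`compute_state_flux`), which reduces to the single-window fit when
    plateaus are uninterrupted.
    """
    policy = policy or WindowPolicy()
    windows = mark_state_windows(trace, policy)
    sp = state_spans(trace)
    step_fits = [compute_state_flux(trace, (t0, t1), policy) for _, t0, t1 in sp.u_steps]
    uncoupler = uncoupler_optimum([f.j_v for f in step_fits])
    fits = {
        label: compute_state_flux(trace, span[:2], policy, end_is_event=span[2])
        for label, span in sp.spans.items()
    }
    fits["NS_E"] = step_fits[uncoupler.step_index - 1]
    fits = {w.label: fits[w.label] for w in windows}  # SUIT order
    table = normalize_fluxes(
        fits,
        chamber_volume_ml=trace.chamber_volume_ml,
        sample_mass_mg=trace.sample_mass_mg,
        cs_units_iu=cs_units_iu,
    )
    corrected = rox_correct(table)
    ratios = flux_control_ratios(corrected)

    cytc = None
    if _last_event(trace.events, "c") is not None:
        before_w, after_w = cytochrome_c_windows(trace, policy)
        before = compute_volume_flux(trace, before_w).j_v
        after = compute_volume_flux(trace, after_w).j_v
        cytc = cytochrome_c_test(before, after, cytc_threshold)
    return RespirometryResult(windows, table, corrected, ratios, uncoupler, cytc)
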