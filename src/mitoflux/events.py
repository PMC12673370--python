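"""Titration-event schedules for SUIT respirometry runs.

An event is a timestamped chamber manipulation: a substrate/uncoupler/inhibitor
injection, a sample addition, an H2O2 calibration titration, or a
reoxygenation. Schedules are stored as YAML so a run is fully described by a
trace CSV plus its event file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

#: substances recognised by the SUIT-028 state-marking logic
SUIT_SUBSTANCES = {
    "sample", "P", "M", "G", "D", "c", "S", "U", "Rot", "Ama",
    "H2O2", "reoxygenation",
}


@dataclass(frozen=True)
class Event:
    """A single titration/manipulation event.

    Parameters
    ----------
    time_s : float
        Time of the injection relative to run start.
    substance : str
        One of :data:`SUIT_SUBSTANCES`.
    final_conc : float or None
        Final chamber concentration reached by the titration (None for
        sample addition / reoxygenation).
    units : str or None
        Units of ``final_conc`` (e.g. ``"mM"``, ``"uM"``).
    """

    time_s: float
    substance: str
    final_conc: float | None = None
    units: str | None = None


def events_to_yaml(events: Sequence[Event], path: str | Path) -> None:
    payload = [
        {k: v for k, v in asdict(e).items() if v is not None} for e in events
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def events_from_yaml(path: str | Path) -> list[Event]:
    payload = yaml.safe_load(Path(path).read_text()) or []
    return [Event(**entry) for entry in payload]


def validate_events(events: Iterable[Event]) -> list[Event]:
    """Return events sorted by time; reject non-increasing duplicates."""
    ev = sorted(events, key=lambda e: e.time_s)
    times = [e.time_s for e in ev]
    if len(set(times)) != len(times):
        raise ValueError("event times must be strictly increasing (duplicates found)")
    return ev


@dataclass(frozen=True)
class O2Regime:
    """Operating O2 band of the chamber.

    Reoxygenations (opening the chamber) step the concentration back to
    ``ceiling_um``; the run is kept above ``floor_um``.
    """

    name: str
    ceiling_um: float
    floor_um: float

    def __post_init__(self):
        if not 0 <= self.floor_um < self.ceiling_um:
            raise ValueError("require 0 <= floor < ceiling")


#: near air saturation (effectively hyperoxic for brain tissue)
AIR_REGIME = O2Regime("air", ceiling_um=190.0, floor_um=150.0)
#: intracellular tissue normoxia
NORMOXIC_REGIME = O2Regime("normoxic", ceiling_um=40.0, floor_um=30.0)

REGIMES = {"air": AIR_REGIME, "normoxic": NORMOXIC_REGIME}


def build_suit028_schedule(
    *,
    sample_time_s: float = 240.0,
    plateau_s: float = 300.0,
    uncoupler_plateau_s: float = 180.0,
    n_uncoupler_steps: int = 3,
    cytochrome_c: bool = True,
    pre_sample_titrations: Sequence[float] = (),
    h2o2_titration_interval_s: float | None = None,
) -> list[Event]:
    """Build the canonical SUIT-028 event schedule.

    The chemistry follows the standard brain-homogenate protocol: pyruvate +
    malate + glutamate (N-linked LEAK), saturating ADP (N-linked OXPHOS),
    cytochrome c (outer-membrane integrity check), succinate (NS OXPHOS),
    stepwise CCCP titration to maximum flux (NS ET capacity), rotenone
    (S-linked ET capacity) and antimycin A (residual O2 consumption, Rox).

    Parameters
    ----------
    pre_sample_titrations : sequence of float
        Times (< ``sample_time_s``) of 0.1 uM H2O2 calibration titrations
        performed before the sample is added (chemical background / AmR
        sensitivity calibration).
    h2o2_titration_interval_s : float, optional
        If given, 0.1 uM H2O2 sensitivity-monitoring titrations are inserted
        at this interval throughout the run (placed mid-plateau, away from
        other injections), plus one near the end so the sensitivity knots
        bracket every analysis window.
    """
    ev: list[Event] = []
    for t in pre_sample_titrations:
        if t >= sample_time_s:
            raise ValueError("pre-sample calibration titrations must precede sample addition")
        ev.append(Event(t, "H2O2", 0.1, "uM"))
    ev.append(Event(sample_time_s, "sample"))
    t = sample_time_s + plateau_s
    ev.append(Event(t, "P", 5.0, "mM"))
    ev.append(Event(t + 5.0, "M", 2.0, "mM"))
    ev.append(Event(t + 10.0, "G", 10.0, "mM"))
    t += plateau_s
    ev.append(Event(t, "D", 2.5, "mM"))
    t += plateau_s
    if cytochrome_c:
        ev.append(Event(t, "c", 10.0, "uM"))
        t += plateau_s
    ev.append(Event(t, "S", 50.0, "mM"))
    t += plateau_s
    cccp = np.linspace(1.5, 3.5, max(n_uncoupler_steps, 1))
    for conc in cccp:
        ev.append(Event(t, "U", float(round(conc, 2)), "uM"))
        t += uncoupler_plateau_s
    ev.append(Event(t, "Rot", 0.5, "uM"))
    t += plateau_s
    ev.append(Event(t, "Ama", 2.5, "uM"))
    end = t + plateau_s

    if h2o2_titration_interval_s is not None:
        used = {e.time_s for e in ev}
        tt = sample_time_s + h2o2_titration_interval_s
        times = list(np.arange(tt, end - 150.0, h2o2_titration_interval_s))
        times.append(end - 30.0)  # final knot brackets the ROX window
        for tcal in times:
            # keep titrations well clear of other injections so the local
            # step-height fit sees a single metabolic state
            while any(abs(tcal - u) < 60.0 for u in used):
                tcal += 65.0
            used.add(tcal)
            ev.append(Event(float(tcal), "H2O2", 0.1, "uM"))
    return validate_events(ev)


def run_end_time(events: Sequence[Event], tail_s: float = 300.0) -> float:
    """Default end of the recorded trace: one plateau past the last SUIT
    injection. Trailing H2O2 calibration titrations only extend the end
    slightly (they mark the end of the analysable span)."""
    suit = [e.time_s for e in events if e.substance != "H2O2"]
    end = max(suit) + tail_s if suit else 0.0
    h2o2 = [e.time_s for e in events if e.substance == "H2O2"]
    if h2o2:
        end = max(end, max(h2o2) + 30.0)
    return end
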