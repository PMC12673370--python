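"""The respirometry trace container and its on-disk form.

A trace is what one Oroboros-style chamber run produces: a time base, the O2
concentration signal, optionally an Amplex UltraRed fluorescence signal, the
event schedule, and chamber metadata (volume, wet sample mass). Traces are
written as plain CSV (time_s, o2_uM, fluo_V, state_label) next to a YAML event
schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import Event, events_from_yaml, events_to_yaml, validate_events

#: label used for samples inside the post-injection mixing artifact
TRANSIENT_LABEL = "transient"


@dataclass
class RespirometryTrace:
    time_s: np.ndarray
    o2_um: np.ndarray
    events: list[Event]
    chamber_volume_ml: float
    sample_mass_mg: float
    fluo_v: np.ndarray | None = None
    state_label: np.ndarray | None = None
    #: clean (state, start, end) segments as generated; analysis code must not
    #: rely on this — it re-derives windows from the events
    segments: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_um = np.asarray(self.o2_um, dtype=float)
        if self.time_s.ndim != 1 or self.o2_um.shape != self.time_s.shape:
            raise ValueError("time_s and o2_um must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.chamber_volume_ml <= 0 or self.sample_mass_mg < 0:
            raise ValueError("chamber volume must be positive, sample mass non-negative")
        self.events = validate_events(self.events)
        tmin, tmax = self.time_s[0], self.time_s[-1]
        for e in self.events:
            if not (tmin <= e.time_s <= tmax):
                raise ValueError(f"event {e.substance!r} at t={e.time_s} outside trace span")
        if self.fluo_v is not None:
            self.fluo_v = np.asarray(self.fluo_v, dtype=float)
            if self.fluo_v.shape != self.time_s.shape:
                raise ValueError("fluo_v length mismatch")
        if self.state_label is None:
            self.state_label = np.array([""] * self.time_s.size, dtype=object)

    # -- selection helpers -------------------------------------------------
    def mask_window(self, start: float, end: float, *, exclude_transient: bool = True) -> np.ndarray:
        m = (self.time_s >= start) & (self.time_s <= end)
        if exclude_transient and self.state_label is not None:
            m &= self.state_label != TRANSIENT_LABEL
        return m

    def sample_time(self) -> float | None:
        for e in self.events:
            if e.substance == "sample":
                return e.time_s
        return None

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        fluo = self.fluo_v if self.fluo_v is not None else np.full_like(self.time_s, np.nan)
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "o2_uM": self.o2_um,
                "fluo_V": fluo,
                "state_label": self.state_label,
            }
        )

    def to_csv(self, trace_path: str | Path, events_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(trace_path, index=False)
        if events_path is not None:
            events_to_yaml(self.events, events_path)

    @classmethod
    def from_csv(
        cls,
        trace_path: str | Path,
        events_path: str | Path,
        *,
        chamber_volume_ml: float,
        sample_mass_mg: float,
    ) -> "RespirometryTrace":
        df = pd.read_csv(trace_path)
        fluo = df["fluo_V"].to_numpy() if "fluo_V" in df else None
        if fluo is not None and np.all(np.isnan(fluo)):
            fluo = None
        labels = (
            df["state_label"].fillna("").to_numpy(dtype=object)
            if "state_label" in df
            else None
        )
        return cls(
            time_s=df["time_s"].to_numpy(),
            o2_um=df["o2_uM"].to_numpy(),
            fluo_v=fluo,
            state_label=labels,
            events=events_from_yaml(events_path),
            chamber_volume_ml=chamber_volume_ml,
            sample_mass_mg=sample_mass_mg,
        )
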