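"""Stem-diameter processing: temporal differences, the RSR index and the
threshold-triggered irrigation controller.

The relative stem ratio (RSR) is the current stem diameter divided by the
maximum diameter observed since the last irrigation event (inclusive of the
current sample).  Under water stress the stem shrinks, RSR falls below 1, and
when it drops below a threshold ``t_rsr`` the controller issues an irrigation
event and resets the window so the next RSR is exactly 1.0000.  The controller
is active from sunrise (defined photometrically) until 19:00, evaluated at the
1-minute cadence of the sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd

#: lux -> PPFD conversion divisor for scattered-light photodiode readings.
LUX_PER_PPFD = 54.0

#: PPFD threshold (umol s^-1 m^-2) defining sunrise.
SUNRISE_PPFD = 14.8

#: End of the daily irrigation-control window (half-open: events strictly before).
CONTROL_CUTOFF = time(19, 0)

MINUTE = pd.Timedelta(minutes=1)


def lux_to_ppfd(lux):
    """Convert scattered light in lux to PPFD (umol s^-1 m^-2).

    Uses the fixed divisor of 54 appropriate for sunlight-spectrum scattered
    light measured by a silicon photodiode.
    """
    arr = np.asarray(lux, dtype=float)
    if np.any(arr < 0):
        raise ValueError("lux must be non-negative")
    out = arr / LUX_PER_PPFD
    return float(out) if np.isscalar(lux) or arr.ndim == 0 else out


def detect_sunrise(ppfd: pd.Series, threshold: float = SUNRISE_PPFD):
    """First timestamp at which PPFD reaches ``threshold``; None if never.

    ``ppfd`` is a minute-resolution series for a single day indexed by
    timestamp.
    """
    hit = ppfd[ppfd >= threshold]
    if hit.empty:
        return None
    return hit.index[0]


def delta_stem(stem: pd.Series, w: int = 5) -> pd.Series:
    """Temporal difference delta(t) = stem(t) - stem(t - w minutes).

    Defined only where both samples exist; gaps propagate (no interpolation).
    Works for any minute-grid series, including series with recorded gaps.
    """
    if w < 1:
        raise ValueError("w must be >= 1 minute")
    if len(stem) < w + 1:
        raise ValueError(f"series too short for w={w}: need at least {w + 1} samples")
    shifted = stem.copy()
    shifted.index = shifted.index + w * MINUTE
    delta = (stem - shifted).dropna()
    delta.name = "delta"
    delta.attrs["window_w"] = w
    return delta


def rsr(stem_window) -> float:
    """RSR for a window of diameters since the last irrigation (current last).

    rsr_t = stem_t / max(stem_{t-n}, ..., stem_t); always in (0, 1].
    """
    arr = np.asarray(stem_window, dtype=float)
    if arr.size == 0:
        raise ValueError("empty RSR window")
    if np.any(arr <= 0):
        raise ValueError("stem diameters must be positive")
    return float(arr[-1] / arr.max())


@dataclass
class RsrControllerState:
    """Streaming state of the RSR irrigation rule.

    Tracks the running maximum diameter since the last irrigation (or since
    the last data gap, which conservatively restarts the window).
    """

    t_rsr: float
    running_max: float = field(default=float("nan"))
    elapsed: int = 0

    def step(self, diameter: float, active: bool) -> tuple[float, float, bool]:
        """Advance one minute.

        Returns ``(pre_rsr, post_rsr, event)`` where ``pre_rsr`` is the RSR
        before the threshold check and ``post_rsr`` the value after any reset
        (1.0 exactly at a reset).
        """
        if np.isnan(self.running_max):
            self.running_max = diameter
            self.elapsed = 0
        else:
            self.running_max = max(self.running_max, diameter)
            self.elapsed += 1
        pre = diameter / self.running_max
        if active and pre < self.t_rsr:
            self.running_max = diameter
            self.elapsed = 0
            return pre, 1.0, True
        return pre, pre, False

    def reset(self) -> None:
        self.running_max = float("nan")
        self.elapsed = 0


def run_rsr_controller(
    stem: pd.Series,
    ppfd: pd.Series,
    t_rsr: float,
    cutoff: time = CONTROL_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replay the RSR irrigation rule over a recorded stem trace.

    At each minute within [sunrise, cutoff) the RSR over the window since the
    last irrigation is computed; when it falls below ``t_rsr`` an event is
    emitted and the window resets so the next RSR is 1.0000.  Sunrise is
    detected per day from ``ppfd``.  Gaps in the stem trace restart the window
    without emitting an event.

    Returns ``(irrigation_log, rsr_trace)``: the log has columns
    ``timestamp, volume_ml, pre_rsr``; the trace has index timestamp and
    columns ``rsr`` (post-reset value), ``elapsed_min``, ``event``.
    """
    if not stem.index.equals(ppfd.index):
        raise ValueError("stem and ppfd must share the same timestamp grid")
    if not (0 < t_rsr <= 1):
        raise ValueError("t_rsr must be in (0, 1]")

    sunrise_by_date = {}
    for date, day_ppfd in ppfd.groupby(ppfd.index.date):
        sunrise_by_date[date] = detect_sunrise(day_ppfd)

    state = RsrControllerState(t_rsr=t_rsr)
    rows = []
    events = []
    prev_ts = None
    for ts, diameter in stem.items():
        if prev_ts is not None and ts - prev_ts != MINUTE:
            state.reset()  # gap: conservative window restart
        prev_ts = ts
        sunrise = sunrise_by_date.get(ts.date())
        active = sunrise is not None and sunrise <= ts and ts.time() < cutoff
        pre, post, event = state.step(float(diameter), active)
        rows.append((ts, post, state.elapsed, event))
        if event:
            events.append((ts, 15.0, pre))

    trace = pd.DataFrame(
        rows, columns=["timestamp", "rsr", "elapsed_min", "event"]
    ).set_index("timestamp")
    trace.attrs["threshold_t_rsr"] = t_rsr
    log = pd.DataFrame(events, columns=["timestamp", "volume_ml", "pre_rsr"])
    return log, trace
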