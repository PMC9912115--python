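"""Control-performance metrics: IAE, M2P and D2R.

All three are computed on percent-of-setpoint error over the 1 s grid so
that outputs with very different physical units are comparable:

* IAE — integral (sum x 1 s) of absolute percent error over a window, %*s;
* M2P — maximum percent deviation from setpoint over a window, %;
* D2R — duration to reject: seconds after an event until the output enters
  a +/- band around the setpoint and stays inside for the rest of the
  window (``None`` if it never settles).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["iae", "m2p", "d2r", "compute_metrics", "metrics_from_frames"]


def _window_mask(t: np.ndarray, window) -> np.ndarray:
    t0, t1 = window
    mask = (t >= t0) & (t <= t1)
    if not mask.any():
        raise ValueError(f"window {window} outside the series time range")
    return mask


def iae(t: Sequence[float], y: Sequence[float], sp: Sequence[float],
        window=(300, 1000)) -> float:
    """Integral of absolute percent-of-setpoint error, %*s (trapezoidal
    rule on the 1 s grid)."""
    t = np.asarray(t, float)
    mask = _window_mask(t, window)
    tt = t[mask]
    y, sp = np.asarray(y, float)[mask], np.asarray(sp, float)[mask]
    if np.any(sp == 0):
        raise ValueError("setpoint must be nonzero for percent normalisation")
    return float(np.trapezoid(np.abs(y - sp) / np.abs(sp), tt) * 100.0)


def m2p(t: Sequence[float], y: Sequence[float], sp: Sequence[float],
        window=(300, 1000)) -> float:
    """Maximum percent deviation from setpoint over the window."""
    t = np.asarray(t, float)
    mask = _window_mask(t, window)
    y, sp = np.asarray(y, float)[mask], np.asarray(sp, float)[mask]
    if np.any(sp == 0):
        raise ValueError("setpoint must be nonzero for percent normalisation")
    return float(np.max(np.abs(y - sp) / np.abs(sp)) * 100.0)


def d2r(t: Sequence[float], y: Sequence[float], sp: Sequence[float],
        event_time: float, band: float = 1.0,
        window_end: Optional[float] = None) -> Optional[float]:
    """Settling time in seconds after ``event_time``.

    First time at which the output enters the +/- ``band`` percent envelope
    around the setpoint and remains inside until ``window_end`` (defaults
    to the end of the series).  Returns ``None`` if the output never
    settles (flagged-unsettled sentinel).
    """
    if band <= 0:
        raise ValueError("band must be positive")
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    sp = np.asarray(sp, float)
    end = t[-1] if window_end is None else window_end
    mask = (t >= event_time) & (t <= end)
    if not mask.any():
        raise ValueError("event_time outside the series")
    tt, yy, ss = t[mask], y[mask], sp[mask]
    inside = np.abs(yy - ss) <= band / 100.0 * np.abs(ss)
    # last index at which the trajectory is outside the band
    outside_idx = np.nonzero(~inside)[0]
    if outside_idx.size == 0:
        return 0.0
    first_settled = outside_idx[-1] + 1
    if first_settled >= len(tt):
        return None
    return float(tt[first_settled] - event_time)


def compute_metrics(result, band: float = 1.0, window=(300, 1000)) -> dict:
    """Per-controlled-output IAE / M2P / D2R report for a closed-loop run.

    Metrics are evaluated on the plant's noise-free outputs (the honest
    CQA trajectories) against the setpoint trace stored with the run.  D2R
    is reported per setpoint/disturbance event that falls inside the
    window, keyed by event time.
    """
    return metrics_from_frames(result.truth, result.setpoints,
                               events=result.event_times(),
                               band=band, window=window)


def metrics_from_frames(truth, setpoints, events=None, band: float = 1.0,
                        window=(300, 1000)) -> dict:
    """Same as :func:`compute_metrics` but from the saved CSV frames, so a
    report can be recomputed from disk and must agree with the in-memory
    values (the metrics are pure functions of the stored series)."""
    t = truth["time_s"].to_numpy(float)
    window = (max(window[0], t[0]), min(window[1], t[-1]))
    if window[0] >= window[1]:
        # run shorter than the requested window: report over the full series
        window = (float(t[0]), float(t[-1]))
    report: dict = {"window": list(window), "band_pct": band}
    for name in ("weight", "pcf", "rate", "tensile"):
        y = truth[f"true_{name}"].to_numpy(float)
        sp = setpoints[f"sp_{name}"].to_numpy(float)
        entry = {
            "iae": iae(t, y, sp, window),
            "m2p": m2p(t, y, sp, window),
            "d2r": {},
        }
        for ev in sorted(set(events or [])):
            if window[0] <= ev <= window[1]:
                val = d2r(t, y, sp, ev, band=band, window_end=window[1])
                entry["d2r"][str(int(ev))] = val if val is None else float(val)
        report[name] = entry
    return report
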