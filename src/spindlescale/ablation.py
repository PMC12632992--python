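"""Velocity analysis of spindle-severing (laser ablation) records.

Separation velocities before and after the cut are the OLS slopes of the
distance series inside the windows (-8, 0) s and (4, 12) s (time zero =
ablation; the 0-4 s severing/recoil transient is excluded by
construction). The response is summarised by the velocity jumps
Delta dD_P-P/dt and Delta dD_C-C/dt and the percent change of the pole
elongation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import WindowError

__all__ = [
    "AblationRecord",
    "AblationResponse",
    "BEFORE_WINDOW",
    "AFTER_WINDOW",
    "window_velocity",
    "ablation_response",
]

BEFORE_WINDOW = (-8.0, 0.0)
AFTER_WINDOW = (4.0, 12.0)


@dataclass
class AblationRecord:
    """Distances around one ablation event; times in s with 0 = ablation."""

    times: np.ndarray
    d_pp: np.ndarray
    d_pc: np.ndarray
    d_cc: np.ndarray
    condition: str = "ablated"  # "ablated" | "control"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("d_pp", "d_pc", "d_cc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != self.times.size:
                raise ValueError(f"{name} length must match times")
            setattr(self, name, arr)
        if self.condition not in ("ablated", "control"):
            raise ValueError("condition must be 'ablated' or 'control'")


@dataclass(frozen=True)
class AblationResponse:
    v_pp_before: float
    v_pp_after: float
    v_cc_before: float
    v_cc_after: float

    @property
    def delta_v_pp(self) -> float:
        return self.v_pp_after - self.v_pp_before

    @property
    def delta_v_cc(self) -> float:
        return self.v_cc_after - self.v_cc_before

    @property
    def pole_rate_change_pct(self) -> float:
        """Percent change of the pole elongation rate after the cut."""
        if self.v_pp_before == 0 or not math.isfinite(self.v_pp_before):
            return float("nan")
        return 100.0 * self.delta_v_pp / self.v_pp_before


def window_velocity(times, dists, window) -> float:
    """OLS slope (um/s) of the samples strictly inside (t_lo, t_hi).

    Raises :class:`WindowError` with fewer than 3 finite in-window samples.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(dists, dtype=float)
    t_lo, t_hi = window
    mask = (t > t_lo) & (t < t_hi) & np.isfinite(d)
    if mask.sum() < 3:
        raise WindowError(
            f"only {int(mask.sum())} finite samples inside ({t_lo}, {t_hi}); need >= 3"
        )
    return float(stats.linregress(t[mask], d[mask]).slope)


def ablation_response(
    record: AblationRecord,
    before=BEFORE_WINDOW,
    after=AFTER_WINDOW,
) -> AblationResponse:
    """Windowed before/after velocities for D_P-P and D_C-C.

    Per-quantity window failures propagate as NaN so one bad channel does
    not discard the record.
    """

    def slope(dists, window):
        try:
            return window_velocity(record.times, dists, window)
        except WindowError:
            return float("nan")

    return AblationResponse(
        v_pp_before=slope(record.d_pp, before),
        v_pp_after=slope(record.d_pp, after),
        v_cc_before=slope(record.d_cc, before),
        v_cc_after=slope(record.d_cc, after),
    )
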