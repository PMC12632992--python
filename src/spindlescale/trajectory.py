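"""Per-cell distance time series, time zero at anaphase onset."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time series of pole-to-pole and chromosome-to-chromosome distance.

    ``times`` are seconds relative to anaphase onset and must be strictly
    increasing; distances are micrometres and non-negative (NaN marks a
    flagged frame, e.g. a failed kymograph detection).
    """

    times: np.ndarray
    d_pp: np.ndarray
    d_cc: np.ndarray
    d_pc: Optional[np.ndarray] = None
    cell_id: str = ""
    stage: Optional[int] = None
    lineage: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d_pp = np.asarray(self.d_pp, dtype=float)
        self.d_cc = np.asarray(self.d_cc, dtype=float)
        if self.d_pc is not None:
            self.d_pc = np.asarray(self.d_pc, dtype=float)
        n = self.times.size
        for name in ("d_pp", "d_cc", "d_pc"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ValueError(f"{name} length {arr.size} != times length {n}")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("d_pp", "d_cc", "d_pc"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"{name} contains negative distances")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        """Rows in the shared trajectory CSV schema."""
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "stage": self.stage,
                "lineage": self.lineage,
                "t_s": self.times,
                "d_pp_um": self.d_pp,
                "d_cc_um": self.d_cc,
                "d_pc_um": self.d_pc if self.d_pc is not None else np.nan,
            }
        )
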