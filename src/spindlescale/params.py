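"""Model parameters for spindle elongation in early C. elegans embryos.

Units are micrometres, seconds and piconewtons throughout the package;
drag coefficients are pN s/um.

The default values are the fixed parameter set used at every developmental
stage, together with the per-stage table of cell radius (cube root of the
measured average cell volume), initial pole-to-pole distance at anaphase
onset, and the stage's inferred microtubule catastrophe rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "MTParams",
    "MotorParams",
    "DragParams",
    "ChromosomeLaw",
    "StageConfig",
    "STAGE_TABLE",
    "DEFAULT_MOTORS",
    "DEFAULT_DRAGS",
    "DEFAULT_LAW",
    "default_mt_params",
]


@dataclass(frozen=True)
class MTParams:
    """Microtubule dynamics of one aster.

    Attributes
    ----------
    n_per_aster:
        Number of microtubules nucleated per aster, N_T.
    growth_velocity:
        Polymerisation velocity V_g (um/s).
    catastrophe_rate:
        Rate lambda (1/s) at which a growing microtubule switches to
        disassembly; the mean microtubule length is V_g / lambda.
    """

    n_per_aster: float = 5000.0
    growth_velocity: float = 1.0
    catastrophe_rate: float = 0.038

    def __post_init__(self) -> None:
        if not (self.n_per_aster > 0 and self.growth_velocity > 0 and self.catastrophe_rate > 0):
            raise ValueError("MTParams fields must be strictly positive")

    @property
    def nucleation_rate(self) -> float:
        """Steady-state nucleation rate n_dot = N_T * lambda (1/s)."""
        return self.n_per_aster * self.catastrophe_rate

    def with_catastrophe_rate(self, lam: float) -> "MTParams":
        return replace(self, catastrophe_rate=float(lam))


@dataclass(frozen=True)
class MotorParams:
    """Cortically anchored, minus-end-directed force generators.

    Each motor binds at most one microtubule (stoichiometric binding) and,
    while bound, exerts a force ``force`` on the centrosome along the
    microtubule direction.
    """

    density: float = 0.12        # motors per um^2 of cortex
    size: float = 1.5            # capture radius r (um)
    unbinding_rate: float = 0.05  # kappa (1/s)
    force: float = 5.0           # f0 (pN)

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.size > 0 and self.unbinding_rate > 0 and self.force > 0):
            raise ValueError("MotorParams fields must be strictly positive")

    def count(self, cell_radius: float) -> int:
        """Total motor number M = round(rho * 4 pi R^2); at least one."""
        m = round(self.density * 4.0 * math.pi * cell_radius ** 2)
        return max(int(m), 1)


@dataclass(frozen=True)
class DragParams:
    """Viscous coefficients acting on a spindle pole.

    ``pole_drag`` (eta) is the cytoplasmic drag on a centrosome;
    ``coupling`` (nu) is the viscous element transmitting relative
    pole-chromosome motion along the spindle axis.
    """

    pole_drag: float = 450.0
    coupling: float = 50.0

    def __post_init__(self) -> None:
        if self.pole_drag <= 0:
            raise ValueError("pole_drag (eta) must be > 0")
        if self.coupling < 0:
            raise ValueError("coupling (nu) must be >= 0")


@dataclass(frozen=True)
class ChromosomeLaw:
    """Imposed chromatid separation Delta_c(t) = c_f * (1 - exp(-t / tau)).

    The separation of the two chromosomal plates is nearly invariant with
    cell size, so the model imposes it rather than deriving it from
    mid-spindle mechanics.
    """

    final_separation: float = 6.2  # c_f (um)
    time_constant: float = 29.0    # tau (s)

    def __post_init__(self) -> None:
        if not (self.final_separation > 0 and self.time_constant > 0):
            raise ValueError("ChromosomeLaw fields must be strictly positive")

    def separation(self, t):
        """Separation magnitude at time ``t`` >= 0 after anaphase onset."""
        import numpy as np

        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("separation is defined for t >= 0 only")
        out = self.final_separation * (1.0 - np.exp(-t / self.time_constant))
        return float(out) if out.ndim == 0 else out

    def rate(self, t):
        """Analytic d(Delta_c)/dt at time ``t`` >= 0."""
        import numpy as np

        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("rate is defined for t >= 0 only")
        out = self.final_separation / self.time_constant * np.exp(-t / self.time_constant)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StageConfig:
    """One developmental stage: geometry plus (optionally) the stage's
    catastrophe rate, which may be left unset until inferred."""

    stage: int
    cell_radius: float
    initial_d_pp: float
    catastrophe_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be > 0")
        if not (0 < self.initial_d_pp < 2 * self.cell_radius):
            raise ValueError("initial_d_pp must lie in (0, 2R)")
        if self.catastrophe_rate is not None and self.catastrophe_rate <= 0:
            raise ValueError("catastrophe_rate must be > 0 when set")


# Per-stage configurations: (cell radius, initial pole separation, inferred lambda).
STAGE_TABLE: dict[int, StageConfig] = {
    2: StageConfig(2, 23.0, 13.0, 0.038),
    4: StageConfig(4, 18.0, 11.2, 0.086),
    8: StageConfig(8, 14.0, 9.0, 0.164),
    16: StageConfig(16, 11.0, 7.5, 0.332),
    32: StageConfig(32, 9.0, 6.4, 0.615),
    64: StageConfig(64, 7.3, 5.4, 0.945),
}

DEFAULT_MOTORS = MotorParams()
DEFAULT_DRAGS = DragParams()
DEFAULT_LAW = ChromosomeLaw()


def default_mt_params(catastrophe_rate: float) -> MTParams:
    """Fixed microtubule parameters with the given catastrophe rate."""
    return MTParams(catastrophe_rate=catastrophe_rate)
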