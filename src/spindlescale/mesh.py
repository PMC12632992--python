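"""Spherical surface quadrature for the cortical force integral.

The cortex is discretised with a deterministic near-equal-area lattice
built from the Fibonacci generative spiral. The lower hemisphere is the
exact antipodal image of the upper one, so mirror-symmetric pole
configurations experience exactly mirror-symmetric quadrature; with a raw
spiral the O(1/n) quadrature asymmetry acts like a small spurious force
and slowly drifts the pole pair off centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SurfaceMesh", "build_cell_mesh"]

_MIN_PATCHES = 128


@dataclass(frozen=True)
class SurfaceMesh:
    """Quadrature patches covering a sphere of radius ``radius``."""

    patch_centers: np.ndarray  # (n, 3), um
    patch_areas: np.ndarray    # (n,), um^2
    radius: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.patch_centers, dtype=float)
        areas = np.asarray(self.patch_areas, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 3 or centers.shape[0] != areas.shape[0]:
            raise ValueError("patch_centers must be (n, 3) aligned with patch_areas (n,)")
        if centers.shape[0] < _MIN_PATCHES:
            raise ValueError(f"need at least {_MIN_PATCHES} patches, got {centers.shape[0]}")
        total = 4.0 * math.pi * self.radius ** 2
        if abs(areas.sum() - total) > 5e-3 * total:
            raise ValueError("patch areas do not sum to the sphere area within 0.5%")
        norms = np.linalg.norm(centers, axis=1)
        if not np.allclose(norms, self.radius, rtol=1e-9, atol=0.0):
            raise ValueError("every patch center must lie on the sphere")
        object.__setattr__(self, "patch_centers", centers)
        object.__setattr__(self, "patch_areas", areas)

    @property
    def n_patches(self) -> int:
        return self.patch_centers.shape[0]

    @property
    def area(self) -> float:
        return float(self.patch_areas.sum())


def build_cell_mesh(radius: float, n_patches: int = 2000) -> SurfaceMesh:
    """Antipodally symmetric Fibonacci lattice on a sphere of ``radius``.

    ``n_patches`` is rounded up to an even count. Each patch carries the
    same area 4 pi R^2 / n.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if n_patches < _MIN_PATCHES:
        raise ValueError(
            f"n_patches={n_patches} is too coarse for the cortical force integral "
            f"(minimum {_MIN_PATCHES})"
        )
    n = int(n_patches) + (int(n_patches) % 2)
    half = n // 2
    k = np.arange(half)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - (2.0 * k + 1.0) / n            # upper-hemisphere z ladder
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * k
    upper = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    centers = radius * np.concatenate([upper, -upper[::-1]], axis=0)
    areas = np.full(n, 4.0 * math.pi * radius ** 2 / n)
    return SurfaceMesh(patch_centers=centers, patch_areas=areas, radius=float(radius))
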