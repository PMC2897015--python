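"""Geometric containers: the regular 3D dose lattice and planar structure contours.

Coordinate conventions used throughout the package:

* patient coordinates are in millimetres, dose in cGy;
* the dose array is indexed ``[z, y, x]`` (slice-major);
* voxel indices are 0-based and ``origin`` is the *centre* of voxel
  ``(0, 0, 0)``, so the centre of voxel ``(k, j, i)`` sits at
  ``origin + (i*dx, j*dy, k*dz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "StructureContours"]

MM3_PER_CC = 1000.0


@dataclass(eq=False)
class DoseGrid:
    """A regular 3D lattice of dose values.

    Parameters
    ----------
    origin : array-like of 3 floats
        (x, y, z) of the centre of voxel (0, 0, 0), mm.
    spacing : array-like of 3 floats
        (dx, dy, dz) voxel pitch, mm, strictly positive.
    dose : ndarray, shape (nz, ny, nx)
        Dose values in cGy; finite and non-negative.
    """

    origin: np.ndarray
    spacing: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be length-3 (x, y, z)")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if self.dose.ndim != 3 or min(self.dose.shape) < 1:
            raise ValueError("dose must be a non-degenerate 3D array (nz, ny, nx)")
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose values must be finite")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        """Voxel counts (nx, ny, nz)."""
        nz, ny, nx = self.dose.shape
        return nx, ny, nz

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / MM3_PER_CC

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along ``axis`` (0=x, 1=y, 2=z), mm."""
        n = self.dims[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def slice_positions(self) -> np.ndarray:
        return self.axis_centers(2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DoseGrid):
            return NotImplemented
        return (
            np.array_equal(self.origin, other.origin)
            and np.array_equal(self.spacing, other.spacing)
            and np.array_equal(self.dose, other.dose)
        )


@dataclass(eq=False)
class StructureContours:
    """A named region of interest as closed planar rings per CT slice.

    ``slices`` is a list of ``(z, rings)`` where each ring is an ``(m, 2)``
    array of (x, y) vertices in mm.  Rings are implicitly closed; a
    duplicated last vertex is dropped on construction.  Membership of a
    point follows the even-odd rule over all rings of a slice, so an inner
    ring carves a hole.
    """

    name: str
    slices: list[tuple[float, list[np.ndarray]]]
    role: str = "organ"  # "target" or "organ"; report layout only

    def __post_init__(self) -> None:
        cleaned: list[tuple[float, list[np.ndarray]]] = []
        for z, rings in self.slices:
            norm_rings = []
            for ring in rings:
                r = np.asarray(ring, dtype=float)
                if r.ndim != 2 or r.shape[1] != 2:
                    raise ValueError(f"ring on slice z={z} is not an (m, 2) array")
                if r.shape[0] >= 2 and np.allclose(r[0], r[-1]):
                    r = r[:-1]
                norm_rings.append(r)
            cleaned.append((float(z), norm_rings))
        self.slices = cleaned

    def validate_rings(self) -> None:
        from .errors import DegenerateContourError

        if not self.slices:
            raise DegenerateContourError(f"degenerate contour: {self.name!r} has no slices")
        for z, rings in self.slices:
            if not rings:
                raise DegenerateContourError(
                    f"degenerate contour: {self.name!r} slice z={z} has no rings"
                )
            for ring in rings:
                if ring.shape[0] < 3:
                    raise DegenerateContourError(
                        f"degenerate contour: {self.name!r} slice z={z} has a ring "
                        f"with {ring.shape[0]} vertices (need >= 3)"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureContours):
            return NotImplemented
        if self.name != other.name or self.role != other.role:
            return False
        if len(self.slices) != len(other.slices):
            return False
        for (za, ra), (zb, rb) in zip(self.slices, other.slices):
            if za != zb or len(ra) != len(rb):
                return False
            for a, b in zip(ra, rb):
                if not np.array_equal(a, b):
                    return False
        return True
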