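"""Spatially resolved histograms: per-slice DVHs (zDVH) and dose-surface
histograms (DSH).

A zDVH is a family of differential DVHs, one per CT slice containing member
voxels, all sharing the bin edges of the whole-structure DVH; summing the
entries bin-by-bin recovers the full differential DVH exactly.

The DSH restricts the differential DVH to the structure's surface voxels:
member voxels with at least one of their six face neighbours outside the
mask (or outside the grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dvh import DifferentialDVH, StructureMask, compute_ddvh
from .errors import EmptyStructureError
from .grid import DoseGrid

__all__ = ["ZDVH", "DSH", "compute_zdvh", "compute_dsh", "slice_flags"]


@dataclass(eq=False)
class ZDVH:
    """Per-slice differential DVHs with shared bin edges.

    ``entries`` lists ``(z_mm, DifferentialDVH)`` for every slice holding
    member voxels; slices without members are omitted.
    """

    entries: list[tuple[float, DifferentialDVH]]
    bin_edges: np.ndarray

    def total_ddvh(self) -> DifferentialDVH:
        """Bin-by-bin sum over slices (recovers the whole-structure dDVH)."""
        volumes = np.zeros(self.bin_edges.size - 1)
        for _, d in self.entries:
            volumes += d.bin_volumes
        return DifferentialDVH(bin_edges=self.bin_edges, bin_volumes=volumes)


@dataclass(eq=False)
class DSH:
    """Differential DVH over a structure's boundary voxels."""

    ddvh: DifferentialDVH
    surface_voxel_count: int


def compute_zdvh(grid: DoseGrid, mask: StructureMask,
                 bin_width: float | None = None) -> ZDVH:
    """Per-slice differential DVHs sharing the whole-structure bin edges."""
    full = compute_ddvh(grid, mask, bin_width=bin_width)
    edges = full.bin_edges
    vv = mask.voxel_volume_cc
    entries: list[tuple[float, DifferentialDVH]] = []
    zs = grid.slice_positions
    for k in range(grid.dose.shape[0]):
        sel = mask.member[k]
        if not sel.any():
            continue
        vols, _ = np.histogram(grid.dose[k][sel], bins=edges,
                               weights=mask.frac[k][sel] * vv)
        entries.append((float(zs[k]), DifferentialDVH(bin_edges=edges, bin_volumes=vols)))
    return ZDVH(entries=entries, bin_edges=edges)


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def compute_dsh(grid: DoseGrid, mask: StructureMask,
                bin_width: float | None = None) -> DSH:
    """Dose-surface histogram over 6-connectivity boundary voxels.

    The surface is the mask minus its one-voxel erosion (grid border counts
    as outside, so voxels on the grid edge are surface voxels).
    """
    member = mask.member
    if not member.any():
        raise EmptyStructureError("empty structure: mask has no member voxels")
    eroded = ndimage.binary_erosion(member, structure=_FACE_STRUCTURE, border_value=0)
    surface = member & ~eroded
    surf_mask = StructureMask(grid=grid, frac=np.where(surface, mask.frac, 0.0))
    # share bin edges with the full-structure DVH for comparability
    full = compute_ddvh(grid, mask, bin_width=bin_width)
    ddvh = compute_ddvh(grid, surf_mask, bin_edges=full.bin_edges)
    return DSH(ddvh=ddvh, surface_voxel_count=int(surface.sum()))


def slice_flags(grid: DoseGrid, mask: StructureMask, pd: float,
                hot_factor: float = 1.05, cold_factor: float = 0.95
                ) -> list[tuple[float, bool, bool]]:
    """Flag each populated slice as hot and/or cold.

    A slice is *hot* when its maximum member dose exceeds ``hot_factor*pd``
    and *cold* when its minimum member dose falls below ``cold_factor*pd``
    (reporting convenience; the factors are conventional, not clinical
    recommendations).
    """
    out: list[tuple[float, bool, bool]] = []
    zs = grid.slice_positions
    for k in range(grid.dose.shape[0]):
        sel = mask.member[k]
        if not sel.any():
            continue
        d = grid.dose[k][sel]
        out.append((float(zs[k]), bool(d.max() > hot_factor * pd),
                    bool(d.min() < cold_factor * pd)))
    return out
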