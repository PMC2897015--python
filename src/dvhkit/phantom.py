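"""Seeded phantom plan bundles with closed-form DVHs.

The phantoms emulate the geometry of a conformal plan — a spherical or box
target centred in the grid, optionally an organ-at-risk shell or offset
sphere around it — and three dose models:

``uniform``
    plateau ``D0`` on every voxel whose centre lies inside the target
    contours, zero elsewhere (membership-consistent with the rasterizer,
    so the plan is exactly "ideal");
``linear_falloff``
    radial plateau-plus-ramp, ``D(r) = D0`` for ``r <= R`` and
    ``D(r) = D0 * max(0, 1 - (r - R)/L)`` beyond, the classic penumbra
    approximation with falloff length ``L``;
``two_level``
    ``D0`` inside the target radius, ``low_dose`` in the shell between
    target and OAR outer radius, zero outside.

Circular contours are emitted as 64-gon approximations per slice; the
rasterization oracle therefore sees the same polygons, while the
closed-form curves use ideal spheres (the in-plane polygon area deficit is
a constant factor and cancels in volume-normalized comparisons).
Noise, when requested, is additive Gaussian on the dose grid (clipped at
0 cGy), driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvh import rasterize_structure
from .errors import NoClosedFormError
from .grid import MM3_PER_CC, DoseGrid, StructureContours
from .plan_io import PlanBundle, PlanRecord

__all__ = [
    "PhantomSpec",
    "AnalyticCumulativeDVH",
    "make_phantom_plan",
    "analytic_cdvh",
    "preset_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic plan bundle.

    Defaults model a head-and-neck-scale boost target: a 20 mm-radius
    sphere on a 1 mm lattice with a 10 mm dose falloff and a prescription
    of 3900 cGy.
    """

    dims: tuple[int, int, int] = (68, 68, 68)  # nx, ny, nz
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    target_shape: str = "sphere"  # "sphere" | "box"
    target_radius: float = 20.0  # mm; box half-width for "box"
    oar_shape: str | None = "shell"  # "shell" | "sphere" | None
    oar_outer_radius: float = 30.0  # shell outer radius / OAR sphere radius, mm
    oar_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dose_model: str = "linear_falloff"  # "uniform" | "linear_falloff" | "two_level"
    d0: float = 3900.0  # plateau dose, cGy
    falloff_length: float = 10.0  # L, mm
    low_dose: float = 1950.0  # shell dose for "two_level", cGy
    pd: float = 3900.0  # prescription dose, cGy
    noise_sd: float = 0.0  # additive Gaussian sd, cGy
    seed: int = 42
    n_vertices: int = 64  # polygon vertices per circular ring

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.pd <= 0:
            raise ValueError("D0 and PD must be positive")
        if self.dose_model == "linear_falloff" and self.falloff_length <= 0:
            raise ValueError("falloff length L must be positive")
        if self.target_shape not in ("sphere", "box"):
            raise ValueError(f"unknown target shape {self.target_shape!r}")
        if self.dose_model not in ("uniform", "linear_falloff", "two_level"):
            raise ValueError(f"unknown dose model {self.dose_model!r}")
        half_extent = min(
            (n - 1) / 2 * s for n, s in zip(self.dims, self.spacing)
        )
        reach = self.target_radius
        if self.oar_shape is not None:
            reach = max(reach, self.oar_outer_radius + max(np.abs(self.oar_offset)))
        if self.dose_model == "linear_falloff":
            reach = max(reach, self.target_radius + self.falloff_length)
        if reach > half_extent:
            raise ValueError(
                f"geometry (reach {reach} mm) exceeds grid half-extent {half_extent} mm"
            )

    # -- derived geometry --------------------------------------------------
    @property
    def center(self) -> np.ndarray:
        """Grid centre in patient mm (origin fixed at 0,0,0)."""
        return np.array(
            [(n - 1) / 2 * s for n, s in zip(self.dims, self.spacing)]
        )


def _circle_ring(cx: float, cy: float, r: float, n: int) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _sphere_contours(center: np.ndarray, radius: float, zs: np.ndarray,
                     n_vertices: int) -> list[tuple[float, list[np.ndarray]]]:
    slices = []
    for z in zs:
        h2 = radius**2 - (z - center[2]) ** 2
        if h2 <= 0:
            continue
        slices.append((float(z), [_circle_ring(center[0], center[1], np.sqrt(h2), n_vertices)]))
    return slices


def _box_contours(center: np.ndarray, half: float, zs: np.ndarray
                  ) -> list[tuple[float, list[np.ndarray]]]:
    ring = np.array([
        [center[0] - half, center[1] - half],
        [center[0] + half, center[1] - half],
        [center[0] + half, center[1] + half],
        [center[0] - half, center[1] + half],
    ])
    return [(float(z), [ring.copy()]) for z in zs if abs(z - center[2]) <= half]


def _build_structures(spec: PhantomSpec, zs: np.ndarray) -> list[StructureContours]:
    c = spec.center
    if spec.target_shape == "sphere":
        target = StructureContours(
            "PTV", _sphere_contours(c, spec.target_radius, zs, spec.n_vertices), role="target"
        )
    else:
        target = StructureContours(
            "PTV", _box_contours(c, spec.target_radius, zs), role="target"
        )
    structures = [target]
    if spec.oar_shape == "shell":
        # outer ring plus, where the target exists, an inner ring carving the hole
        slices: list[tuple[float, list[np.ndarray]]] = []
        for z in zs:
            ho2 = spec.oar_outer_radius**2 - (z - c[2]) ** 2
            if ho2 <= 0:
                continue
            rings = [_circle_ring(c[0], c[1], np.sqrt(ho2), spec.n_vertices)]
            hi2 = spec.target_radius**2 - (z - c[2]) ** 2
            if hi2 > 0:
                rings.append(_circle_ring(c[0], c[1], np.sqrt(hi2), spec.n_vertices))
            slices.append((float(z), rings))
        structures.append(StructureContours("OAR", slices, role="organ"))
    elif spec.oar_shape == "sphere":
        oc = c + np.asarray(spec.oar_offset)
        structures.append(
            StructureContours(
                "OAR", _sphere_contours(oc, spec.oar_outer_radius, zs, spec.n_vertices),
                role="organ",
            )
        )
    return structures


def make_phantom_plan(spec: PhantomSpec) -> PlanBundle:
    """Build the phantom bundle: one plan, a PTV and (usually) an OAR.

    Deterministic for a given spec — identical seeds give byte-identical
    bundles once written.
    """
    nx, ny, nz = spec.dims
    origin = np.zeros(3)
    spacing = np.asarray(spec.spacing, dtype=float)
    zs = origin[2] + spacing[2] * np.arange(nz)
    structures = _build_structures(spec, zs)

    c = spec.center
    x = origin[0] + spacing[0] * np.arange(nx)
    y = origin[1] + spacing[1] * np.arange(ny)
    gz, gy, gx = np.meshgrid(zs, y, x, indexing="ij")
    r = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2)

    if spec.dose_model == "uniform":
        # membership-consistent plateau: dose follows the rasterized contours
        probe = DoseGrid(origin=origin, spacing=spacing, dose=np.zeros((nz, ny, nx)))
        mask = rasterize_structure(structures[0], probe, supersample=1)
        dose = spec.d0 * mask.member.astype(float)
    elif spec.dose_model == "linear_falloff":
        dose = spec.d0 * np.clip(
            1.0 - (r - spec.target_radius) / spec.falloff_length, 0.0, 1.0
        )
    else:  # two_level
        dose = np.zeros_like(r)
        dose[r <= spec.target_radius] = spec.d0
        shell = (r > spec.target_radius) & (r <= spec.oar_outer_radius)
        dose[shell] = spec.low_dose

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dose = np.clip(dose + rng.normal(0.0, spec.noise_sd, size=dose.shape), 0.0, None)

    grid = DoseGrid(origin=origin, spacing=spacing, dose=dose)
    plan = PlanRecord(plan_id="PTV1", prescription_dose=spec.pd)
    return PlanBundle(plans=[plan], structures=structures, grids={"PTV1": grid})


# ---------------------------------------------------------------------------
# Closed-form cumulative curves
# ---------------------------------------------------------------------------

class AnalyticCumulativeDVH:
    """Exact cumulative curve: callables for V(>= D) and its inverse."""

    def __init__(self, volume_fn, inverse_fn, total_volume_cc: float,
                 max_dose: float):
        self._volume_fn = volume_fn
        self._inverse_fn = inverse_fn
        self.total_volume_cc = float(total_volume_cc)
        self.max_dose = float(max_dose)

    def volume_at_dose(self, dose):
        return self._volume_fn(np.asarray(dose, dtype=float))

    def dose_at_volume(self, volume_cc: float) -> float:
        if volume_cc > self.total_volume_cc * (1 + 1e-12):
            raise ValueError("requested volume exceeds curve total")
        return float(self._inverse_fn(volume_cc))


def _sphere_vol_cc(radius_mm: float) -> float:
    return (4.0 / 3.0) * np.pi * radius_mm**3 / MM3_PER_CC


def _step_curve(level: float, total_cc: float) -> AnalyticCumulativeDVH:
    def vol(d):
        return np.where(d <= level, total_cc, 0.0)

    def inv(v):
        return level if v > 0 else level

    return AnalyticCumulativeDVH(vol, inv, total_cc, level)


def analytic_cdvh(spec: PhantomSpec, structure: str) -> AnalyticCumulativeDVH:
    """Closed-form cumulative DVH for supported noise-free phantoms.

    Supported: any uniform/two-level structure (step curves) and the
    linear-falloff model for the target sphere (step at D0) and the
    concentric OAR shell, where

        V(>= D) = 4/3 pi [ (R + L (1 - D/D0))^3 - R^3 ],  0 < D <= D0,

    clipped to the shell's outer radius.
    """
    if spec.noise_sd > 0:
        raise NoClosedFormError("no closed form: noisy phantom")
    R = spec.target_radius
    if structure == "PTV":
        if spec.target_shape == "sphere":
            total = _sphere_vol_cc(R)
        else:
            total = (2 * R) ** 3 / MM3_PER_CC
        if spec.dose_model in ("uniform", "linear_falloff", "two_level"):
            return _step_curve(spec.d0, total)  # plateau covers the whole target
        raise NoClosedFormError(f"no closed form: model {spec.dose_model!r}")
    if structure == "OAR" and spec.oar_shape == "shell" and spec.target_shape == "sphere":
        Ro = spec.oar_outer_radius
        total = _sphere_vol_cc(Ro) - _sphere_vol_cc(R)
        if spec.dose_model == "two_level":
            return _step_curve(spec.low_dose, total)
        if spec.dose_model == "uniform":
            # zero dose everywhere in the shell: all volume at D = 0
            return _step_curve(0.0, total)
        if spec.dose_model == "linear_falloff":
            L, d0 = spec.falloff_length, spec.d0

            def vol(d):
                d = np.clip(np.asarray(d, dtype=float), 0.0, None)
                r_star = np.clip(R + L * (1.0 - d / d0), R, Ro)
                out = _vec_sphere_vol(r_star) - _sphere_vol_cc(R)
                return np.where(d > d0, 0.0, out)

            def inv(v):
                if v <= 0:
                    return d0
                r3 = v * MM3_PER_CC * 3.0 / (4.0 * np.pi) + R**3
                r_star = min(r3 ** (1.0 / 3.0), Ro)
                return d0 * (1.0 - (r_star - R) / L)

            return AnalyticCumulativeDVH(vol, inv, total, d0)
    raise NoClosedFormError(
        f"no closed form: structure {structure!r} with model {spec.dose_model!r}"
    )


def _vec_sphere_vol(radius_mm):
    return (4.0 / 3.0) * np.pi * np.asarray(radius_mm) ** 3 / MM3_PER_CC


def preset_spec(preset: str, seed: int = 42, noise_sd: float = 0.0) -> PhantomSpec:
    """Named phantom presets for the CLI and tests."""
    if preset == "sphere":
        return PhantomSpec(seed=seed, noise_sd=noise_sd)
    if preset == "box":
        return PhantomSpec(target_shape="box", dose_model="uniform", oar_shape=None,
                           seed=seed, noise_sd=noise_sd)
    if preset == "shell":
        return PhantomSpec(dose_model="two_level", seed=seed, noise_sd=noise_sd)
    raise ValueError(f"unknown preset {preset!r}")
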