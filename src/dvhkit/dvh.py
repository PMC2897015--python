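"""Core DVH machinery: rasterization, differential/cumulative histograms,
statistics extraction, windowed polynomial smoothing, and curve-comparison
metrics (NRMSD, DTA).

Binning convention
------------------
Differential DVH bins are *centre-aligned*: bin ``k`` covers
``[k*w - w/2, k*w + w/2)`` and is represented by the dose ``k*w``.  A voxel
population at a dose that is an exact multiple of the bin width therefore
lands on a bin centre, and the cumulative curve evaluated at that dose
returns the full volume, with no half-bin offset.  The default bin width is
``max(grid dose)/500``, which yields a 501-point cumulative curve spanning
[0, max dose].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import shapely
from scipy.optimize import brentq

from .errors import (
    CurveTooShortError,
    DegenerateContourError,
    EmptyStructureError,
    StructureOutsideGridError,
)
from .grid import DoseGrid, StructureContours

__all__ = [
    "StructureMask",
    "DifferentialDVH",
    "CumulativeDVH",
    "DVHStatistics",
    "SmoothedCDVH",
    "rasterize_structure",
    "compute_ddvh",
    "cumulate",
    "dvh_statistics",
    "smooth_cdvh",
    "nrmsd",
    "dta",
]

DEFAULT_N_POINTS = 501


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class StructureMask:
    """Voxel membership of a structure on a dose grid.

    ``frac`` holds the fractional membership of every voxel in [0, 1]
    (pure 0/1 when rasterized with ``supersample=1``).  Volume bookkeeping
    uses the fractional values, so partial voxels contribute partial volume.
    """

    grid: DoseGrid
    frac: np.ndarray

    @property
    def member(self) -> np.ndarray:
        """Boolean membership (any positive fraction)."""
        return self.frac > 0

    @property
    def voxel_volume_cc(self) -> float:
        return self.grid.voxel_volume_cc

    @property
    def volume_cc(self) -> float:
        return float(self.frac.sum()) * self.voxel_volume_cc


def _slice_index(grid: DoseGrid, z: float) -> int | None:
    """Map a contour z to the nearest grid slice, or None when outside."""
    dz = grid.spacing[2]
    k = int(round((z - grid.origin[2]) / dz))
    nz = grid.dose.shape[0]
    if k < 0 or k >= nz:
        return None
    if abs(z - (grid.origin[2] + k * dz)) > dz / 2 + 1e-9:
        return None
    return k


def rasterize_structure(
    contours: StructureContours, grid: DoseGrid, supersample: int = 1
) -> StructureMask:
    """Rasterize planar contours to a (fractional) voxel mask.

    A voxel belongs to the structure when its sample point lies inside the
    slice's rings under the even-odd rule (points on a ring boundary count
    inside).  With ``supersample=k`` each voxel is probed at a k x k
    stratified grid of in-plane sub-centres and its membership fraction is
    the inside fraction; contours are planar per slice, so sub-sampling
    along z would re-probe the same polygon and is not performed.
    """
    if supersample not in (1, 2, 3, 4):
        raise ValueError("supersample must be 1, 2, 3 or 4")
    contours.validate_rings()

    nz, ny, nx = grid.dose.shape
    frac = np.zeros((nz, ny, nx))
    per_slice: dict[int, list[np.ndarray]] = {}
    for z, rings in contours.slices:
        k = _slice_index(grid, z)
        if k is None:
            continue
        per_slice.setdefault(k, []).extend(rings)
    if not per_slice:
        raise StructureOutsideGridError(
            f"structure outside grid: {contours.name!r} overlaps no dose-grid slice"
        )

    dx, dy = grid.spacing[0], grid.spacing[1]
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5  # stratified sub-centres, voxel units

    for k, rings in per_slice.items():
        polys = [shapely.Polygon(r) for r in rings]
        rx_min = min(r[:, 0].min() for r in rings) - dx
        rx_max = max(r[:, 0].max() for r in rings) + dx
        ry_min = min(r[:, 1].min() for r in rings) - dy
        ry_max = max(r[:, 1].max() for r in rings) + dy
        i_sel = np.nonzero((xs >= rx_min) & (xs <= rx_max))[0]
        j_sel = np.nonzero((ys >= ry_min) & (ys <= ry_max))[0]
        if i_sel.size == 0 or j_sel.size == 0:
            continue
        # sample coordinates: (nj, ni, s, s)
        px = xs[i_sel][None, :, None, None] + (offs * dx)[None, None, None, :]
        py = ys[j_sel][:, None, None, None] + (offs * dy)[None, None, :, None]
        px, py = np.broadcast_arrays(px, py)
        crossings = np.zeros(px.shape, dtype=int)
        for poly in polys:
            # intersects == inside-or-on-boundary for a point vs polygon
            crossings += shapely.intersects_xy(poly, px, py)
        inside = (crossings % 2) == 1
        frac[np.ix_([k], j_sel, i_sel)] += inside.mean(axis=(2, 3))[None, :, :]

    np.clip(frac, 0.0, 1.0, out=frac)
    return StructureMask(grid=grid, frac=frac)


# ---------------------------------------------------------------------------
# Differential DVH
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class DifferentialDVH:
    """Binned volume-vs-dose distribution.

    ``bin_edges`` are uniform and centre-aligned (see module docstring);
    ``bin_volumes`` are in cc and sum to the structure volume.
    """

    bin_edges: np.ndarray
    bin_volumes: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_volumes = np.asarray(self.bin_volumes, dtype=float)
        if self.bin_edges.size != self.bin_volumes.size + 1:
            raise ValueError("need len(bin_edges) == len(bin_volumes) + 1")
        if np.any(self.bin_volumes < 0):
            raise ValueError("bin volumes must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_volume_cc(self) -> float:
        return float(self.bin_volumes.sum())

    @property
    def mean_dose(self) -> float:
        """First moment of the distribution (bin-centre weighted)."""
        return float(np.average(self.bin_centers, weights=self.bin_volumes))

    def min_dose(self) -> float:
        """Centre of the lowest occupied bin (half-bin-width resolution)."""
        nz = np.nonzero(self.bin_volumes)[0]
        return float(self.bin_centers[nz[0]])

    def max_dose(self) -> float:
        nz = np.nonzero(self.bin_volumes)[0]
        return float(self.bin_centers[nz[-1]])


def _centered_edges(max_dose: float, bin_width: float) -> np.ndarray:
    """Centre-aligned bin edges covering [0, max_dose]."""
    n_bins = max(int(np.floor(max_dose / bin_width + 0.5)) + 1, 2)
    return (np.arange(n_bins + 1) - 0.5) * bin_width


def compute_ddvh(
    grid: DoseGrid,
    mask: StructureMask,
    bin_width: float | None = None,
    bin_edges: np.ndarray | None = None,
) -> DifferentialDVH:
    """Differential DVH of ``mask`` on ``grid``.

    Each member voxel deposits its (possibly fractional) volume into the
    bin containing its dose.  By default the bin width is the grid maximum
    dose divided by 500 so the cumulative curve has 501 points.
    """
    member = mask.member
    if not member.any():
        raise EmptyStructureError("empty structure: mask has no member voxels")
    doses = grid.dose[member]
    weights = mask.frac[member] * mask.voxel_volume_cc
    if bin_edges is None:
        if bin_width is None:
            grid_max = float(grid.dose.max())
            bin_width = grid_max / (DEFAULT_N_POINTS - 1) if grid_max > 0 else 1.0
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        bin_edges = _centered_edges(float(doses.max()), bin_width)
    volumes, _ = np.histogram(doses, bins=bin_edges, weights=weights)
    return DifferentialDVH(bin_edges=bin_edges, bin_volumes=volumes)


# ---------------------------------------------------------------------------
# Cumulative DVH
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class CumulativeDVH:
    """Volume receiving at least a given dose, sampled on ascending dose points.

    Between samples the curve is piecewise linear; below the first point it
    equals the total volume and beyond the last point it is zero.
    """

    dose_points: np.ndarray
    volume_cc: np.ndarray

    def __post_init__(self) -> None:
        self.dose_points = np.asarray(self.dose_points, dtype=float)
        self.volume_cc = np.asarray(self.volume_cc, dtype=float)
        if self.dose_points.size != self.volume_cc.size:
            raise ValueError("dose_points and volume_cc must align")
        if self.dose_points.size < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(self.dose_points) <= 0):
            raise ValueError("dose_points must be strictly ascending")
        if np.any(np.diff(self.volume_cc) > 1e-9 * max(self.volume_cc[0], 1.0)):
            raise ValueError("cumulative volumes must be non-increasing")

    @property
    def total_volume_cc(self) -> float:
        return float(self.volume_cc[0])

    @property
    def volume_pct(self) -> np.ndarray:
        return 100.0 * self.volume_cc / self.total_volume_cc

    def volume_at_dose(self, dose):
        """V(>= dose) in cc (linear between samples, total below, 0 beyond)."""
        return np.interp(dose, self.dose_points, self.volume_cc,
                         left=self.total_volume_cc, right=0.0)

    def dose_at_volume(self, volume_cc: float) -> float:
        """Largest dose receiving at least ``volume_cc`` (inverse lookup).

        On flat segments the highest dose of the plateau is returned.
        Raises ValueError when the requested volume exceeds the total.
        """
        v = self.volume_cc
        if volume_cc > self.total_volume_cc * (1 + 1e-12):
            raise ValueError(
                f"volume {volume_cc} cc exceeds curve total {self.total_volume_cc} cc"
            )
        at_least = np.nonzero(v >= volume_cc)[0]
        if at_least.size == 0:  # only possible through rounding at the total
            return float(self.dose_points[0])
        i = int(at_least[-1])
        if i == v.size - 1:
            return float(self.dose_points[-1])
        v0, v1 = v[i], v[i + 1]
        d0, d1 = self.dose_points[i], self.dose_points[i + 1]
        if v0 == v1:
            return float(d0)
        return float(d0 + (d1 - d0) * (v0 - volume_cc) / (v0 - v1))

    def max_support_dose(self) -> float:
        """Highest dose point with positive volume."""
        nz = np.nonzero(self.volume_cc > 0)[0]
        if nz.size == 0:
            return float(self.dose_points[0])
        return float(self.dose_points[nz[-1]])


def cumulate(ddvh: DifferentialDVH) -> CumulativeDVH:
    """Cumulative DVH: V(d) = sum of bin volumes at bin dose >= d.

    Dose points are the (centre-aligned) bin doses, which under the default
    bin width gives 501 evenly spaced points spanning [0, max dose].
    """
    centers = ddvh.bin_centers
    suffix = np.cumsum(ddvh.bin_volumes[::-1])[::-1]
    return CumulativeDVH(dose_points=centers, volume_cc=suffix)


# ---------------------------------------------------------------------------
# Smoothing: cosine midpoint + windowed least-squares polynomials
# ---------------------------------------------------------------------------

_COSINE_WEIGHT = 0.5
_DEGREES = (2, 3, 4, 5)


class SmoothedCDVH:
    """Piecewise-polynomial model of a cumulative DVH.

    For each inter-sample interval a virtual midpoint is synthesized by
    cosine interpolation with weight 0.5 — the blend fraction
    ``(1 - cos(pi * 0.5)) / 2 = 0.5`` — and a least-squares polynomial is
    fit through that midpoint plus the six nearest samples (the contiguous
    run centred on the interval).  The polynomial degree (2–5) is chosen
    per window by minimal leave-one-out RMSE, ties to the lowest degree.
    Evaluation returns the running-minimum envelope of the window
    polynomial clipped to the bracketing sample values, which keeps the
    modelled curve monotone non-increasing everywhere; at a sample dose
    the sample value itself is returned.
    """

    def __init__(self, cdvh: CumulativeDVH):
        if cdvh.dose_points.size < 7:
            raise CurveTooShortError(
                f"curve too short: {cdvh.dose_points.size} points (need >= 7)"
            )
        self._x = cdvh.dose_points
        self._y = cdvh.volume_cc
        self.total_volume_cc = cdvh.total_volume_cc
        self.dose_range = (float(self._x[0]), float(self._x[-1]))
        self._windows: dict[int, tuple[np.ndarray, float]] = {}
        self._snap_eps = 1e-9 * max(self._x[-1] - self._x[0], 1.0)

    # -- window fitting ----------------------------------------------------
    def _fit_window(self, j: int) -> tuple[np.ndarray, float]:
        """Cached polynomial for the interval [x_j, x_{j+1})."""
        cached = self._windows.get(j)
        if cached is not None:
            return cached
        x, y = self._x, self._y
        m = x.size
        xm = 0.5 * (x[j] + x[j + 1])
        f = (1.0 - np.cos(np.pi * _COSINE_WEIGHT)) / 2.0  # = 0.5
        ym = (1.0 - f) * y[j] + f * y[j + 1]
        lo = min(max(j - 2, 0), m - 6)
        idx = np.arange(lo, lo + 6)
        xs = np.append(x[idx], xm) - xm  # centre for conditioning
        ys = np.append(y[idx], ym)
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for deg in _DEGREES:
                sq = 0.0
                for leave in range(xs.size):
                    keep = np.arange(xs.size) != leave
                    if keep.sum() <= deg:
                        sq = np.inf
                        break
                    c = np.polynomial.polynomial.polyfit(xs[keep], ys[keep], deg)
                    pred = np.polynomial.polynomial.polyval(xs[leave], c)
                    sq += (pred - ys[leave]) ** 2
                rmse = np.sqrt(sq / xs.size)
                if best is None or rmse < best[0] - 1e-12:
                    coeffs = np.polynomial.polynomial.polyfit(xs, ys, deg)
                    best = (rmse, coeffs)
        coeffs = best[1]
        # real critical points of the fitted polynomial, for the monotone
        # (running-minimum) envelope used at evaluation time
        der = np.polynomial.polynomial.polyder(coeffs)
        crit = np.array([], dtype=float)
        if der.size > 1:
            roots = np.polynomial.polynomial.polyroots(der)
            real = roots[np.abs(roots.imag) < 1e-9].real
            lo_t, hi_t = x[j] - xm, x[j + 1] - xm
            crit = np.sort(real[(real > lo_t) & (real < hi_t)])
        result = (coeffs, float(xm), crit)
        self._windows[j] = result
        return result

    # -- evaluation --------------------------------------------------------
    def _eval_scalar(self, d: float) -> float:
        x, y = self._x, self._y
        if d <= x[0]:
            return float(y[0])
        if d >= x[-1]:
            return float(y[-1])
        j = int(np.searchsorted(x, d, side="right") - 1)
        if abs(d - x[j]) <= self._snap_eps:
            return float(y[j])
        if abs(d - x[j + 1]) <= self._snap_eps:
            return float(y[j + 1])
        coeffs, xm, crit = self._fit_window(j)
        t = d - xm
        # running-minimum envelope: min of the polynomial over [x_j, d],
        # i.e. its value at d and at any earlier interior critical point —
        # monotone non-increasing in d by construction
        ts = np.append(crit[crit <= t], t)
        val = float(np.polynomial.polynomial.polyval(ts, coeffs).min())
        # clip to the bracketing samples
        val = min(max(val, float(y[j + 1])), float(y[j]))
        return min(max(val, 0.0), self.total_volume_cc)

    def __call__(self, dose):
        if np.isscalar(dose):
            return self._eval_scalar(float(dose))
        return np.array([self._eval_scalar(float(d)) for d in np.asarray(dose).ravel()])

    # duck-type the curve interface used by nrmsd/dta
    def volume_at_dose(self, dose):
        return self(dose)

    def dose_at_volume(self, volume_cc: float) -> float:
        """Invert the smoothed curve by bracketed root finding."""
        x, y = self._x, self._y
        if volume_cc > self.total_volume_cc * (1 + 1e-12):
            raise ValueError("requested volume exceeds curve total")
        at_least = np.nonzero(y >= volume_cc)[0]
        if at_least.size == 0:
            return float(x[0])
        i = int(at_least[-1])
        if i == y.size - 1:
            return float(x[-1])
        a, b = float(x[i]), float(x[i + 1])
        fa = self._eval_scalar(a) - volume_cc
        fb = self._eval_scalar(b) - volume_cc
        if fa == 0.0:
            return a
        if fb == 0.0:
            return b
        if fa * fb > 0:  # flat window; fall back to the linear curve
            v0, v1 = y[i], y[i + 1]
            if v0 == v1:
                return a
            return float(a + (b - a) * (v0 - volume_cc) / (v0 - v1))
        return float(brentq(lambda d: self._eval_scalar(d) - volume_cc, a, b, xtol=1e-8))


def smooth_cdvh(cdvh: CumulativeDVH) -> SmoothedCDVH:
    """Build the windowed-polynomial model of a cumulative DVH."""
    return SmoothedCDVH(cdvh)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class QueryResult:
    """Answer to one DVH query (see :mod:`dvhkit.plan_io` for the grammar)."""

    query: object
    dose_cgy: float | None = None
    volume_cc: float | None = None
    volume_pct: float | None = None
    clamped: bool = False


@dataclass
class DVHStatistics:
    min_dose: float
    max_dose: float
    mean_dose: float
    median_dose: float
    total_volume_cc: float
    answers: list[QueryResult]


def _dose_at_fraction(cdvh: CumulativeDVH, smoothed: SmoothedCDVH | None,
                      fraction: float) -> float:
    target = fraction * cdvh.total_volume_cc
    if smoothed is not None:
        return smoothed.dose_at_volume(target)
    return cdvh.dose_at_volume(target)


def dvh_statistics(cdvh: CumulativeDVH, ddvh: DifferentialDVH,
                   queries: list | None = None) -> DVHStatistics:
    """Extract summary statistics and answer point-of-interest queries.

    Volume-at-dose queries are read off the cumulative curve; dose-at-volume
    (Dx) queries invert the smoothed curve (falling back to linear inversion
    when the curve is too short to smooth); the mean is the first moment of
    the differential DVH and the median is D50.  Queries outside the curve
    range are clamped and flagged, never silently extrapolated.
    """
    try:
        smoothed: SmoothedCDVH | None = smooth_cdvh(cdvh)
    except CurveTooShortError:
        smoothed = None

    total = cdvh.total_volume_cc
    stats = DVHStatistics(
        min_dose=ddvh.min_dose(),
        max_dose=ddvh.max_dose(),
        mean_dose=ddvh.mean_dose,
        median_dose=_dose_at_fraction(cdvh, smoothed, 0.5),
        total_volume_cc=total,
        answers=[],
    )
    for q in queries or []:
        res = QueryResult(query=q)
        kind = getattr(q, "kind", None)
        if kind in ("volume_at_dose", "coverage_rel"):
            d = q.dose_cgy
            if d is None:
                raise ValueError(f"query {q!r} has no resolved dose threshold")
            if d < cdvh.dose_points[0] or d > cdvh.dose_points[-1]:
                res.clamped = True
                d = min(max(d, cdvh.dose_points[0]), cdvh.dose_points[-1])
            vol = float(cdvh.volume_at_dose(d))
            if getattr(q, "direction", ">") == "<":
                vol = total - vol
            res.volume_cc = vol
            res.volume_pct = 100.0 * vol / total
        elif kind == "dose_at_volume":
            frac = q.volume_pct / 100.0
            if frac > 1.0 or frac < 0.0:
                res.clamped = True
                frac = min(max(frac, 0.0), 1.0)
            res.dose_cgy = _dose_at_fraction(cdvh, smoothed, frac)
        elif kind == "stat":
            res.dose_cgy = {
                "min": stats.min_dose,
                "max": stats.max_dose,
                "mean": stats.mean_dose,
                "median": stats.median_dose,
            }[q.stat]
        else:
            raise ValueError(f"unsupported query kind: {kind!r}")
        stats.answers.append(res)
    return stats


# ---------------------------------------------------------------------------
# Curve-comparison metrics
# ---------------------------------------------------------------------------

def nrmsd(curve_a, curve_b, probe_doses) -> float:
    """Normalized root-mean-square difference between two cumulative curves.

    Both curves are normalized by their own total volume (so curves in cc
    and % compare on equal footing) and the RMS of the pointwise difference
    at the probe doses is reported in percent.  Symmetric in its arguments.
    """
    probes = np.asarray(probe_doses, dtype=float)
    if probes.size == 0:
        raise ValueError("nrmsd requires at least one probe dose")
    fa = np.asarray(curve_a.volume_at_dose(probes), dtype=float) / curve_a.total_volume_cc
    fb = np.asarray(curve_b.volume_at_dose(probes), dtype=float) / curve_b.total_volume_cc
    return float(100.0 * np.sqrt(np.mean((fa - fb) ** 2)))


def dta(curve_a, curve_b, volume_fraction: float = 0.5, pd: float = 1.0) -> float:
    """Distance-to-agreement along the dose axis at a fixed volume fraction.

    Evaluated by default at 50% of each curve's volume and normalized to
    the prescription dose, in percent.
    """
    if not 0.0 < volume_fraction < 1.0:
        raise ValueError("volume_fraction must be in (0, 1)")
    if pd <= 0:
        raise ValueError("pd must be positive")
    da = curve_a.dose_at_volume(volume_fraction * curve_a.total_volume_cc)
    db = curve_b.dose_at_volume(volume_fraction * curve_b.total_volume_cc)
    return float(100.0 * abs(da - db) / pd)
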