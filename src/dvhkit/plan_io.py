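"""Plan-bundle input/output and spreadsheet-style reporting.

Bundle dialect
--------------
A plan bundle is a directory holding:

``bundle.hdr``
    Line-oriented plain-text header.  Blank lines and ``#`` comments are
    ignored.  Records::

        bundlefmt 1
        grid dims <nx> <ny> <nz>
        grid spacing <dx> <dy> <dz>
        grid origin <ox> <oy> <oz>
        plan <plan_id> <pd_cGy> <dose_file>
        composite <plan_id> <dose_file> <component_id> [<component_id> ...]
        structure <name> <contour_file> [target|organ]

    A ``composite`` plan's prescription dose is the sum of its components'.

dose file
    First line ``dims <nx> <ny> <nz>``; then one whitespace-separated row
    of ``nx`` values per line, ``ny`` rows per slice, ``nz`` slices
    (slice-major, x fastest).  Values in cGy, printed with ``%.17g`` so
    round-trips are bit-exact.

contour file
    ::

        structure <name>
        slice <z_mm>
        ring <n_vertices>
        <x_mm> <y_mm>
        ...

    Rings are written open (no repeated last vertex) and are implicitly
    closed.

All coordinates are patient millimetres; the grid origin is the centre of
voxel (0, 0, 0).
"""

from __future__ import annotations

import csv
import io
import math
import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    BundleMalformedError,
    DanglingStructureError,
    GridInconsistentError,
    PoiParseError,
)
from .grid import DoseGrid, StructureContours

__all__ = [
    "PlanRecord",
    "PlanBundle",
    "DVHQuery",
    "read_plan_bundle",
    "write_plan_bundle",
    "read_poi_config",
    "parse_poi_token",
    "write_report",
    "PlanReport",
    "TargetRow",
    "CoverageRow",
    "StatsRow",
    "round_half_up_pct",
]

HEADER_NAME = "bundle.hdr"
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PlanRecord:
    """One treatment plan: an identifier and its prescription dose in cGy.

    ``components`` is non-empty for a composite plan, whose prescription
    dose must equal the sum of its components'.
    """

    plan_id: str
    prescription_dose: float
    components: tuple[str, ...] = ()


@dataclass(eq=False)
class PlanBundle:
    """Plans, structures and per-plan dose grids of one exported case."""

    plans: list[PlanRecord]
    structures: list[StructureContours]
    grids: dict[str, DoseGrid]

    def __post_init__(self) -> None:
        if not self.plans:
            raise ValueError("bundle must contain at least one plan")
        ids = [p.plan_id for p in self.plans]
        if len(set(ids)) != len(ids):
            raise ValueError("plan ids must be unique")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise ValueError("structure names must be unique")
        by_id = {p.plan_id: p for p in self.plans}
        for p in self.plans:
            if p.prescription_dose <= 0:
                raise ValueError(f"plan {p.plan_id!r} has non-positive prescription dose")
            if p.components:
                missing = [c for c in p.components if c not in by_id]
                if missing:
                    raise ValueError(f"composite {p.plan_id!r} references unknown plans {missing}")
                total = sum(by_id[c].prescription_dose for c in p.components)
                if not math.isclose(total, p.prescription_dose, rel_tol=1e-9):
                    raise ValueError(
                        f"composite {p.plan_id!r} prescription {p.prescription_dose} "
                        f"!= sum of components {total}"
                    )
            if p.plan_id not in self.grids:
                raise ValueError(f"plan {p.plan_id!r} has no dose grid")

    def plan(self, plan_id: str) -> PlanRecord:
        for p in self.plans:
            if p.plan_id == plan_id:
                return p
        raise KeyError(plan_id)

    def structure(self, name: str) -> StructureContours:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlanBundle):
            return NotImplemented
        return (
            self.plans == other.plans
            and self.structures == other.structures
            and self.grids == other.grids
        )


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def _dose_filename(plan_id: str) -> str:
    return f"dose_{plan_id}.txt"


def _contour_filename(name: str) -> str:
    safe = re.sub(r"[^A-Za-z0-9_.-]", "_", name)
    return f"roi_{safe}.txt"


def write_plan_bundle(bundle: PlanBundle, path: str | Path) -> None:
    """Write a bundle to ``path`` in the documented dialect (deterministic)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    any_grid = bundle.grids[bundle.plans[0].plan_id]
    nx, ny, nz = any_grid.dims
    lines = ["bundlefmt 1",
             f"grid dims {nx} {ny} {nz}",
             "grid spacing " + " ".join(_FLOAT_FMT % v for v in any_grid.spacing),
             "grid origin " + " ".join(_FLOAT_FMT % v for v in any_grid.origin)]
    for p in bundle.plans:
        if p.components:
            lines.append(
                f"composite {p.plan_id} {_dose_filename(p.plan_id)} " + " ".join(p.components)
            )
        else:
            lines.append(
                f"plan {p.plan_id} {_FLOAT_FMT % p.prescription_dose} {_dose_filename(p.plan_id)}"
            )
    for s in bundle.structures:
        lines.append(f"structure {s.name} {_contour_filename(s.name)} {s.role}")
    (path / HEADER_NAME).write_text("\n".join(lines) + "\n")

    for p in bundle.plans:
        grid = bundle.grids[p.plan_id]
        gx, gy, gz = grid.dims
        buf = io.StringIO()
        buf.write(f"dims {gx} {gy} {gz}\n")
        flat = grid.dose.reshape(gz * gy, gx)
        for row in flat:
            buf.write(" ".join(_FLOAT_FMT % v for v in row))
            buf.write("\n")
        (path / _dose_filename(p.plan_id)).write_text(buf.getvalue())

    for s in bundle.structures:
        buf = io.StringIO()
        buf.write(f"structure {s.name}\n")
        for z, rings in s.slices:
            buf.write(f"slice {_FLOAT_FMT % z}\n")
            for ring in rings:
                buf.write(f"ring {ring.shape[0]}\n")
                for x, y in ring:
                    buf.write(f"{_FLOAT_FMT % x} {_FLOAT_FMT % y}\n")
        (path / _contour_filename(s.name)).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Bundle reader
# ---------------------------------------------------------------------------

def _read_dose_file(path: Path, dims: tuple[int, int, int],
                    origin: np.ndarray, spacing: np.ndarray) -> DoseGrid:
    if not path.is_file():
        raise GridInconsistentError(f"grid inconsistent: missing dose file {path.name}")
    with open(path) as fh:
        first = fh.readline().split()
        if len(first) != 4 or first[0] != "dims":
            raise GridInconsistentError(f"grid inconsistent: bad dims line in {path.name}")
        file_dims = tuple(int(v) for v in first[1:])
        if file_dims != tuple(dims):
            raise GridInconsistentError(
                f"grid inconsistent: {path.name} dims {file_dims} != header dims {tuple(dims)}"
            )
        values = np.array(fh.read().split(), dtype=float)
    nx, ny, nz = dims
    if values.size != nx * ny * nz:
        raise GridInconsistentError(
            f"grid inconsistent: {path.name} holds {values.size} values, "
            f"expected {nx * ny * nz}"
        )
    return DoseGrid(origin=origin, spacing=spacing, dose=values.reshape(nz, ny, nx))


def _read_contour_file(path: Path, name: str, role: str) -> StructureContours:
    if not path.is_file():
        raise DanglingStructureError(f"dangling structure: missing contour file {path.name}")
    slices: list[tuple[float, list[np.ndarray]]] = []
    with open(path) as fh:
        line = fh.readline().split()
        if len(line) != 2 or line[0] != "structure":
            raise DanglingStructureError(f"dangling structure: bad contour header in {path.name}")
        current_rings: list[np.ndarray] | None = None
        for raw in fh:
            tok = raw.split()
            if not tok:
                continue
            if tok[0] == "slice":
                current_rings = []
                slices.append((float(tok[1]), current_rings))
            elif tok[0] == "ring":
                if current_rings is None:
                    raise DanglingStructureError(
                        f"dangling structure: ring before slice in {path.name}"
                    )
                n = int(tok[1])
                pts = np.empty((n, 2))
                for i in range(n):
                    xy = fh.readline().split()
                    pts[i] = (float(xy[0]), float(xy[1]))
                current_rings.append(pts)
            else:
                raise DanglingStructureError(
                    f"dangling structure: unexpected token {tok[0]!r} in {path.name}"
                )
    return StructureContours(name=name, slices=slices, role=role)


def read_plan_bundle(path: str | Path) -> PlanBundle:
    """Read and validate a plan bundle directory."""
    path = Path(path)
    header = path / HEADER_NAME
    if not header.is_file():
        raise BundleMalformedError(f"bundle malformed: missing {HEADER_NAME} in {path}")

    dims = spacing = origin = None
    plan_specs: list[tuple[str, float | None, str, tuple[str, ...]]] = []
    struct_specs: list[tuple[str, str, str]] = []
    for raw in header.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if tok[0] == "bundlefmt":
                if tok[1] != "1":
                    raise BundleMalformedError(f"bundle malformed: unknown format {tok[1]}")
            elif tok[0] == "grid":
                if tok[1] == "dims":
                    dims = tuple(int(v) for v in tok[2:5])
                elif tok[1] == "spacing":
                    spacing = np.array([float(v) for v in tok[2:5]])
                elif tok[1] == "origin":
                    origin = np.array([float(v) for v in tok[2:5]])
                else:
                    raise BundleMalformedError(f"bundle malformed: bad grid record {line!r}")
            elif tok[0] == "plan":
                plan_specs.append((tok[1], float(tok[2]), tok[3], ()))
            elif tok[0] == "composite":
                plan_specs.append((tok[1], None, tok[2], tuple(tok[3:])))
            elif tok[0] == "structure":
                role = tok[3] if len(tok) > 3 else "organ"
                struct_specs.append((tok[1], tok[2], role))
            else:
                raise BundleMalformedError(f"bundle malformed: unknown record {tok[0]!r}")
        except (IndexError, ValueError) as exc:
            raise BundleMalformedError(f"bundle malformed: cannot parse {line!r}") from exc

    if dims is None or spacing is None or origin is None or not plan_specs:
        raise BundleMalformedError("bundle malformed: header lacks grid geometry or plans")

    pd_by_id = {pid: pd for pid, pd, _, _ in plan_specs}
    plans: list[PlanRecord] = []
    grids: dict[str, DoseGrid] = {}
    for pid, pd, dose_file, components in plan_specs:
        if pd is None:  # composite: prescription is the sum of its parts
            try:
                pd = sum(pd_by_id[c] for c in components)
            except KeyError as exc:
                raise BundleMalformedError(
                    f"bundle malformed: composite {pid!r} references unknown plan {exc}"
                ) from exc
        plans.append(PlanRecord(plan_id=pid, prescription_dose=pd, components=components))
        grids[pid] = _read_dose_file(path / dose_file, dims, origin, spacing)

    structures = [
        _read_contour_file(path / fname, name, role) for name, fname, role in struct_specs
    ]
    return PlanBundle(plans=plans, structures=structures, grids=grids)


# ---------------------------------------------------------------------------
# Point-of-interest query grammar
# ---------------------------------------------------------------------------

@dataclass
class DVHQuery:
    """One normalized DVH query.

    kind
        ``volume_at_dose`` (Vx, threshold in cGy), ``dose_at_volume``
        (Dx, volume in percent), ``coverage_rel`` (PD-relative threshold,
        resolved to cGy once the prescription dose is known) or ``stat``.
    """

    kind: str
    raw: str
    dose_cgy: float | None = None
    volume_pct: float | None = None
    pd_fraction: float | None = None
    direction: str = ">"
    stat: str | None = None

    def resolve(self, pd: float) -> "DVHQuery":
        """Return a copy with PD-relative thresholds turned into cGy."""
        if self.kind == "coverage_rel" and self.dose_cgy is None:
            return DVHQuery(kind=self.kind, raw=self.raw,
                            dose_cgy=self.pd_fraction * pd,
                            pd_fraction=self.pd_fraction, direction=self.direction)
        return self


_REL_RE = re.compile(r"^([<>])(\d+(?:\.\d+)?)PD$", re.IGNORECASE)
_VX_RE = re.compile(r"^V(\d+(?:\.\d+)?)$", re.IGNORECASE)
_DX_RE = re.compile(r"^D(\d+(?:\.\d+)?)$", re.IGNORECASE)
CGY_PER_GY = 100.0


def parse_poi_token(token: str) -> DVHQuery:
    """Parse one query token.

    ``V40`` → volume receiving >= 40 Gy (thresholds in the Vx shorthand are
    in Gy, the field's reporting convention); ``D95`` → dose covering 95%
    of the volume; ``>0.25PD`` / ``<0.95PD`` → PD-relative coverage;
    ``min``/``max``/``mean``/``median`` → summary statistic.
    """
    tok = token.strip()
    if not tok:
        raise PoiParseError("malformed query token: empty token")
    low = tok.lower()
    if low in ("min", "max", "mean", "median"):
        return DVHQuery(kind="stat", raw=tok, stat=low)
    m = _REL_RE.match(tok)
    if m:
        return DVHQuery(kind="coverage_rel", raw=tok,
                        pd_fraction=float(m.group(2)), direction=m.group(1))
    m = _VX_RE.match(tok)
    if m:
        return DVHQuery(kind="volume_at_dose", raw=tok,
                        dose_cgy=float(m.group(1)) * CGY_PER_GY)
    m = _DX_RE.match(tok)
    if m:
        pct = float(m.group(1))
        if pct > 100:
            raise PoiParseError(f"malformed query token: {tok!r} (Dx percent > 100)")
        return DVHQuery(kind="dose_at_volume", raw=tok, volume_pct=pct)
    raise PoiParseError(f"malformed query token: {tok!r}")


def read_poi_config(path: str | Path, pd: float | None = None) -> list[DVHQuery]:
    """Read a point-of-interest config: tokens separated by commas or
    whitespace, ``#`` starts a comment.  When ``pd`` is given, PD-relative
    thresholds are resolved to cGy."""
    text = Path(path).read_text()
    queries: list[DVHQuery] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0]
        for token in re.split(r"[,\s]+", line):
            if token:
                queries.append(parse_poi_token(token))
    if pd is not None:
        queries = [q.resolve(pd) for q in queries]
    return queries


# ---------------------------------------------------------------------------
# Spreadsheet-style report
# ---------------------------------------------------------------------------

def round_half_up_pct(fraction: float) -> int:
    """Integer percent with half-up rounding (0.465 of the volume → 47%)."""
    return int(math.floor(100.0 * fraction + 0.5))


TARGET_COVERAGE_LABELS = ("<0.93PD", "<0.95PD", ">1.05PD", ">1.10PD", ">1.15PD", ">1.20PD")
ORGAN_COVERAGE_LABELS = (">0.25PD", ">0.50PD", ">0.75PD", ">1.00PD")


@dataclass
class TargetRow:
    patient: str
    trial: str
    pd: float
    min_dose: float
    max_dose: float
    mean_dose: float
    volume_cc: float
    coverage_cc: dict[str, float] = field(default_factory=dict)


@dataclass
class CoverageRow:
    patient: str
    structure: str
    trial: str
    total_cc: float
    coverage_cc: dict[str, float] = field(default_factory=dict)


@dataclass
class StatsRow:
    patient: str
    structure: str
    trial: str
    vx_pct: dict[str, float] = field(default_factory=dict)
    min_dose: float = 0.0
    max_dose: float = 0.0
    mean_dose: float = 0.0
    median_dose: float = 0.0


@dataclass
class PlanReport:
    targets: list[TargetRow]
    organs: list[CoverageRow]
    stats: list[StatsRow]


def _fmt(v: float) -> str:
    return f"{v:.1f}"


def write_report(report: PlanReport, path: str | Path) -> list[Path]:
    """Write the four report sections as CSV files under ``path``.

    Section A: per-target min/max/mean/volume plus absolute and normalized
    coverage at PD fractions; sections B/C: normalized / absolute coverage
    for normal structures; section D: Vx and min/max/mean/median per
    structure per plan.  Percent cells are rounded half-up to integers.
    Output is a pure function of the rows, so re-runs are byte-identical.
    """
    if not (report.targets or report.organs or report.stats):
        raise ValueError("cannot write an empty report")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _open(name: str):
        p = path / name
        written.append(p)
        return open(p, "w", newline="")

    with _open("report_targets.csv") as fh:
        w = csv.writer(fh)
        w.writerow(["Patient", "Trial", "PD (cGy)", "Min (cGy)", "Max (cGy)",
                    "Mean (cGy)", "Volume (cc)"])
        for r in report.targets:
            w.writerow([r.patient, r.trial, _fmt(r.pd), _fmt(r.min_dose),
                        _fmt(r.max_dose), _fmt(r.mean_dose), _fmt(r.volume_cc)])
        w.writerow([])
        w.writerow(["Absolute Volume (cc)"])
        w.writerow(["Patient", "Trial", *TARGET_COVERAGE_LABELS])
        for r in report.targets:
            w.writerow([r.patient, r.trial,
                        *[_fmt(r.coverage_cc.get(lbl, 0.0)) for lbl in TARGET_COVERAGE_LABELS]])
        w.writerow([])
        w.writerow(["Normalized Volume (%)"])
        w.writerow(["Patient", "Trial", *TARGET_COVERAGE_LABELS])
        for r in report.targets:
            w.writerow([r.patient, r.trial,
                        *[f"{round_half_up_pct(r.coverage_cc.get(lbl, 0.0) / r.volume_cc)}%"
                          for lbl in TARGET_COVERAGE_LABELS]])

    with _open("report_normalized.csv") as fh:
        w = csv.writer(fh)
        w.writerow(["Patient", "Structure", "Trial", *ORGAN_COVERAGE_LABELS])
        for r in report.organs:
            w.writerow([r.patient, r.structure, r.trial,
                        *[f"{round_half_up_pct(r.coverage_cc.get(lbl, 0.0) / r.total_cc)}%"
                          for lbl in ORGAN_COVERAGE_LABELS]])

    with _open("report_absolute.csv") as fh:
        w = csv.writer(fh)
        w.writerow(["Patient", "Structure", "Trial", *ORGAN_COVERAGE_LABELS])
        for r in report.organs:
            w.writerow([r.patient, r.structure, r.trial,
                        *[_fmt(r.coverage_cc.get(lbl, 0.0)) for lbl in ORGAN_COVERAGE_LABELS]])

    with _open("report_stats.csv") as fh:
        w = csv.writer(fh)
        vx_labels = sorted({k for r in report.stats for k in r.vx_pct},
                           key=lambda s: float(s[1:]))
        w.writerow(["Patient", "Structure", "Trial", *vx_labels,
                    "MIN", "MAX", "MEAN", "MEDIAN"])
        for r in report.stats:
            w.writerow([r.patient, r.structure, r.trial,
                        *[f"{round_half_up_pct(r.vx_pct.get(lbl, 0.0) / 100.0)}%"
                          for lbl in vx_labels],
                        _fmt(r.min_dose), _fmt(r.max_dose),
                        _fmt(r.mean_dose), _fmt(r.median_dose)])

    return written
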