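"""Pipeline from a plan bundle to the spreadsheet-style report rows.

Summary doses for the report (min/max/mean) are taken directly from the
member voxel doses so that a uniform-dose target reports exactly the
plateau; coverages and the median are read from the cumulative curve.
"""

from __future__ import annotations

import numpy as np

from .dvh import compute_ddvh, cumulate, dvh_statistics, rasterize_structure
from .plan_io import (
    ORGAN_COVERAGE_LABELS,
    TARGET_COVERAGE_LABELS,
    CoverageRow,
    DVHQuery,
    PlanBundle,
    PlanReport,
    StatsRow,
    TargetRow,
    parse_poi_token,
)

__all__ = ["build_report"]

DEFAULT_VX_QUERIES = ("V40", "V50", "V65", "V75")


def _coverage(cdvh, label: str, pd: float) -> float:
    """Absolute covered volume (cc) for a '<xPD' or '>xPD' label."""
    frac = float(label[1:-2])
    above = float(cdvh.volume_at_dose(frac * pd))
    if label.startswith("<"):
        return cdvh.total_volume_cc - above
    return above


def build_report(
    bundle: PlanBundle,
    patient: str = "CASE",
    queries: list[DVHQuery] | None = None,
    supersample: int = 1,
    bin_width: float | None = None,
) -> PlanReport:
    """Evaluate every (structure, plan) pair of a bundle into report rows."""
    if queries is None:
        queries = [parse_poi_token(t) for t in DEFAULT_VX_QUERIES]
    vx_queries = [q for q in queries if q.kind == "volume_at_dose"]

    report = PlanReport(targets=[], organs=[], stats=[])
    any_grid = bundle.grids[bundle.plans[0].plan_id]
    masks = {
        s.name: rasterize_structure(s, any_grid, supersample=supersample)
        for s in bundle.structures
    }
    for plan in bundle.plans:
        grid = bundle.grids[plan.plan_id]
        pd = plan.prescription_dose
        for s in bundle.structures:
            mask = masks[s.name]
            ddvh = compute_ddvh(grid, mask, bin_width=bin_width)
            cdvh = cumulate(ddvh)
            member_doses = grid.dose[mask.member]
            weights = mask.frac[mask.member]
            dmin = float(member_doses.min())
            dmax = float(member_doses.max())
            dmean = float(np.average(member_doses, weights=weights))
            if s.role == "target":
                report.targets.append(TargetRow(
                    patient=patient, trial=plan.plan_id, pd=pd,
                    min_dose=dmin, max_dose=dmax, mean_dose=dmean,
                    volume_cc=cdvh.total_volume_cc,
                    coverage_cc={lbl: _coverage(cdvh, lbl, pd)
                                 for lbl in TARGET_COVERAGE_LABELS},
                ))
            else:
                report.organs.append(CoverageRow(
                    patient=patient, structure=s.name, trial=plan.plan_id,
                    total_cc=cdvh.total_volume_cc,
                    coverage_cc={lbl: _coverage(cdvh, lbl, pd)
                                 for lbl in ORGAN_COVERAGE_LABELS},
                ))
            stats = dvh_statistics(cdvh, ddvh, vx_queries)
            report.stats.append(StatsRow(
                patient=patient, structure=s.name, trial=plan.plan_id,
                vx_pct={q.raw: (r.volume_pct if not r.clamped else 0.0)
                        for q, r in zip(vx_queries, stats.answers)},
                min_dose=dmin, max_dose=dmax, mean_dose=dmean,
                median_dose=stats.median_dose,
            ))
    return report
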