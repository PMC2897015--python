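"""Treatment-plan quality indices: the ten-member universal plan-index (UPI)
set and the exponential quality factor (QF).

All indices are dimensionless ratios of DVH-derived volumes and doses and
equal unity for an ideal plan (prescription isodose exactly covering the
target, no hot spots, no organ-at-risk overdose):

====== =====================================================================
TCI    target coverage index, ``PTV_PD / PTV``
COSI   critical-organ scoring index, ``1 - [sum_i w_i V(OAR_i >= TOL_i)] / TCI``
RCI    radiation conformity index, ``PTV_PD / PTV_0.95PD``
PITV   prescription-isodose-to-target-volume ratio, ``PIV / PTV``
HI     homogeneity index, ``Dmax / PD``
MHI    modified homogeneity index, ``D95 / D5``
CN     conformation number, ``TCI / TR`` (= TCI * CI)
TVR    target volume ratio, ``PTV / PIV`` (inverse of PITV)
DGI    dose gradient index, ``PTV_PD / PTV_0.50PD``
NCI    new conformity index, ``PIV * PTV / PTV_PD**2``
====== =====================================================================

with the auxiliaries ``TR = PIV / PTV_PD`` (treatment volume ratio) and
``CI = 1 / TR`` (conformality index).  ``PTV_x`` is the target volume
covered at dose ``x``; ``PIV`` is the prescription isodose volume over the
whole dose grid.  QF combines selected indices as
``QF = 2.718 * exp(-sum_i W_i X_i)`` with user weights ``W_i`` in [0, 1];
the printed constant 2.718 (rather than e) is kept deliberately, a relative
deviation below 4e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "UPI_NAMES",
    "OARConstraint",
    "UPIInputs",
    "UPIResult",
    "compute_upi_inputs",
    "compute_upi",
    "compute_qf",
]

UPI_NAMES = ("TCI", "COSI", "RCI", "PITV", "HI", "MHI", "CN", "TVR", "DGI", "NCI")

_QF_BASE = 2.718  # as printed; not math.e


@dataclass
class OARConstraint:
    """One organ-at-risk entry: fractional volume above its tolerance dose."""

    name: str
    fractional_volume: float  # V(>= TOL) / V_total, in [0, 1]
    tolerance_cgy: float
    weight: float  # w_i, conventionally 1/N

    def __post_init__(self) -> None:
        if not 0.0 <= self.fractional_volume <= 1.0:
            raise ValueError(f"OAR {self.name!r}: fractional volume must be in [0, 1]")
        if self.weight < 0:
            raise ValueError(f"OAR {self.name!r}: weight must be non-negative")


@dataclass
class UPIInputs:
    """Dose/volume quantities feeding the index formulas.

    Volumes in cc, doses in cGy.  ``ptv_pd``, ``ptv_095pd`` and
    ``ptv_050pd`` are the target volumes covered at PD, 0.95 PD and
    0.50 PD; ``piv`` is the whole-grid volume at or above PD.
    """

    pd: float
    ptv_volume: float
    ptv_pd: float
    ptv_095pd: float
    ptv_050pd: float
    piv: float
    dmax: float
    d95: float
    d5: float
    oars: list[OARConstraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label in ("ptv_volume", "ptv_pd", "ptv_095pd", "ptv_050pd", "piv"):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be non-negative")
        tol = 1e-9 * max(self.ptv_volume, 1.0)
        if self.ptv_pd > self.ptv_095pd + tol or self.ptv_095pd > self.ptv_volume + tol:
            raise ValueError("expected PTV_PD <= PTV_0.95PD <= PTV")


@dataclass
class UPIResult:
    """Index values keyed by name; undefined indices carry a reason instead."""

    values: dict[str, float]
    reasons: dict[str, str]
    tr: float | None  # treatment volume ratio, PIV / PTV_PD
    ci: float | None  # conformality index, 1 / TR

    def defined(self, name: str) -> bool:
        return self.values.get(name) is not None


def compute_upi_inputs(cdvh_ptv, cdvh_body, oar_cdvhs, pd: float) -> UPIInputs:
    """Evaluate the index inputs from cumulative DVHs.

    ``cdvh_body`` is the whole-grid curve from which PIV is taken and is
    mandatory (PITV, TVR, NCI, CN and TR all depend on it);
    ``oar_cdvhs`` is a sequence of ``(name, cdvh, tolerance_cgy)``,
    weighted 1/N each.
    """
    if cdvh_body is None:
        raise ValueError(
            "whole-grid cumulative DVH is required: PIV-dependent indices "
            "(PITV, TVR, NCI, CN, TR) cannot be evaluated without it"
        )
    total = cdvh_ptv.total_volume_cc
    n = len(oar_cdvhs)
    oars = [
        OARConstraint(
            name=name,
            fractional_volume=float(c.volume_at_dose(tol)) / c.total_volume_cc,
            tolerance_cgy=tol,
            weight=1.0 / n,
        )
        for name, c, tol in oar_cdvhs
    ]
    return UPIInputs(
        pd=pd,
        ptv_volume=total,
        ptv_pd=float(cdvh_ptv.volume_at_dose(pd)),
        ptv_095pd=float(cdvh_ptv.volume_at_dose(0.95 * pd)),
        ptv_050pd=float(cdvh_ptv.volume_at_dose(0.50 * pd)),
        piv=float(cdvh_body.volume_at_dose(pd)),
        dmax=cdvh_ptv.max_support_dose(),
        d95=cdvh_ptv.dose_at_volume(0.95 * total),
        d5=cdvh_ptv.dose_at_volume(0.05 * total),
        oars=list(oars),
    )


def _ratio(num: float, den: float, den_label: str):
    if den == 0:
        return None, f"undefined: denominator {den_label} is zero"
    return num / den, None


def compute_upi(inputs: UPIInputs) -> UPIResult:
    """Evaluate the ten UPI indices (QF is computed separately).

    An index whose denominator vanishes is reported as undefined with a
    reason, never as +/-inf.
    """
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}

    def put(name: str, value, reason):
        if reason is None:
            values[name] = value
        else:
            values[name] = None
            reasons[name] = reason

    tci, r = _ratio(inputs.ptv_pd, inputs.ptv_volume, "PTV")
    put("TCI", tci, r)

    if tci is None or tci == 0:
        put("COSI", None, "undefined: TCI is zero or undefined")
    else:
        overdose = sum(o.weight * o.fractional_volume for o in inputs.oars)
        put("COSI", 1.0 - overdose / tci, None)

    put("RCI", *_ratio(inputs.ptv_pd, inputs.ptv_095pd, "PTV_0.95PD"))
    put("PITV", *_ratio(inputs.piv, inputs.ptv_volume, "PTV"))
    put("HI", *_ratio(inputs.dmax, inputs.pd, "PD"))
    put("MHI", *_ratio(inputs.d95, inputs.d5, "D5"))

    tr, tr_reason = _ratio(inputs.piv, inputs.ptv_pd, "PTV_PD")
    ci = None if tr in (None, 0) else 1.0 / tr
    if tci is None or tr in (None, 0):
        put("CN", None, "undefined: requires TCI and a nonzero TR")
    else:
        put("CN", tci / tr, None)

    put("TVR", *_ratio(inputs.ptv_volume, inputs.piv, "PIV"))
    put("DGI", *_ratio(inputs.ptv_pd, inputs.ptv_050pd, "PTV_0.50PD"))
    if inputs.ptv_pd == 0:
        put("NCI", None, "undefined: denominator PTV_PD is zero")
    else:
        put("NCI", inputs.piv * inputs.ptv_volume / inputs.ptv_pd**2, None)

    return UPIResult(values=values, reasons=reasons, tr=tr, ci=ci)


def compute_qf(result: UPIResult, weights=None, indices=None) -> float:
    """Quality factor ``QF = 2.718 * exp(-sum W_i X_i)`` over selected indices.

    ``weights`` maps index name to W_i in [0, 1] (default: 1/10 for each of
    the ten indices).  ``indices`` selects a subset; every selected index
    must be defined.
    """
    selected = tuple(indices) if indices is not None else UPI_NAMES
    unknown = [n for n in selected if n not in UPI_NAMES]
    if unknown:
        raise ValueError(f"unknown indices: {unknown}")
    if weights is None:
        weights = {name: 0.1 for name in selected}
    undefined = [n for n in selected if result.values.get(n) is None]
    if undefined:
        detail = "; ".join(f"{n}: {result.reasons.get(n, 'missing')}" for n in undefined)
        raise ValueError(f"cannot compute QF, undefined indices: {detail}")
    acc = 0.0
    for name in selected:
        w = weights.get(name, 0.0)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight for {name} must be in [0, 1], got {w}")
        acc += w * result.values[name]
    return _QF_BASE * math.exp(-acc)
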