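"""Radiobiological outcome models on fractional DVHs.

Tumour control probability (TCP) uses the Poisson single-hit model

    TCP = (1/2) ** sum_i v_i * exp[2 * gamma50 * (1 - D_i / TCD50) * ln 2]

where ``TCD50`` and ``gamma50`` are the dose and normalized slope at 50%
control.  Normal-tissue complication probability (NTCP) uses the Lyman
sigmoidal dose-response (probit) model on the equivalent uniform dose:

    NTCP = Phi[(EUD - TD50) / (m * TD50)],    EUD = GMD = (sum_i v_i * D_i**(1/n)) ** n

``Phi`` is the standard normal CDF, implemented through the complementary
error function: ``Phi(x) = erfc(-x / sqrt(2)) / 2``.  The parameter ``m``
sets the response slope, ``TD50`` its position, and ``n`` in (0, 1] the
dose-volume dependence of the tissue (n = 1: mean-dose-driven "parallel"
behaviour; n -> 0: max-dose-driven "serial" behaviour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, logsumexp

from .dvh import DifferentialDVH

__all__ = [
    "FractionalDVH",
    "TCPParams",
    "NTCPParams",
    "tcp_poisson",
    "gmd",
    "ntcp_lyman",
    "EXAMPLE_TCP_PARAMS",
    "EXAMPLE_NTCP_PARAMS",
]

_LN2 = math.log(2.0)


@dataclass(eq=False)
class FractionalDVH:
    """Dose levels ``D_i`` (cGy) with fractional volumes ``v_i`` summing to 1."""

    doses: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.atleast_1d(np.asarray(self.doses, dtype=float))
        self.volumes = np.atleast_1d(np.asarray(self.volumes, dtype=float))
        if self.doses.shape != self.volumes.shape or self.doses.ndim != 1:
            raise ValueError("doses and volumes must be 1D and aligned")
        if np.any(self.volumes < 0):
            raise ValueError("fractional volumes must be non-negative")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if abs(self.volumes.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"fractional volumes must sum to 1 (got {self.volumes.sum()!r})"
            )

    @classmethod
    def from_ddvh(cls, ddvh: DifferentialDVH) -> "FractionalDVH":
        """Normalize a differential DVH: bin-centre doses, fractional volumes.

        Zero-volume bins are dropped; zero-dose bins are kept — volume at
        zero dose must still count against tumour control.
        """
        total = ddvh.total_volume_cc
        if total <= 0:
            raise ValueError("differential DVH has zero total volume")
        keep = ddvh.bin_volumes > 0
        return cls(doses=ddvh.bin_centers[keep], volumes=ddvh.bin_volumes[keep] / total)

    @classmethod
    def uniform(cls, dose: float) -> "FractionalDVH":
        return cls(doses=np.array([dose]), volumes=np.array([1.0]))


@dataclass(frozen=True)
class TCPParams:
    """Poisson model parameters: TCD50 (cGy) and normalized slope gamma50."""

    tcd50: float
    gamma50: float

    def __post_init__(self) -> None:
        if self.tcd50 <= 0 or self.gamma50 <= 0:
            raise ValueError("TCD50 and gamma50 must be positive")


@dataclass(frozen=True)
class NTCPParams:
    """Lyman model parameters: TD50 (cGy), slope m, volume exponent n."""

    td50: float
    m: float
    n: float

    def __post_init__(self) -> None:
        if self.td50 <= 0 or self.m <= 0:
            raise ValueError("TD50 and m must be positive")
        if not 0.0 < self.n <= 1.0:
            raise ValueError("n must be in (0, 1]")


# Illustrative parameter sets for a prostate-type evaluation (target and
# rectum); examples only, not clinical recommendations.
EXAMPLE_TCP_PARAMS = TCPParams(tcd50=4180.0, gamma50=0.6)
EXAMPLE_NTCP_PARAMS = NTCPParams(td50=8190.0, m=0.19, n=0.23)


def tcp_poisson(dvh: FractionalDVH, params: TCPParams) -> float:
    """Poisson tumour control probability in (0, 1].

    Uniform irradiation at exactly TCD50 returns 0.5; zero-dose bins
    contribute ``exp(2 * gamma50 * ln 2)`` to the exponent sum rather than
    being dropped.
    """
    expo = np.exp(2.0 * params.gamma50 * (1.0 - dvh.doses / params.tcd50) * _LN2)
    return float(0.5 ** float(np.dot(dvh.volumes, expo)))


def gmd(dvh: FractionalDVH, n: float) -> float:
    """Generalized mean dose ``(sum_i v_i D_i**(1/n)) ** n`` in cGy.

    Reduces to the arithmetic mean dose at n = 1 and approaches the
    maximum dose as n -> 0+.  Zero-dose bins contribute zero
    (``0**(1/n) = 0``) but their volume still dilutes the mean.  The
    power mean is evaluated in log space (log-sum-exp), which stays finite
    for small n where ``D**(1/n)`` overflows.
    """
    if n <= 0:
        raise ValueError("volume exponent n must be positive")
    pos = (dvh.doses > 0) & (dvh.volumes > 0)
    if not pos.any():
        return 0.0
    log_terms = np.log(dvh.doses[pos]) / n
    return float(np.exp(n * logsumexp(log_terms, b=dvh.volumes[pos])))


def _phi(x: float) -> float:
    """Standard normal CDF via the complementary error function."""
    return 0.5 * erfc(-x / math.sqrt(2.0))


def ntcp_lyman(dvh: FractionalDVH, params: NTCPParams) -> float:
    """Lyman probit NTCP: reduce the DVH to EUD = GMD, then Phi-transform."""
    eud = gmd(dvh, params.n)
    return float(_phi((eud - params.td50) / (params.m * params.td50)))
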