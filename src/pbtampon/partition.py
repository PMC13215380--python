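"""Menstrual-fluid Pb partitioning, hematocrit adjustment and protein binding.

Arithmetic layer for the donor measurements: converting plasma- and
RBC-fraction concentrations to a whole-fluid basis via the sample
hematocrit, RBC:plasma and fluid:plasma partition coefficients, the
equilibrium-dialysis percent unbound, and donor-group summaries.

Conventions
-----------
* "raw" (in-fraction) concentrations are what the instrument reports on the
  isolated fraction; "adjusted" concentrations are on the whole-fluid basis:
  ``adjusted_plasma = raw_plasma * (1 - hct)`` and
  ``adjusted_rbc = raw_rbc * hct``.
* Partition coefficients are always ratios of *raw* fraction concentrations;
  adjusted inputs are un-adjusted first so the correction is never applied
  twice.
* Percent unbound is ``100 * F / (F + B)`` — receiver (free) over donor
  (free + bound) chamber concentration; values above 100 are clipped with a
  warning because measurement noise near full-unbound can push the ratio
  past its physical ceiling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Matrix",
    "HematocritRecord",
    "DonorMeasurement",
    "DialysisPair",
    "PartitionResult",
    "GroupSummary",
    "adjust_for_hematocrit",
    "unadjust_for_hematocrit",
    "partition_rbc_plasma",
    "partition_fluid_plasma",
    "percent_unbound",
    "summarize_donors",
    "paper_round",
]

Matrix = Literal["whole_fluid", "plasma", "rbc", "plasma_fraction", "rbc_fraction"]

_PLASMA = {"plasma", "plasma_fraction"}
_RBC = {"rbc", "rbc_fraction"}


def _check_hct(hct: float) -> None:
    if not (0.0 < hct < 1.0):
        raise ValueError(f"hematocrit must lie strictly in (0, 1), got {hct!r}")


@dataclass(frozen=True)
class HematocritRecord:
    """One hematocrit reading for a donor sample.

    ``hematocrit`` is a volume fraction in (0, 1); ``None`` marks a failed
    measurement (over-viscous sample), which is excluded from every
    adjustment, partition-coefficient and group-mean computation.
    """

    donor_id: str
    hematocrit: float | None
    cycle_day: int | None = None
    cycle_month: int | None = None

    def __post_init__(self) -> None:
        if self.hematocrit is not None:
            _check_hct(self.hematocrit)

    @property
    def failed(self) -> bool:
        return self.hematocrit is None


@dataclass(frozen=True)
class DonorMeasurement:
    """One Pb concentration observation on a donor sample."""

    donor_id: str
    matrix: Matrix
    concentration: float          #: ng/ml (ppb)
    spike_dose: float = 0.0       #: ng/ml; 0 means endogenous
    incubation_min: float | None = None
    cycle_day: int | None = None
    cycle_month: int | None = None
    n_replicates: int = 1
    adjusted: bool = False        #: already on the whole-fluid basis?

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.spike_dose < 0:
            raise ValueError("spike_dose must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")


@dataclass(frozen=True)
class DialysisPair:
    """Equilibrium-dialysis chamber concentrations for one binding assay.

    ``donor_conc`` holds free + bound chemical (F + B); ``receiver_conc``
    holds free chemical only (F).  A receiver above the donor is physically
    impossible at equilibrium but tolerated as measurement noise.
    """

    donor_conc: float
    receiver_conc: float
    spike_dose: float = 0.0
    source: Literal["menstrual_plasma", "systemic_plasma"] = "menstrual_plasma"

    def __post_init__(self) -> None:
        if self.donor_conc < 0 or self.receiver_conc < 0:
            raise ValueError("chamber concentrations must be non-negative")
        if self.receiver_conc > self.donor_conc:
            warnings.warn(
                "receiver chamber exceeds donor chamber "
                f"({self.receiver_conc} > {self.donor_conc}); "
                "treated as measurement noise",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PartitionResult:
    """RBC:plasma and fluid:plasma partition coefficients for one sample."""

    k_rbc_plasma: float
    k_fluid_plasma: float
    hematocrit_used: float


def _matrix_kind(matrix: str) -> str:
    if matrix in _PLASMA:
        return "plasma"
    if matrix in _RBC:
        return "rbc"
    raise ValueError(
        f"matrix must be a plasma or RBC fraction, got {matrix!r}"
    )


def adjust_for_hematocrit(concentration: float, matrix: str, hct: float) -> float:
    """Convert a raw fraction concentration to the whole-fluid basis.

    Plasma: ``c * (1 - hct)``; RBC: ``c * hct``.
    """
    _check_hct(hct)
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    kind = _matrix_kind(matrix)
    return concentration * (1.0 - hct) if kind == "plasma" else concentration * hct


def unadjust_for_hematocrit(adjusted_conc: float, matrix: str, hct: float) -> float:
    """Exact inverse of :func:`adjust_for_hematocrit`.

    Needed because partition coefficients are defined on raw in-fraction
    concentrations while reported tables are on the whole-fluid basis.
    """
    _check_hct(hct)
    if adjusted_conc < 0:
        raise ValueError("concentration must be non-negative")
    kind = _matrix_kind(matrix)
    return adjusted_conc / (1.0 - hct) if kind == "plasma" else adjusted_conc / hct


def partition_rbc_plasma(
    c_rbc: float,
    c_plasma: float,
    *,
    hct: float | None = None,
    adjusted: bool = False,
) -> float:
    """RBC:plasma partition coefficient from fraction concentrations.

    By default the inputs are raw in-fraction concentrations and the result
    is their quotient.  With ``adjusted=True`` (whole-fluid basis) the
    sample hematocrit ``hct`` must be supplied; both values are un-adjusted
    first so the hematocrit correction never enters the ratio twice.
    """
    if adjusted:
        if hct is None:
            raise ValueError("hct is required to un-adjust whole-fluid-basis inputs")
        c_rbc = unadjust_for_hematocrit(c_rbc, "rbc", hct)
        c_plasma = unadjust_for_hematocrit(c_plasma, "plasma", hct)
    if c_plasma <= 0:
        raise ValueError(
            f"plasma concentration must be strictly positive, got {c_plasma!r}"
        )
    if c_rbc < 0:
        raise ValueError("RBC concentration must be non-negative")
    return c_rbc / c_plasma


def partition_fluid_plasma(k_rbc_plasma: float, hct: float) -> float:
    """Whole-fluid:plasma partition coefficient ``K*hct + (1 - hct)``.

    Affine in hematocrit; equals 1 when there are no RBCs (hct = 0) or when
    the chemical shows no RBC preference (K = 1).
    """
    if k_rbc_plasma < 0:
        raise ValueError("k_rbc_plasma must be non-negative")
    if not (0.0 <= hct < 1.0):
        raise ValueError(f"hematocrit must lie in [0, 1), got {hct!r}")
    return k_rbc_plasma * hct + (1.0 - hct)


def partition_result(
    c_rbc: float, c_plasma: float, hct: float, *, adjusted: bool = False
) -> PartitionResult:
    """Both partition coefficients for one sample."""
    k = partition_rbc_plasma(c_rbc, c_plasma, hct=hct, adjusted=adjusted)
    return PartitionResult(
        k_rbc_plasma=k,
        k_fluid_plasma=partition_fluid_plasma(k, hct),
        hematocrit_used=hct,
    )


def percent_unbound(
    pair: DialysisPair | None = None,
    *,
    receiver_conc: float | None = None,
    donor_conc: float | None = None,
) -> float:
    """Percent of chemical unbound, ``100 * F / (F + B)``, clipped to 100.

    Accepts either a :class:`DialysisPair` or the two chamber concentrations
    as keywords.
    """
    if pair is not None:
        receiver_conc, donor_conc = pair.receiver_conc, pair.donor_conc
    if receiver_conc is None or donor_conc is None:
        raise ValueError("supply a DialysisPair or both chamber concentrations")
    if donor_conc <= 0:
        raise ValueError(
            f"donor chamber concentration must be strictly positive, got {donor_conc!r}"
        )
    if receiver_conc < 0:
        raise ValueError("receiver chamber concentration must be non-negative")
    value = 100.0 * receiver_conc / donor_conc
    if value > 100.0:
        warnings.warn(
            f"percent unbound {value:.1f} exceeds 100; clipped", stacklevel=2
        )
        return 100.0
    return value


@dataclass(frozen=True)
class GroupSummary:
    """Arithmetic mean and sample SD (n-1) of a donor group."""

    mean: float
    sd: float
    n: int

    def formatted(self, ndigits: int = 1) -> str:
        if self.n < 2:
            return f"{paper_round(self.mean, ndigits)}"
        return f"{paper_round(self.mean, ndigits)} ± {paper_round(self.sd, ndigits)}"


def summarize_donors(
    values: Iterable[float] | Sequence[float],
    *,
    donor_ids: Sequence[str] | None = None,
    exclude: Iterable[str] = (),
) -> GroupSummary:
    """Group mean +/- sample SD of per-donor values.

    ``exclude`` drops donors by id (requires ``donor_ids``); a single
    remaining value reports SD = 0 by convention.
    """
    vals = np.asarray(list(values), dtype=float)
    excl = set(exclude)
    if excl:
        if donor_ids is None:
            raise ValueError("donor_ids are required to exclude donors by id")
        keep = [i for i, d in enumerate(donor_ids) if d not in excl]
        vals = vals[keep]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no values remain after exclusion")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return GroupSummary(mean=float(np.mean(vals)), sd=sd, n=int(vals.size))


def paper_round(x: float, ndigits: int = 1) -> float:
    """Round half *away from zero*, the convention of the printed tables.

    Python's built-in ``round`` is banker's rounding (14.05 -> 14.0); the
    reported tables round 14.05 -> 14.1.
    """
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
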