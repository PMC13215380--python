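"""Table-level donor analyses built on the scalar partition operations.

These functions take the delimited-table schemas (measurements, hematocrit,
dialysis, printed partition coefficients) and produce per-donor partition
coefficients, percent-unbound tables and group summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .partition import (
    GroupSummary,
    partition_fluid_plasma,
    percent_unbound,
    summarize_donors,
    unadjust_for_hematocrit,
)

__all__ = [
    "donor_hematocrit",
    "donor_partition_table",
    "percent_unbound_table",
    "group_k_summary",
]


def donor_hematocrit(hematocrit: pd.DataFrame) -> pd.Series:
    """Per-donor mean hematocrit *fraction* over non-failed readings.

    Failed readings (over-viscous samples) carry no numeric value and are
    excluded; donors with only failed readings are dropped entirely.
    """
    ok = hematocrit[hematocrit["hematocrit_pct"].notna()]
    if "status" in ok.columns:
        ok = ok[ok["status"] != "failed"]
    return ok.groupby("donor_id")["hematocrit_pct"].mean() / 100.0


def donor_partition_table(
    measurements: pd.DataFrame,
    hematocrit: pd.DataFrame,
    spike_dose: float = 10.0,
) -> pd.DataFrame:
    """Per-donor partition coefficients recomputed from fraction measurements.

    Uses the mean reported plasma and RBC concentrations at ``spike_dose``,
    un-adjusts them with the donor-mean hematocrit (partition coefficients
    are defined on raw in-fraction concentrations), and forms both
    coefficients.  Donors lacking a hematocrit or either fraction are
    skipped.
    """
    hct = donor_hematocrit(hematocrit)
    sub = measurements[
        (measurements["spike_dose_ng_ml"] == spike_dose)
        & (measurements["matrix"].isin(["plasma", "rbc"]))
    ]
    rows = []
    for donor, grp in sub.groupby("donor_id"):
        if donor not in hct.index:
            continue
        h = float(hct[donor])
        means = grp.groupby("matrix")["conc_ng_ml"].mean()
        if "plasma" not in means or "rbc" not in means or means["plasma"] <= 0:
            continue
        adjusted = bool(grp["adjusted"].iloc[0])
        c_p, c_r = float(means["plasma"]), float(means["rbc"])
        if adjusted:
            c_p = unadjust_for_hematocrit(c_p, "plasma", h)
            c_r = unadjust_for_hematocrit(c_r, "rbc", h)
        k = c_r / c_p
        rows.append(
            {
                "donor_id": donor,
                "hematocrit": h,
                "k_rbc_plasma": k,
                "k_fluid_plasma": partition_fluid_plasma(k, h),
            }
        )
    return pd.DataFrame(rows)


def percent_unbound_table(dialysis: pd.DataFrame) -> pd.DataFrame:
    """Percent unbound per dialysis row, computed from the chamber pair."""
    out = dialysis.copy()
    out["percent_unbound_calc"] = [
        percent_unbound(receiver_conc=r, donor_conc=d)
        for d, r in zip(out["donor_conc"], out["receiver_conc"])
    ]
    return out


def group_k_summary(
    k_table: pd.DataFrame,
    column: str = "k_rbc_plasma",
    *,
    purpose: str | None = "donor_to_donor",
    exclude: tuple[str, ...] = (),
) -> GroupSummary:
    """Donor-group mean +/- SD of a partition-coefficient column."""
    sub = k_table
    if purpose is not None and "purpose" in sub.columns:
        sub = sub[sub["purpose"] == purpose]
    sub = sub[np.isfinite(sub[column].astype(float))]
    return summarize_donors(
        sub[column].astype(float),
        donor_ids=list(sub["donor_id"]),
        exclude=exclude,
    )
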