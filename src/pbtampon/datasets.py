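"""Loaders for the packaged donor-measurement fixture tables.

The fixtures reproduce, row for row, the printed summary tables of the
donor study this package reanalyses: donor demographics, per-sample
hematocrit, endogenous and spiked Pb concentrations (whole fluid / plasma
fraction / RBC fraction, hematocrit-adjusted basis), per-sample partition
coefficients, and equilibrium-dialysis percent unbound.

Schema validation is deliberately strict: downstream code assumes these
column names, and the synthetic generator emits the same schemas.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_donors",
    "load_hematocrit",
    "load_measurements",
    "load_partition_coefficients",
    "load_dialysis",
    "read_table",
]

_SCHEMAS: dict[str, set[str]] = {
    "donors": {"donor_id", "age", "race"},
    "hematocrit": {"donor_id", "cycle_day", "cycle_month", "hematocrit_pct", "status"},
    "measurements": {
        "donor_id", "cycle_day", "cycle_month", "matrix", "spike_dose_ng_ml",
        "incubation_min", "conc_ng_ml", "n_replicates", "adjusted",
    },
    "partition_coefficients": {
        "donor_id", "spike_dose_ng_ml", "k_rbc_plasma", "k_fluid_plasma",
    },
    "dialysis": {"donor_id", "source", "spike_dose_ng_ml", "donor_conc", "receiver_conc"},
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a delimited table and validate it against a fixture schema.

    Raises
    ------
    ValueError
        naming the missing columns if the file does not match the schema.
    """
    df = pd.read_csv(path)
    required = _SCHEMAS[kind]
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{kind} table {path} is missing required columns: {sorted(missing)}"
        )
    if df.empty:
        raise ValueError(f"{kind} table {path} contains no data rows")
    return df


def _load(name: str, kind: str) -> pd.DataFrame:
    ref = resources.files("pbtampon.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return read_table(path, kind)


def load_donors() -> pd.DataFrame:
    """Donor demographics (id, age, race)."""
    return _load("donors", "donors")


def load_hematocrit() -> pd.DataFrame:
    """Hematocrit readings (percent) per donor/cycle-day/cycle-month.

    ``status == "failed"`` marks over-viscous samples with no numeric
    reading; these are excluded from all downstream computation.
    """
    return _load("hematocrit", "hematocrit")


def load_measurements() -> pd.DataFrame:
    """Pb concentrations (ng/ml) in whole fluid and isolated fractions.

    Fraction (plasma/rbc) rows are on the hematocrit-adjusted, whole-fluid
    basis (``adjusted == True``), matching how the values were reported.
    """
    return _load("measurements", "measurements")


def load_partition_coefficients() -> pd.DataFrame:
    """Reported per-sample RBC:plasma and fluid:plasma partition coefficients.

    These were derived from per-replicate raw fraction concentrations that
    are not available in summary form, so they cannot be reproduced exactly
    from :func:`load_measurements`; they are packaged as reported.
    """
    return _load("partition_coefficients", "partition_coefficients")


def load_dialysis() -> pd.DataFrame:
    """Equilibrium-dialysis results per donor/pool and spike dose.

    The reported quantity is ``percent_unbound``; the ``donor_conc`` /
    ``receiver_conc`` chamber pair is *reconstructed* (donor = nominal spike
    dose, receiver = dose x percent/100) so the printed percentages
    round-trip through :func:`pbtampon.partition.percent_unbound`.
    """
    return _load("dialysis", "dialysis")
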