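"""Synthetic donor panels with known ground truth.

No raw donor dataset is distributed, so end-to-end tests run on generated
panels that emulate the statistical structure of the measured donor group:

* hematocrit ~ Normal(0.25, 0.07) truncated to (0.05, 0.6) across donors;
* endogenous whole-fluid Pb ~ log-normal, median 3 ng/ml, geometric spread
  covering the observed ~1-5 ppb inter-donor range;
* RBC:plasma partition coefficient K ~ log-normal, median 2.6, geometric SD
  1.6 -- with a discrete high-K outlier class (K ~ Uniform(60, 120)) drawn
  with probability ``outlier_prob``, emulating the one strongly RBC-
  partitioning donor in the measured group;
* plasma fraction unbound ~ log-normal, median 0.03, geometric SD 2
  (clipped to (0.005, 0.95)), spanning the observed ~1-12%.

Fraction-level concentrations are constructed to satisfy the partitioning
and hematocrit-adjustment identities exactly before replicate-level
multiplicative noise is applied, so a noiseless panel round-trips exactly
through every estimation routine.  All randomness flows from one seed via
named child streams, so regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .partition import percent_unbound, unadjust_for_hematocrit

__all__ = [
    "DonorTruth",
    "NoiseModel",
    "generate_donor_panel",
    "simulate_spike_experiment",
    "simulate_dialysis",
    "recovery_report",
    "write_synthetic_panel",
]

# child-stream indices off the master SeedSequence, one per quantity
_STREAMS = {"hct": 0, "endog": 1, "k": 2, "f_unbound": 3, "outlier": 4, "noise": 5}


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level measurement noise: multiplicative, mean-1 log-normal."""

    measurement_cv: float = 0.10
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be non-negative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be a positive integer")

    @property
    def sigma(self) -> float:
        """Log-space SD giving the requested CV with mean exactly 1."""
        return float(np.sqrt(np.log1p(self.measurement_cv**2)))


@dataclass(frozen=True)
class DonorTruth:
    """Ground-truth donor characteristics known to the generator."""

    donor_id: str
    hematocrit_true: float
    k_rbc_plasma_true: float
    f_unbound_true: float
    endogenous_whole_fluid: float    #: ng/ml
    outlier_flag: bool

    def __post_init__(self) -> None:
        if not (0.05 < self.hematocrit_true < 0.6):
            raise ValueError("hematocrit_true must lie in (0.05, 0.6)")
        if self.k_rbc_plasma_true <= 0:
            raise ValueError("k_rbc_plasma_true must be positive")
        if not (0 < self.f_unbound_true < 1):
            raise ValueError("f_unbound_true must lie in (0, 1)")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(children[i]) for name, i in _STREAMS.items()}


def _noise_factors(rng: np.random.Generator, noise: NoiseModel, n: int) -> np.ndarray:
    if noise.measurement_cv == 0:
        return np.ones(n)
    s = noise.sigma
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        ok = draw[(draw > lo) & (draw < hi)][: n - filled]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return out


def generate_donor_panel(
    n_donors: int,
    noise: NoiseModel | None = None,
    outlier_prob: float = 0.125,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate donor truths, a hematocrit table and endogenous measurements.

    Returns ``(truths, hematocrit, measurements)``:

    * ``truths`` -- one row per donor with the ground-truth parameters;
    * ``hematocrit`` -- measured (noisy) hematocrit per donor, in the same
      schema as the packaged fixture (``hematocrit_pct``, ``status``);
    * ``measurements`` -- replicate-level endogenous (0 ng/ml spike)
      whole-fluid / plasma / RBC concentrations on the whole-fluid
      (adjusted) basis.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be at least 1")
    if not 0 <= outlier_prob <= 1:
        raise ValueError("outlier_prob must lie in [0, 1]")
    noise = noise or NoiseModel()
    rng = _streams(noise.seed)

    hct = _truncated_normal(rng["hct"], 0.25, 0.07, 0.05, 0.6, n_donors)
    endog = rng["endog"].lognormal(mean=np.log(3.0), sigma=0.4, size=n_donors)
    k = rng["k"].lognormal(mean=np.log(2.6), sigma=np.log(1.6), size=n_donors)
    is_outlier = rng["outlier"].random(n_donors) < outlier_prob
    k = np.where(is_outlier, rng["outlier"].uniform(60.0, 120.0, size=n_donors), k)
    f_unb = np.clip(
        rng["f_unbound"].lognormal(mean=np.log(0.03), sigma=np.log(2.0), size=n_donors),
        0.005,
        0.95,
    )

    truths = pd.DataFrame(
        {
            "donor_id": [f"SD{i + 1:03d}" for i in range(n_donors)],
            "hematocrit_true": hct,
            "k_rbc_plasma_true": k,
            "f_unbound_true": f_unb,
            "endogenous_whole_fluid": endog,
            "outlier_flag": is_outlier,
        }
    )

    noise_rng = rng["noise"]
    hct_factor = _noise_factors(noise_rng, noise, n_donors)
    hematocrit = pd.DataFrame(
        {
            "donor_id": truths["donor_id"],
            "cycle_day": 2,
            "cycle_month": np.nan,
            "hematocrit_pct": np.clip(hct * hct_factor, 0.01, 0.99) * 100.0,
            "status": "ok",
        }
    )

    frames = [
        simulate_spike_experiment(t, 0.0, noise, rng=noise_rng)
        for t in truths.itertuples(index=False)
    ]
    measurements = pd.concat(frames, ignore_index=True)
    return truths, hematocrit, measurements


def simulate_spike_experiment(
    truth: DonorTruth,
    dose: float,
    noise: NoiseModel | None = None,
    *,
    rng: np.random.Generator | None = None,
    closure_violation: float = 0.0,
    incubation_min: float | None = 60.0,
) -> pd.DataFrame:
    """Replicate-level whole/plasma/RBC measurements for one spiked sample.

    Pre-noise, the whole-fluid concentration is ``endogenous + dose`` and
    the fraction concentrations satisfy the partitioning and hematocrit
    identities exactly, so hematocrit-adjusted plasma + RBC equals the whole
    fluid (closure).  ``closure_violation`` diverts that fraction of mass to
    an unmeasured pool (buffy coat / clots) before fractionation, emulating
    the imperfect closure of real spiked samples.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if not 0 <= closure_violation < 1:
        raise ValueError("closure_violation must lie in [0, 1)")
    noise = noise or NoiseModel()
    if rng is None:
        rng = _streams(noise.seed)["noise"]
    h = truth.hematocrit_true
    k = truth.k_rbc_plasma_true
    c_whole = truth.endogenous_whole_fluid + dose
    accounted = c_whole * (1.0 - closure_violation)
    # raw fraction levels consistent with K and the hematocrit adjustment
    c_plasma_raw = accounted / ((1.0 - h) + k * h)
    c_rbc_raw = k * c_plasma_raw
    targets = {
        "whole_fluid": c_whole,
        "plasma": c_plasma_raw * (1.0 - h),
        "rbc": c_rbc_raw * h,
    }
    rows = []
    for matrix, value in targets.items():
        factors = _noise_factors(rng, noise, noise.replicate_count)
        for rep, factor in enumerate(factors, start=1):
            rows.append(
                {
                    "donor_id": truth.donor_id,
                    "cycle_day": 2,
                    "cycle_month": np.nan,
                    "matrix": matrix,
                    "spike_dose_ng_ml": dose,
                    "incubation_min": incubation_min if dose > 0 else np.nan,
                    "replicate": rep,
                    "conc_ng_ml": value * factor,
                    "n_replicates": 1,
                    "adjusted": matrix != "whole_fluid",
                }
            )
    return pd.DataFrame(rows)


def simulate_dialysis(
    truth: DonorTruth,
    dose: float,
    noise: NoiseModel | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate equilibrium-dialysis chamber pairs for one donor.

    Pre-noise, receiver = ``f_unbound_true`` x donor; noise is applied
    independently to the two chambers.
    """
    if dose <= 0:
        raise ValueError("dose must be strictly positive")
    noise = noise or NoiseModel()
    if rng is None:
        rng = _streams(noise.seed)["noise"]
    donor_f = _noise_factors(rng, noise, noise.replicate_count)
    recv_f = _noise_factors(rng, noise, noise.replicate_count)
    return pd.DataFrame(
        {
            "donor_id": truth.donor_id,
            "source": "menstrual_plasma",
            "spike_dose_ng_ml": dose,
            "replicate": np.arange(1, noise.replicate_count + 1),
            "donor_conc": dose * donor_f,
            "receiver_conc": dose * truth.f_unbound_true * recv_f,
        }
    )


def _estimate_donor(
    truths: pd.DataFrame,
    hematocrit: pd.DataFrame,
    measurements: pd.DataFrame,
    dialysis: pd.DataFrame | None,
) -> pd.DataFrame:
    """Per-donor parameter estimates via the partition/binding operations."""
    hct_est = (
        hematocrit.set_index("donor_id")["hematocrit_pct"].astype(float) / 100.0
    )
    rows = []
    for t in truths.itertuples(index=False):
        sub = measurements[measurements["donor_id"] == t.donor_id]
        h = float(hct_est[t.donor_id])
        means = sub.groupby("matrix")["conc_ng_ml"].mean()
        k_est = np.nan
        if "plasma" in means and "rbc" in means and means["plasma"] > 0:
            k_est = unadjust_for_hematocrit(means["rbc"], "rbc", h) / \
                unadjust_for_hematocrit(means["plasma"], "plasma", h)
        f_est = np.nan
        if dialysis is not None:
            dsub = dialysis[dialysis["donor_id"] == t.donor_id]
            if len(dsub):
                f_est = float(
                    np.mean(
                        [
                            percent_unbound(receiver_conc=r, donor_conc=d) / 100.0
                            for d, r in zip(dsub["donor_conc"], dsub["receiver_conc"])
                        ]
                    )
                )
        endog_est = float(means.get("whole_fluid", np.nan))
        rows.append(
            {
                "donor_id": t.donor_id,
                "hematocrit_est": h,
                "hematocrit_true": t.hematocrit_true,
                "k_est": k_est,
                "k_true": t.k_rbc_plasma_true,
                "f_unbound_est": f_est,
                "f_unbound_true": t.f_unbound_true,
                "endogenous_est": endog_est,
                "endogenous_true": t.endogenous_whole_fluid,
            }
        )
    return pd.DataFrame(rows)


def recovery_report(
    truths: pd.DataFrame,
    hematocrit: pd.DataFrame,
    measurements: pd.DataFrame,
    dialysis: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bias/RMSE of the pipeline's parameter estimates against ground truth.

    One row per parameter with the mean relative bias, relative RMSE and the
    relative bias of the group median (robust to outlier donors).
    """
    missing = set(truths["donor_id"]) - set(measurements["donor_id"])
    if missing:
        raise ValueError(f"measurements missing for donors: {sorted(missing)}")
    est = _estimate_donor(truths, hematocrit, measurements, dialysis)
    rows = []
    for param, (e_col, t_col) in {
        "hematocrit": ("hematocrit_est", "hematocrit_true"),
        "k_rbc_plasma": ("k_est", "k_true"),
        "f_unbound": ("f_unbound_est", "f_unbound_true"),
        "endogenous_whole_fluid": ("endogenous_est", "endogenous_true"),
    }.items():
        e, t = est[e_col].to_numpy(float), est[t_col].to_numpy(float)
        ok = np.isfinite(e) & np.isfinite(t)
        if not np.any(ok):
            continue
        rel = (e[ok] - t[ok]) / t[ok]
        rows.append(
            {
                "parameter": param,
                "n_donors": int(ok.sum()),
                "rel_bias": float(np.mean(rel)),
                "rel_rmse": float(np.sqrt(np.mean(rel**2))),
                "median_rel_bias": float(
                    (np.median(e[ok]) - np.median(t[ok])) / np.median(t[ok])
                ),
            }
        )
    return pd.DataFrame(rows)


def write_synthetic_panel(
    outdir: str | Path,
    n_donors: int = 20,
    noise: NoiseModel | None = None,
    outlier_prob: float = 0.125,
    spike_doses: tuple[float, ...] = (1.0, 10.0, 25.0),
    dialysis_dose: float = 10.0,
) -> dict[str, Path]:
    """Write a full synthetic panel in the packaged fixture schemas.

    Emits donors.csv, hematocrit.csv, measurements.csv (endogenous plus
    spiked), dialysis.csv and a truths.csv side-file; returns the paths.
    """
    noise = noise or NoiseModel()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths, hematocrit, measurements = generate_donor_panel(
        n_donors, noise, outlier_prob
    )
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed).spawn(7)[-1])
    spiked = [
        simulate_spike_experiment(t, dose, noise, rng=rng)
        for t in truths.itertuples(index=False)
        for dose in spike_doses
    ]
    measurements = pd.concat([measurements, *spiked], ignore_index=True)
    dialysis = pd.concat(
        [
            simulate_dialysis(t, dialysis_dose, noise, rng=rng)
            for t in truths.itertuples(index=False)
        ],
        ignore_index=True,
    )
    donors = pd.DataFrame(
        {"donor_id": truths["donor_id"], "age": pd.NA, "race": "synthetic"}
    )
    paths = {}
    for name, frame in {
        "donors": donors,
        "hematocrit": hematocrit,
        "measurements": measurements,
        "dialysis": dialysis,
        "truths": truths,
    }.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
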