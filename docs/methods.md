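# Methods

## Scope and model structure

The package couples a data-analysis layer for Pb measurements in menstrual
fluid with a deterministic, four-compartment mass-balance model of Pb release
from a tampon within the vaginal lumen.

The model assumes:

* **Constant-rate release.** The tampon releases its Pb content at a constant
  rate over a release window; for the baseline this is the full wear time
  (264 ng over 4 h = 66 ng/h). Burst scenarios use a short window (15 min)
  at constant rate rather than a Dirac bolus.
* **Instantaneous split at release.** Released mass distributes between the
  menstrual-plasma and menstrual-RBC pools as a mass ratio equal to the
  RBC:plasma partition coefficient K, i.e. fractions 1/(1+K) and K/(1+K).
  Split-at-release and fast dynamic exchange are indistinguishable at the
  reported output times; split-at-release is adopted as the simpler reading,
  and it reproduces the end-of-wear plasma:RBC mass ratio (9 ng : 24 ng =
  1 : 2.6).
* **Constant fluid volume, first-order washout.** Fluid uptake into the
  tampon (Q_abs, ml/h) is balanced by fresh menses, so the free-fluid volume
  V is constant and both fluid pools are cleared into the tampon at
  k_out = Q_abs/V, applied equally to plasma- and RBC-associated mass.
* **Unidirectional tissue sink on unbound plasma Pb.** The permeation flux is
  Papp·Area·C_u with driving concentration C_u = f_unbound·A_p/V over the
  whole free-fluid volume (hematocrit is not a model parameter); permeated
  mass is debited from the plasma pool and accumulated. Units: hours
  internally, Papp converted cm/s → cm/h by ×3600, cm³ ≡ ml.

With piecewise-constant input the system is linear; `analytic_trajectory`
implements the exact solution (resident pools are saturating/decaying
exponentials; cumulative sinks are their exact integrals) and serves as an
independent oracle for the numerical route.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| R_release | 66 | ng/h | Pb release rate from tampon (264 ng / 4 h) |
| Q_abs | 1 | ml/h | menstrual fluid uptake into tampon |
| Papp | 1×10⁻⁶ | cm/s | tissue permeability (Caco-2-derived, ×10 for conservatism) |
| Area | 21 | cm² | vaginal tissue area in contact with the tampon |
| V_menses | 0.5 | ml | free fluid volume in the lumen |
| f_unbound | 0.12 | – | unbound fraction of Pb in menstrual plasma |
| RBC_part_coef | 2.6 | – | menstrual RBC:plasma partition coefficient |

Schedule quantities (tampon content 264 ng, released fraction, release
window, wear time) live in `ReleaseSchedule`; the operative release rate is
always content × fraction / duration, which equals R_release at baseline.
The sensitivity knob "R_release" scales tampon content at fixed duration —
an identical rate change — so its coefficient is exactly 1 by linearity.

## Numerical choices

* Integrator: adaptive LSODA at rtol 1e-10 / atol 1e-12, integrating the two
  constant-input legs separately so the solver never steps across the release
  switch. Mass-balance residual (released − sum of pools) is checked below
  1e-6 × released mass at every output time; `fate_summary` refuses
  trajectories that violate it.
* Output grid: 241 points per simulation (step 1 min over a 4-h run), enough
  that interpolation error is irrelevant to any reported 2-decimal figure.
* The reported baseline tampon-reabsorbed percentage (87.39) differs from
  the closed form (87.32) by <0.1 percentage point; the solver behind the
  reported figure is not available, so comparisons to that single value use
  a 0.1-pp band. All other scenario percentages agree to the printed
  2-decimal precision.
* Sensitivity: forward +1% perturbation (the single-direction convention),
  dose metric = cumulative tissue mass at the end of wear. Designations use
  |SC| with the standard brackets (≥0.5 high, 0.2–0.5 medium, 0.1–0.2 low)
  plus a "negligible" bucket below 0.1 that the brackets leave unnamed.
  Coefficients on the numerical and analytic routes agree to 4 decimals.
* Rounding: all computation at full precision; `paper_round` (half away from
  zero) exists only to reproduce the reported 1-decimal table style (e.g.
  the donor-group K mean 14.05 → 14.1), never for internal arithmetic.

## Partitioning and binding conventions

Partition coefficients are defined on raw in-fraction concentrations;
reported tables are on the hematocrit-adjusted (whole-fluid) basis, so
adjusted inputs are un-adjusted first (`adjusted` flag) to prevent silent
double correction. Dialysis pairs with receiver > donor are clipped to 100%
unbound with a warning (noise near full-unbound), not rejected. Failed
hematocrit readings (over-viscous samples) are excluded from every
adjustment, K computation and group mean. Group summaries use sample SD
(n−1); a single value reports SD 0 by convention.

Recomputing per-donor K from the packaged *summary* measurement table and
donor-mean hematocrits lands near, but not exactly on, the reported
per-sample coefficients (which derive from unpublished per-replicate raw
data; e.g. 2.60 recomputed vs 2.4 reported for one donor at 10 ng/ml). The
reported coefficient table is therefore packaged as its own fixture and is
canonical for group summaries (14.1 all donors; 2.6 excluding the high-K
outlier donor RP54); the recomputed per-donor table is shown alongside in
the CLI for transparency.

## Synthetic donor panels

The generator emulates the donor group's statistical structure: hematocrit
~ N(0.25, 0.07) truncated to (0.05, 0.6); endogenous whole-fluid Pb
log-normal with median 3 ng/ml and σ_log 0.4 (matching the observed ~1–5 ppb
donor range and ~0.43 CV); K log-normal with median 2.6 and geometric SD 1.6
(spanning the observed 0.9–4.4 bulk), with a discrete high-K outlier class
K ~ U(60, 120) at probability 0.125 (one donor in eight), reflecting the
bimodal donor set; unbound fraction log-normal median 0.03, geometric SD 2
(spanning the observed ~1–12%). Replicate noise is multiplicative mean-1
log-normal at 10% CV by default — a value inferred from the reported
SD/mean ratios and treated as a default, not a finding.

Fraction-level concentrations are constructed to satisfy the partitioning
and adjustment identities exactly before noise, so noiseless panels
round-trip exactly through the estimation pipeline. Real spiked samples do
*not* close mass perfectly (buffy coat/clot losses); a `closure_violation`
knob diverts a stated mass fraction to an unmeasured pool to emulate this.
All randomness flows from one seed through named child streams, so
regeneration is byte-identical.

What the generator does **not** emulate: menstrual-fluid rheology and
clotting, day-to-day hematocrit autocorrelation, matrix-dependent recovery
artifacts, and the real samples' imperfect mass closure (unless the knob is
turned). Passing recovery tests therefore demonstrate correctness of the
arithmetic pipeline under the stated noise model, not robustness to every
matrix artifact of real menstrual fluid.

Parameter-recovery bias is assessed as an expectation: the median-K relative
deviation of a single 20-donor panel has ~9% sampling SD, so the recovery
check averages the per-panel deviation over 40 replicate panels (seeded from
one master seed), which estimates the actual bias (~2% at 10% CV).

## Known limitations

* No bidirectional tissue flux and no systemic Pb kinetics; the blood
  increment is a static instantaneous-dilution bound, intentionally
  conservative.
* The model is deterministic; parameter distributions (a probabilistic
  extension) are out of scope.
* The extended-run duration (2 h past release) and the scenario set are
  conventions of the comparison, both exposed as parameters.
* Hematocrit enters the data analysis but not the release model; fluid
  sub-volumes are not resolved.
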