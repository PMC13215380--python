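# pbtampon

Quantitative assessment of potential lead (Pb) exposure from tampon use.

Trace levels of Pb have been reported in tampons, but chemical *presence* in a
product is not the same as biologically relevant *exposure*. This package
implements the two halves of a mechanistic exposure assessment for Pb in the
vaginal lumen, for toxicologists and exposure modellers:

1. **Menstrual-fluid data analysis** — hematocrit adjustment of
   fraction-level Pb concentrations, RBC:plasma and fluid:plasma partition
   coefficients, equilibrium-dialysis percent unbound, and donor-group
   summaries (with packaged fixture tables reproducing the reported donor
   measurements row for row).
2. **A four-compartment deterministic mass-balance model** of Pb release from
   a tampon into menstrual fluid — partitioning between plasma and RBC pools,
   reabsorption into the tampon with fluid uptake, and unidirectional
   permeation of the unbound plasma fraction across vaginal tissue — plus
   local sensitivity analysis, release-scenario comparison, and exposure
   contextualisation against the CDC blood lead reference value (3.5 µg/dl).

A synthetic donor-panel generator with known ground truth supports end-to-end
pipeline tests and parameter-recovery checks without any raw donor data.

## Model

States (ng): plasma-resident $A_p$, RBC-resident $A_r$, cumulative tissue
uptake $A_T$, cumulative tampon reabsorption $A_B$. With release rate $u(t)$
(constant over the release window, zero after), split fraction
$f_p = 1/(1+K)$ with $K$ the RBC:plasma partition coefficient,
$k_{out} = Q_{abs}/V$ and $k_{tis} = P_{app}\,A\,f_u/V$:

```
dA_p/dt = u(t) f_p − (k_out + k_tis) A_p
dA_r/dt = u(t) (1 − f_p) − k_out A_r
dA_T/dt = k_tis A_p
dA_B/dt = k_out (A_p + A_r)
```

Baseline parameters: R_release 66 ng/h (264 ng per tampon over a 4-h wear),
Q_abs 1 ml/h, Papp 1×10⁻⁶ cm/s, Area 21 cm², V_menses 0.5 ml, f_unbound 0.12,
K 2.6. The system is linear with piecewise-constant input, so a closed-form
solution is available (`analytic_trajectory`) and is used as an independent
oracle for the adaptive numerical integrator (`simulate`).

## Worked example

```bash
$ pbtampon simulate
released: 264.00 ng over 4 h; state at 4 h:
  tampon (reabsorbed)    230.52 ng   87.32 % of released
  menstrual RBCs          23.83 ng    9.02 % of released
  menstrual plasma         9.08 ng    3.44 % of released
  vaginal tissue           0.58 ng    0.22 % of released
```

Of 264 ng released over a 4-h wear, ~87% is reabsorbed into the tampon with
fluid uptake, ~12% remains resident in the free menstrual fluid (RBC and
plasma pools in the 2.6:1 partition ratio), and only 0.58 ng (0.22%) ever
reaches vaginal tissue. The same conclusion holds across release scenarios
(`pbtampon scenarios`): an instantaneous-burst release changes the timing
but not the fate — ≥99.7% ends up back in the tampon with ~0.25% in tissue —
and a two-fold sweep of every parameter keeps tissue uptake under 1.2 ng
(`pbtampon sensitivity --sweep`). Contextualised, one cycle's worth of
absorbed Pb (25 tampons × ~1 ng) mixed instantly into 39 dl of blood gives
0.000641 µg/dl, several thousand-fold below the 3.5 µg/dl reference value,
and well under the ~261 ng/cycle excreted naturally via menses.

The same numbers are available programmatically:

```python
from pbtampon import ModelParams, ReleaseSchedule, simulate, fate_summary
summary = fate_summary(simulate(ModelParams(), ReleaseSchedule()))
summary.tissue_ng   # 0.5777
summary.pct_tampon  # 87.32
```

Donor-data analysis runs off the packaged fixtures or your own CSVs:

```bash
pbtampon partition            # per-donor K, percent unbound, group means
pbtampon synth --n-donors 20 --seed 1 --out-dir panel/   # synthetic panel
```

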