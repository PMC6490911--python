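# lznpk — paediatric linezolid population PK, dose optimization and safety

Linezolid is a key drug for multidrug-resistant tuberculosis (MDR-TB), but
long-course use causes dose- and exposure-dependent toxicity (anaemia,
peripheral neuropathy), and until recently there were no pharmacokinetic
data in children treated for TB. `lznpk` implements, as a tested and
reusable pipeline, the analysis workflow behind a paediatric linezolid
dosing study: a population PK model fitted to intensively sampled
concentration data from children, model-based derivation of weight-banded
doses matching an adult exposure target, and exposure–toxicity survival
analyses of long-term safety data. A synthetic-cohort generator reproduces
the statistical structure of such a study so every stage is testable
without any clinical data.

It is aimed at pharmacometricians and TB researchers who want a
transparent, scriptable alternative to a NONMEM workflow for this class of
problem.

## The model

Disposition is a one-compartment model with first-order absorption and
elimination, parameterized by apparent clearance and volume (oral dosing,
F = 1) with fixed allometric weight scaling:

    CL/F = θ_CL · (WT/70)^0.75 · e^η₁      η₁ ~ N(0, ω²_CL)
    V/F  = θ_V  · (WT/70)      · e^η₂      η₂ ~ N(0, ω²_V)
    Ka   = θ_Ka + CL/V                      (absorption strictly faster than
                                             elimination: no flip-flop)

Residual error is combined additive + proportional,
y = f·(1+ε_p) + ε_a, optionally left-truncated at zero since measured
concentrations are non-negative. The default parameter values are the
final estimates of the motivating study: θ_Ka = 0.77 h⁻¹, θ_CL = 4.73 L/h,
θ_V = 54.8 L (at 70 kg), BSV 37%/32%, additive SD 0.78 mg/L, proportional
SD 25%.

Estimation is by approximate marginal likelihood: subject-level random
effects are integrated out with the Laplace method *with interaction*
(residual variance evaluated at each subject's conditional mode), the
conditional-estimation approach standard in pharmacometrics. Linear PK
gives AUC_0–24ss = daily dose / CL, which drives both the exposure tables
and the Monte-Carlo weight-band dose optimizer.

## Worked example

Simulate a 48-child cohort at the study design, refit the model, and
derive quarter-tablet weight-banded doses hitting the adult exposure
target (AUC_0–24ss = 110 mg·h/L after 600 mg once daily):

```python
import lznpk as L
from lznpk.estimate import FitSettings

ds, truth = L.generate_pk_dataset(L.CohortDesign(n_subjects=48),
                                  L.PopulationModel(), seed=2024)
res = L.fit(ds, settings=FitSettings())
table = L.optimize_band_doses(res.model, regime="tablet", seed=1)
sim = L.simulate_exposures(res.model, table, n_replicates=200, seed=1)
```

This prints (fit summary, then the dose table):

```
theta_ka     0.749  (RSE 12%)
theta_cl     5.353  (RSE 6%)
theta_v     52.069  (RSE 7%)
BSV CL %: 37  BSV V %: 30

 band_lo_kg  band_hi_kg  dose_mg  interval_h   formulation_note  mgkg_min  mgkg_max
        5.0         7.0    150.0        48.0 alt days (1/4 tab)      10.7      15.0
        7.0        10.0    150.0        24.0            1/4 tab      15.0      21.4
       10.0        16.0    150.0        24.0            1/4 tab       9.4      15.0
       16.0        24.0    300.0        24.0            1/2 tab      12.5      18.8
       24.0        31.0    300.0        24.0            1/2 tab       9.7      12.5
       31.0        35.0    300.0        24.0            1/2 tab       8.6       9.7
       35.0        44.0    450.0        24.0            3/4 tab      10.2      12.9
       44.0        56.0    450.0        24.0            3/4 tab       8.0      10.2

median simulated AUC0-24ss: 115.9 mg.h/L
```

Reading it: the estimated typical clearance in this synthetic cohort is
5.35 L/h at 70 kg (vs the generating 4.73 — within sampling noise of a
48-child study), and under the derived quarter-tablet banding the median
simulated steady-state exposure lands within ~5% of the 110 mg·h/L adult
target. The smallest children (5–<7 kg) cannot be dosed daily with a
quarter tablet without overshooting, so the optimizer proposes a quarter
tablet on alternate days.

The same steps are available from the shell:

```sh
lznpk generate --n 48 --seed 2024 --out pk.csv
lznpk fit --data pk.csv --out fit.json
lznpk optimize-dose --regime tablet --fit fit.json --seed 1 --out doses.csv
lznpk vpc --data pk.csv --fit fit.json --out vpc.csv
lznpk exposures --data pk.csv --fit fit.json --out exposures.csv
lznpk safety --safety-data safety.csv --out rates.csv
```

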