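# galnet

Stochastic modelling and allele-specific parameter inference for the yeast
galactose (GAL) induction network.

## The problem

When *S. cerevisiae* meets galactose, the GAL regulon switches on through a
positive feedback loop: galactose-activated Gal3p (and its paralog Gal1p)
relieves Gal80p repression of Gal4p-driven promoters, which further induces
*GAL1* and *GAL3*. Natural *GAL3* alleles change how a population turns on —
some strains induce **gradually** (every cell responds with similar kinetics,
the fluorescence distribution stays unimodal while shifting up), others induce
in a **binary** fashion (ON and OFF subpopulations coexist transiently, some
cells lagging for hours). `galnet` implements a personalized gene-network
model of this process: it simulates the stochastic induction dynamics,
analyses flow-cytometry-like readouts, and infers, per allele, the two
parameters that govern the phenotype.

## The model

Four genes are tracked (*GAL1*, *GAL3*, *GAL80*, and a P<sub>GAL1</sub>
fluorescent reporter). Each promoter is a telegraph switch between an OFF
(leaky transcription, rate α) and an ON state (full transcription, α + Δα),
with switching rates driven by the regulators' dimers:

    k_off,i = k0_off · (Gal80p / K80)^(2 n_i)
    k_on,i  = k0_on  · ((Gal1p*/K1)² + (Gal3p*/K3)²)^(n_i)
    Galp*   = Galp · ([gal]/K_gal) / (1 + [gal]/K_gal)

where n_i is the number of strong Gal4p binding sites of promoter i and
Galp\* the count of galactose-activated molecules. mRNA and protein follow
birth–death kinetics (transcription α(+Δα), decay β; translation γ, decay μ),
and the reporter additionally matures at rate ν. Populations of independent
cells are simulated with the exact Gillespie algorithm: burn-in to the
stationary state at [gal] = 0 (where k_on ≡ 0), then induction at t = 0.

Only two GAL3-related quantities are identifiable from induction curves:

* the **GAL3 strength** ρ_Gal3 = α₃γ₃ / (β₃μ₃K₃) — the mean basal Gal3p
  level in units of the effective constant K₃, and
* **K_gal** — the galactose concentration at which half of Gal3p/Gal1p is
  activated.

High ρ_Gal3 gives every cell enough potential inducers to fire the feedback
immediately (gradual response); low ρ_Gal3 makes the first promoter
activation a rare event whose waiting time varies cell to cell (binary
response, lag anticorrelated with the cell's Gal1p+Gal3p reserve). A strain
is "fitted" by simulating inducibility (fraction of ON cells over time) on a
2D logarithmic (ρ_Gal3, K_gal) grid at three galactose concentrations and
minimizing a global χ² against the measured curves.

## Worked example

```python
import numpy as np
from galnet import default_parameters, default_time_grid, study_inducibility
from galnet.inference import FitGrid, grid_fit
from galnet import meanfield as mf

params = default_parameters()

# the two reference regimes at [gal] = 0.5%
print(mf.classify_response(params.with_gal3(rho=140.0, kgal=0.055), 0.5,
                           n_cells=600, seed=1))   # -> 'gradual'
print(mf.classify_response(params.with_gal3(rho=40.0, kgal=0.055), 0.5,
                           n_cells=600, seed=1))   # -> 'binary'

# infer (rho_Gal3, Kgal) back from synthetic curves of the weak allele
gen = params.with_gal3(rho=40.0, kgal=0.055)
obs = study_inducibility(gen, (0.05, 0.1, 0.5), default_time_grid(),
                         n_cells=1000, seed=2)
fit = grid_fit(obs, FitGrid.default(), params, n_cells=250, seed=3)
print(round(fit.rho_hat, 1), round(fit.kgal_hat, 4))  # -> 40.0 0.055
```

The two printed labels say that, with all GAL3-independent parameters held
fixed, lowering the GAL3 strength from 140 to 40 switches the population
phenotype from gradual to binary. The fit recovers the generating
coordinates exactly: both reference strengths (40 and 140) and the reference
K_gal (0.055) lie on the default grid axes, so a correct fit returns them
verbatim, and the grid spacing (about 28% in ρ, 27% in K_gal per cell) is
the resolution the grid-χ² method claims.

## Analysis scripts

`analysis/` contains the narrative drivers, each writing tables under
`results/`:

1. `01_simulate_regimes.py` — gradual vs binary single-cell trajectories,
   ON-fraction curves, lag-vs-inducer statistics.
2. `02_landscape.py` — gradual/binary phenotypic landscape over the
   (ρ_Gal3, K_gal) plane and the deterministic bistability scan.
3. `03_synthetic_study.py` — synthetic multi-plate cytometry study and the
   full event pipeline (gating, plate ANOVA correction, mixture statistics).
4. `04_fit_alleles.py` — grid-χ² fits for three synthetic alleles under
   alternative fixed-parameter sets, with allele coordinates relative to the
   reference.
5. `05_holdout_validation.py` — no-refit prediction at the untrained
   concentration 0.2%.

A `galnet` command-line tool exposes the same steps
(`galnet simulate|landscape|synth|gate|stats|fit|report`).

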