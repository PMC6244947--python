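# rtktraffic

Bayesian inference of receptor tyrosine kinase (RTK) trafficking kinetics
from end-point abundance and pulse-chase surface-biotinylation data.

## The problem

Targeted kinase inhibitors often trigger *RTK reprogramming*: coordinated,
non-genetic shifts in the abundances of receptors such as Axl, Met, EGFR
and Her2 that blunt drug response. A measured abundance change says
nothing about *how* it arose — more synthesis, less degradation, slower
endocytosis, or reduced ectodomain shedding all move lysate levels. This
package dissects such changes mechanistically with a three-compartment
mass-action model of receptor traffic:

    dr_i/dt = k_end r_s − (k_rec + k_deg) r_i
    dr_s/dt = P_syn + k_rec r_i − (k_end + k_shed) r_s
    dr_f/dt = k_shed r_s

where `r_s`, `r_i`, `r_f` are surface, internal and shed (supernatant)
receptor pools, `P_syn` (molecules cell⁻¹ min⁻¹) is net synthesis, and
`k_deg`, `k_end`, `k_rec`, `k_shed` (min⁻¹) are first-order rates for
degradation, endocytosis, recycling and shedding. Pulse-chase
(biotinylation) experiments follow only the labelled pool, so their
variant of the model drops `P_syn`.

The five rates of one receptor under one condition are estimated jointly
from 24-h lysate/supernatant levels (molecules/cell, converted from
bead-ELISA readouts by 5PL standard curves) and 5–90-min pulse-chase time
courses, via a log-Gaussian likelihood, data-derived and
literature-anchored priors, multi-start pattern-search optimization and
4-chain adaptive Metropolis MCMC with Gelman–Rubin diagnostics.
Downstream, single-parameter substitution attributes each treatment's
predicted lysate fold change to individual trafficking steps, and PCA
over (receptor × parameter) matrices summarizes treatment signatures.

A first-class synthetic-data generator reproduces the study design
(n = 12 end-point and n = 18 time-course replicates, log-normal noise,
LLOQ censoring, 5PL curves) with known ground truth, so the whole
pipeline is testable end to end.

## Worked example

```python
from rtktraffic import RateParams, CompartmentState, simulate_full, steady_state

params = RateParams(P_syn=100, k_deg=0.01, k_end=0.01, k_rec=0.01, k_shed=0.001)
ss = steady_state(params)
print(f"steady state: r_s = {ss.r_s:.2f}, r_i = {ss.r_i:.2f} molecules/cell")
traj = simulate_full(params, CompartmentState(r_s=ss.r_s, r_i=ss.r_i), [1440])
print(f"shed after 24 h: {traj.r_f[0]:.0f} molecules/cell "
      f"({traj.r_f[0] / traj.r_t[0]:.0%} of lysate)")
```

prints

```
steady state: r_s = 16666.67, r_i = 8333.33 molecules/cell
shed after 24 h: 24000 molecules/cell (96% of lysate)
```

i.e. with these rates a cell holds 25,000 receptors at steady state and
releases nearly one lysate-equivalent of ectodomain per day.

The full analysis sequence lives under `analysis/` as numbered drivers:

```bash
python analysis/01_simulate_study.py 1    # synthetic control + Mek-like study
python analysis/02_standard_curves.py 1   # 5PL calibration and LLOQ
python analysis/03_fit_conditions.py 1    # two-stage Bayesian fits (writes results/pipeline/)
python analysis/04_attribution_report.py  # which rate explains the change
python analysis/05_pca_report.py          # treatment-signature PCA
```

The same stages are available as a CLI
(`rtktraffic simulate|quantify|fit|predict|pca|run-all|validate`).

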