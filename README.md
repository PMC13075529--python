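# aacea — cost-effectiveness of ritlecitinib for severe alopecia areata in Japan

`aacea` implements a lifetime Markov cohort model comparing **ritlecitinib
50 mg once daily** against **no treatment** for adults and adolescents with
alopecia areata (AA) and ≥ 50% scalp hair loss in Japan, from a societal or
payer perspective.  It is aimed at health-economics analysts who want a
tested, scriptable, fully parameterized re-implementation of this kind of
decision model rather than a spreadsheet.

## The model

Health states are the four Severity of Alopecia Tool strata
(SALT ≤ 10, 11–20, 21–49, ≥ 50), crossed with on/off-treatment status, plus
an absorbing Dead state.  Cycles are 12 weeks with half-cycle correction;
costs and QALYs are discounted at 2%/year.  Trial-phase occupancy
(weeks 0–48) is imposed from the observed cross-sectional SALT distributions
of the pivotal phase 2b/3 trial; afterwards:

* responders (SALT ≤ 20 at week 48) continue treatment, leaving at a
  constant per-cycle hazard `d = 1 − (1 − 0.131)^(12/48)` derived from the
  cumulative 13.1% discontinuation by week 48, and worsen one SALT stratum
  on exit;
* off-treatment patients worsen gradually (default one stratum per 52
  weeks, a configurable knob), except untreated patients who reached
  SALT ≤ 10 by week 24 — spontaneous remission — who never worsen;
* background mortality follows an age × sex life table, identical in both
  arms.

Outcomes per arm are discounted drug-acquisition costs, monthly HCRU costs
by stratum, a one-off expected adverse-event cost (Σ incidence × unit cost),
human-capital productivity losses
(employment × hours × wage × WPAI overall impairment `A + (1−A)P`), QALYs
from TTO-derived stratum utilities, and comparative results
ICER = ΔC/ΔE and NMB = λ·ΔE − ΔC at λ = 5,000,000 JPY/QALY.

Sensitivity analysis: one-way ±20% sweeps (tornado), and probabilistic
sensitivity analysis with moment-matched Beta (probabilities, utilities),
Gamma (costs, wages, hours) and Dirichlet (SALT distributions) draws at
SE = 10% of base values, with CE-plane and CEAC outputs.

Because the official Japanese abridged life table and the claims database
behind the HCRU costs are not redistributable, `aacea.synthetic` generates
statistically similar stand-ins: a Gompertz–Makeham life table calibrated to
Japanese-like life expectancy, and claims-like stratified cost records for
the weighted-average back-calculation.

## Worked example

```python
from aacea import load_model_config, make_life_table, run_base_case

p = load_model_config()            # packaged base-case parameter file
p.life_table = make_life_table()   # synthetic Japanese-like mortality
res = run_base_case(p)             # simulate both arms, societal view
print(f"dQALY {res.delta_qaly:.3f}  dCost {res.delta_cost:,.0f} JPY  "
      f"ICER {res.icer:,.0f} JPY/QALY  NMB {res.nmb:,.0f} JPY")
```

prints

```
dQALY 1.001  dCost 5,018,378 JPY  ICER 5,013,863 JPY/QALY  NMB -13,875 JPY
```

i.e. ritlecitinib gains about one quality-adjusted life year per patient at
an incremental lifetime cost of about 5.0 million JPY, an ICER at the
Japanese willingness-to-pay threshold of 5 million JPY/QALY (treated/
untreated lifetime QALYs 17.46 and 16.45).  The same run from a payer
perspective (excluding productivity losses) raises the ICER to about
6.9 million JPY/QALY.

The same analyses are available from the shell:

```sh
aacea base --outdir out/base            # component costs, QALYs, ICER, traces
aacea base --perspective payer --outdir out/payer
aacea owsa --outdir out/owsa            # tornado table
aacea psa  --seed 1 --n-iter 10000 --outdir out/psa   # CE plane, CEAC
aacea synth --outdir out/synth          # synthetic life table + claims
```

All outputs are plain CSV/JSON, with a manifest per run.

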