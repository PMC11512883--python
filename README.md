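# radecon

Cost-effectiveness and budget-impact modelling of minimally invasive **rectus
abdominal diastasis (RAD) repair** with mesh implant versus **no intervention**
(standard of care, SOC), from both the Italian NHS and the societal
perspective.

RAD — separation of the rectus abdominis muscles along the linea alba —
affects roughly one in three women after pregnancy and commonly causes
urinary incontinence and lower-back pain. Surgical repair is rarely
reimbursed, so the decision problem is whether the one-off surgical cost is
justified by lifelong quality-of-life gains and avoided out-of-pocket and
productivity costs. `radecon` is aimed at health-economics analysts who want
this evaluation as a reproducible, tested pipeline rather than a spreadsheet.

## The model

A three-state cohort Markov model with 1-year cycles over a lifetime horizon:

```
RAD (first year) ──► RAD (following years) ──► stays
        │                     │
        ▼                     ▼
              Death (general female mortality)
```

Every woman starts at age 43 in *RAD (first year)*; after one cycle all
survivors move to *RAD (following years)*. Mortality comes from a female
life table and is strategy-independent, so the strategies differ only in
costs and utilities:

* **Utilities** (EuroQol 5D-5L): u = 0.69 under SOC in every state; 0.87 in
  the first post-surgical year, 0.91 thereafter.
* **Costs by payer**: patient out-of-pocket expenses and productivity losses
  (human-capital approach, zeroed from retirement age 67) from a
  socio-economic e-survey; NHS costs only for the repair pathway (two
  specialist visits, the DRG tariff and the expected complication cost
  `Σ rateᵢ × unit_costᵢ ≈ 174 €`, all charged in the first cycle).
* **Outcomes**: discounted lifetime costs C and QALYs E per strategy; the
  incremental cost-utility ratio `ICUR = ΔC/ΔE` (or a dominance flag), the
  cumulative incremental net monetary benefit `INMB(t) = λ·ΔE(≤t) − ΔC(≤t)`
  at willingness-to-pay λ, probabilistic sensitivity analysis (gamma costs,
  beta utilities/percentages, CEAC), one-way tornado analyses, and a
  five-year dynamic budget-impact model with yearly incident cohorts of
  105,000 women and a 2→10% adoption ramp.

Discounting is 3 %/year on costs and QALYs. The per-cycle discount weight is
configurable (`exponential` (1+r)^−t or `simple` 1/(1+rt)); the bundled
default is the convention selected by the `calibrate-discounting` search
(see `docs/methods.md`).

## Worked example

```bash
$ radecon cea --out-dir out
INFO radecon: nhs perspective: dC=5,104 EUR, dE=6.14 QALYs, ICUR 831 EUR/QALY
INFO radecon: societal perspective: dC=-17,438 EUR, dE=6.14 QALYs, dominant

$ radecon bia --out-dir out
INFO radecon: BIA: total incremental 184,222,178 EUR (160,778,300 EUR NHS, share 87.27%), incremental QALYs 14897.31

$ radecon psa --n-draws 2000 --seed 7 --out-dir out
INFO radecon: PSA n=2000 seed=7: mean dC(NHS)=5,095 EUR, mean dE=6.17 QALYs
INFO radecon: CEAC at reference WTP 25,000: NHS 0.954, societal 0.965
```

Reading the numbers: from the NHS point of view repair adds 5,104 € per
patient (visits + DRG + expected complications) and 6.14 discounted QALYs
over her remaining lifetime, i.e. about 831 € per QALY gained — far below
any willingness-to-pay threshold in use. From the societal point of view
repair *saves* 17,438 € per patient while adding the same QALYs, so it is
dominant. Scaling up adoption from 0 % to 10 % over five years costs society
≈ 184 M€ (87 % borne by the NHS, ≈ 351 € per eligible patient) because the
savings accrue over decades while the surgical outlay is immediate; the PSA
shows the conclusion is robust across parameter uncertainty.

Every command writes delimited tables, a JSON summary and a run manifest
(config, seed, flags, outputs) into `--out-dir`. The full Python API
(`radecon.run_cea`, `radecon.run_psa`, `radecon.run_bia`, ...) exposes the
same computations; the configuration schema is documented in
`docs/config_schema.md`.

Because the questionnaire microdata and the national life table are not
redistributable, the package ships a synthetic-data module: a
questionnaire-record generator anchored to the published group summaries and
a Gompertz life-table generator with Italian-female magnitudes
(`radecon synth-survey`, `radecon synth-lifetable`). The bundled
`life_table_synthetic_italian_female.csv` is such a synthetic stand-in.

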