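# Methods

## Decision problem and model structure

The package compares two management strategies for women with rectus
abdominal diastasis (RAD) after pregnancy: minimally invasive surgical
repair with mesh implant (`REPAIR`) versus no intervention (`SOC`). The
vehicle is a cohort state-transition (Markov) model with three states —
*RAD, first year*, *RAD, following years*, *dead* — and 1-year cycles from a
start age of 43 to a closure age of 110. The first-year state exists to
carry the transiently different post-surgical costs (physiotherapy,
postural training, paid assistance) and utility; after one cycle all
survivors are in the following-years state. SOC has identical costs and
utility in both alive states, so the distinction is inert for that arm.

Key structural assumptions:

* **Mortality is strategy-independent.** Death follows the general female
  annual probabilities q(age) of a life table; neither RAD nor its repair
  changes survival. A direct consequence, tested as an invariant: whenever
  repair utilities exceed the SOC utility, ΔQALY > 0 for *any* life table.
* **Complications are first-cycle costs, not states.** Post-surgical
  complications (recurrence 0.4 %, hematoma 5.4 %, posterior rectus-sheath
  disruption 3.5 %, seroma 3.1 %, superficial surgical-site infection
  1.9 %) enter as an expected cost Σ rateᵢ·unit_costᵢ ≈ 174 € added to the
  NHS first-cycle bundle (22 € pre-visit + 16.20 € post-visit + 4,892 € DRG
  → 5,104 € in total). Sheath disruption is priced at the recurrence
  management cost (similar re-intervention).
* **Human-capital productivity costing.** Lost working time is valued at
  the average hourly wage of the professional category (annual wage /
  1,720 h; 8 h per whole day lost) and zeroed from the first cycle whose
  attained age reaches the retirement age of 67.

## Accrual and discounting conventions

Costs and QALYs accrue on the occupancy alive at cycle start; cycle 0 is
undiscounted by default; a half-cycle correction (averaging start- and
end-of-cycle occupancy) is available but off. Two per-cycle discount
weights are implemented: exponential (1+r)^−t and simple 1/(1+r·t), both at
r = 3 %/year.

The published lifetime totals this model is calibrated against (societal
costs 64,115/46,541 €, QALYs 19.55/25.75) imply ≈ 28.3 discounted
life-years from age 43 — more than an exponentially discounted annuity at
3 % can produce over any survival curve from that age. The generating
convention is therefore not identifiable from the text, and the package
ships a `calibrate-discounting` search over all eight combinations of
{exponential, simple} × {cycle 0 discounted or not} × {half-cycle on/off}.
Against the bundled parameters and life table the best match is **simple
discounting, cycle 0 undiscounted, no half-cycle correction**, reproducing
all four totals within 0.9 %; this convention is the bundled default, and
the search log is written as a run artifact. All dominance/ICUR logic and
the structural invariants are convention-independent.

## Cost parameters

Patient-borne costs come from a socio-economic e-survey summarised per
group (no intervention, repair ≤ 1 year, repair > 1 year). Monthly items
(expenses for incontinence and lower-back pain management, visits/
transport/meals, paid assistance, productivity losses for visits and
malaise) contribute 12× their monthly mean per cycle; one-off totals for
resolved/unresolved problems are charged once in the first cycle. Two
conventions follow from how the survey means were published:

* Group means are over **all** respondents (zeros included), so they are
  used as-is, with no re-weighting by problem prevalence.
* For the repair arm only the ≤ 1-year column feeds the model (the > 1-year
  column repeats largely the same historical expenses; using both would
  double-count). Both "resolved" and "not resolved" one-off totals are
  charged, as each is already a mean over the whole column.

This yields per-cycle societal costs of 2,761.52 € (first year, incl.
112.28 € one-offs) and 2,649.24 € for SOC, and 10,027.89 € / 1,584.24 € for
repair (first year includes the 5,104 € NHS bundle and 365.86 € one-off
out-of-pocket). The published budget-impact table's *absolute*
current-scenario totals imply a SOC first-year cost of ≈ 5,407 € — about
twice the sum of the published monthly items and inconsistent with the same
table's incremental columns and with the published year-8 per-patient
crossover (21,285 € SOC vs 21,102 € repair), both of which match the
2,761/2,649 stream used here. The package follows the internally consistent
stream; only the absolute scenario totals differ.

Unit costs are stored in 2022 euros; each item carries a multiplicative
uplift factor (default 1 — the bundled complication costs already reproduce
the 174 € expectation, so they are treated as already at the analysis price
level) and a citation key, with a completeness check (`uncited_parameters`)
enforced in the tests.

## Sensitivity analyses

**PSA.** Parameters are sampled independently: gamma for positive costs and
beta for utilities and percentages, both moment-matched (gamma: shape
m²/s², scale s²/m; beta: ν = m(1−m)/s² − 1). Where no source SD exists, a
±20 % variation is interpreted as the half-width of a 95 % interval
(s = 0.2 m/1.96); the alternative s = 0.2 m is a switch. The complication
expectation is recomputed inside each draw from the sampled rates and unit
costs. Draw order is fixed (utilities, complication rates, complication
costs, tariffs, cost items in configuration order; n variates per parameter
from a single seeded `numpy` Generator), making runs bit-reproducible.
CEAC(λ) is the fraction of draws with λ·ΔE − ΔC > 0. With these
distributional choices the NHS acceptability curve crosses 0.5 near the
deterministic ICUR (high hundreds of €/QALY) and exceeds 0.85 by
2,000 €/QALY; the exact crossing depends on source SDs that are not
published, so only the curve's shape — ≈ 0 at λ = 0, high by the low
thousands, ≈ 1 societal everywhere — is asserted.

**OWSA.** Each parameter in turn to mean ± 20 % (or ± SD where provided),
reporting the NHS ICUR, or the incremental cost under the societal
perspective where baseline dominance makes the ICUR sign-unstable; entries
are sorted by bar width. With baseline parameters the widest NHS bars are
the intervention DRG tariff and the following-years repair utility, and
societal dominance survives every single-parameter variation.

## Budget impact

A dynamic model over a 5-year window: each year an incident cohort of
105,000 women (393,997 newborns / fecundity 1.25 → 315,198 mothers; one in
three with RAD; rounded to the nearest 1,000) enters and is split by that
year's repair adoption fraction (current scenario 0 %; future scenario 2,
4, 6, 8, 10 %). Every cohort is followed through the Markov engine's
undiscounted per-cycle costs within the window only (no terminal value);
yearly totals sum over active cohorts. Financial streams and the mirrored
QALY streams are undiscounted. User counts are displayed un-thinned while
accruals are mortality-thinned (`thin_mortality=False` disables thinning;
at these ages the difference is < 0.05 %).

Two QALY-accrual variants are exposed because the published incremental
QALY total (16,155) is only consistent with applying the steady-state
utility gain (0.91 − 0.69) from cohort entry: `first_year_utility=True`
(default, engine-consistent: 0.87 in the entry year, ≈ 14,900 QALYs) and
`False` (calibration variant, ≈ 16,157). Costs, user counts and the NHS
share are identical between variants.

## Synthetic data

The survey generator reproduces the e-survey's structure: group sizes
521/94/77, per-group problem-status multinomials taken from the published
counts, and per-group cost-item means anchored to the published summary.
Individual amounts are zero-inflated gamma (default 50 % non-spenders,
shape 1.2 among spenders) — only the mean is anchored; the dispersion and
zero fraction are free knobs since no SDs were published, so tests assert
mean-level recovery only. The generator does not reproduce the registry's
complication follow-up (rates enter the model directly), EuroQol item-level
responses, recall error, or any correlation between expenses and statuses;
passing recovery tests therefore validate the costing pipeline's
arithmetic, not survey realism.

The life-table generator is Gompertz, q(x) = min(1, a·e^{bx}) with q forced
to 1 at the closure age. Defaults a = 10⁻⁵, b = 0.10 were fixed once to give
e(43) ≈ 43.5 years, q(43) ≈ 7.4·10⁻⁴ and q(80) ≈ 3 % — the magnitude of a
recent Italian female period table. It has no infant-mortality hump, which
is irrelevant for a model starting at 43. The bundled
`life_table_synthetic_italian_female.csv` is generated by this function.

## Numerical choices and problem sizes

* Occupancy conservation is maintained to < 10⁻¹² per cycle; the engine is
  cross-checked against an independent path-enumeration oracle at short
  horizons.
* ICUR is never formed when ΔE = 0 (explicit undefined signal) and never
  reported as a negative ratio under dominance.
* Printed-value comparisons round half away from zero at the displayed
  precision (euros 0 decimals, QALYs 2, fractions 4).
* Default problem sizes: lifetime horizon 67 cycles; PSA 10,000 draws in
  the acceptance run and 2,000 in the test suite; survey recovery at
  5,000/10,000 respondents. A full acceptance run takes well under a
  minute on one core.

## Known limitations

* The life table and wage table are synthetic stand-ins; absolute lifetime
  totals inherit their (documented, small) deviation from national data.
* Parameters are sampled independently in the PSA; no correlation structure
  between survey items is modelled.
* No microsimulation: complications and symptom trajectories are not
  individual-level states, and prevalent (pre-existing) RAD cases are
  outside the budget-impact model, which follows incident cohorts only.
* No EVPI computation and no plotting; all figures' underlying data are
  exported as delimited tables.
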