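# Configuration file schema

A model configuration is a single YAML mapping with five sections. Unknown
keys are rejected anywhere; every amount is in euros at the analysis price
level (2022 in the bundled baseline). Monthly amounts are €/month; one-off
amounts are €/event. The bundled baseline lives at
`src/radecon/data/default_config.yaml` and loads via
`radecon.default_config()`.

## `econ`

| key | type | meaning |
|---|---|---|
| `discount_rate` | fraction/year, 0 ≤ r < 1 | applied to costs and QALYs |
| `cycle_length_years` | int, fixed `1` | Markov cycle length |
| `start_age_years` | int | cohort age at model start |
| `retirement_age_years` | int | productivity costs zeroed from this age |
| `max_age_years` | int | closure age; must satisfy start < retirement ≤ max |
| `wtp_grid_eur_per_qaly` | list of € ≥ 0 | CEAC evaluation grid |
| `wtp_reference_eur_per_qaly` | € > 0 | WTP for the INMB series |
| `discounting` | `exponential` \| `simple` | (1+r)^−t vs 1/(1+rt) |
| `discount_cycle0` | bool | discount the first cycle too |
| `half_cycle_correction` | bool | average start/end occupancy |
| `sources` | map field → citation | citation keys (see below) |

## `utilities`

`soc`, `repair_first_year`, `repair_following_years` — utility weights in
[0, 1] per year — plus a `sources` map.

## `cost_items` (list)

Each item:

| key | values |
|---|---|
| `label` | free text |
| `strategy` | `SOC` \| `REPAIR` |
| `payer` | `nhs` \| `out_of_pocket` \| `productivity` |
| `recurrence` | `monthly_recurring` \| `one_off_first_cycle` |
| `state_scope` | `first_year` \| `following_years` \| `both` |
| `amount_eur` | ≥ 0 (€/month if monthly, €/event if one-off) |
| `sd_eur` | optional source-reported SD (else the ±20 % rule applies in PSA) |
| `uplift_factor` | > 0, default 1 (price-year inflation) |
| `source` | citation key (required for audit completeness) |

## `complications` (map name → entry)

`rate` (fraction in [0, 1]), `unit_cost_eur` (≥ 0), optional `rate_sd` /
`cost_sd_eur`, `uplift_factor`, `source`. The engine charges
Σ rate × unit_cost × uplift once, in the repair arm's first cycle.

## `nhs_tariffs` (map name → entry)

`amount_eur`, optional `sd_eur`, `source`. The repair pathway requires the
keys `pre_intervention_visit`, `post_intervention_visit` and
`intervention_drg`.

## Citation keys

Every numeric parameter must be traceable: list-type entries carry an
inline `source` string, scalar sections use their `sources` map.
`radecon.parameters.uncited_parameters(cfg)` returns the dotted names of
anything missing; the test suite requires it to be empty for the bundled
baseline.

## Life table file

Separate from the config: a CSV with header `age,q`, one row per integer
age, contiguous ascending, q ∈ [0, 1]. Tables ending before
`max_age_years` are padded with q = 1 (with a warning); the final q is
always forced to 1.
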