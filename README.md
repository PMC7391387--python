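# osteorisk

Analytic chain for building a country-specific fracture-risk model from a
small-area hip-fracture survey:

* **registry** — case data model, eligibility filters (study window,
  residence, minimum age, low-energy mechanism, non-pathological) and
  same-site deduplication, with a full removal audit trail.
* **incidence** — age/sex-band and crude rates per 100,000 person-years
  with exact (Garwood, chi-square) Poisson confidence intervals, plus the
  care-pathway ascertainment breakdown.
* **lifetable** — piecewise-constant hazard schedules over age and
  closed-form event-free survival.
* **frax** — MOF (major osteoporotic fracture) incidence imputed from hip
  incidence via age/sex ratio tables, relative-risk multipliers, and
  closed-form integration of competing fracture and death hazards into
  10-year and remaining-lifetime first-fracture probabilities.
* **projections** — expected fracture counts by calendar year from fixed
  rates applied to population pyramids, with Poisson uncertainty bands.
* **synthetic** — a deterministic packaged district fixture (registry +
  population reconstructed from printed marginals, with labelled decoy
  records) and seeded Poisson registry simulation for parameter-recovery
  testing.

## CLI

```sh
# write the packaged fixture (cases, population, mortality, ratios)
osteorisk simulate --model fixture --out-dir data/

# incidence table with exact 95% CIs
osteorisk incidence --cases data/cases.csv --population data/population.csv \
    --alpha 0.05 --min-age 40 --out table.csv

# 10-year MOF probability, prior-fracture relative risk 1.85
osteorisk frax --hip-rates hip.csv --mortality data/mortality.csv \
    --ratios data/ratios.csv --age 70 --sex female --horizon 10 \
    --rr 1.85 --outcome mof

# remaining-lifetime hip fracture probability from age 50
osteorisk lifetime --hip-rates hip.csv --mortality data/mortality.csv --start-age 50

# burden projection under fixed rates
osteorisk project --rates hip.csv --pyramids pyramids.csv --min-age 50 --out proj.csv

# full pipeline with a YAML config (CLI flags override file values)
osteorisk run --cases data/cases.csv --population data/population.csv \
    --mortality data/mortality.csv --ratios data/ratios.csv --out-dir out/
```

Rate CSVs carry a `units` column (`per_100k` or `per_person_year`); band
CSVs use `sex, age_lo, age_hi` with an empty `age_hi` marking the open
terminal band (e.g. 90+). The shipped MOF/hip ratio table is illustrative
and synthetic — supply measured ratios for real use.

## Modelling conventions

First fracture is the absorbing event; no post-fracture excess mortality;
hazards are piecewise-constant on the input bands (all integrals closed
form); truncation at age 110; person-years = census headcount x 1 year.
Display rounding (two-stage half-up for per-100,000 figures, one decimal
below 1) is a formatting concern only — internal values are never rounded.
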