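# adcea

Patient-level microsimulation and cost-effectiveness analysis (CEA) of a
hypothetical disease-modifying treatment for Alzheimer disease, from mild
cognitive impairment (MCI) through severe dementia and death.  The package
computes incremental cost-effectiveness ratios (ICERs) under six analytic
perspectives (A–F) that progressively add patient non-health-care costs,
caregiver health-care costs, caregiver quality-of-life effects, and
caregiver productivity costs, plus one-time-vs-repeated treatment pricing
sweeps.

## Model sketch

* **Cohort** — synthetic observational-cohort-like MCI patients (MMSE 24–30 at entry) with
  configurable age/sex/CDR-SB/NPI distributions and one informal caregiver
  each (`adcea.cohort`).
* **Progression** — CDR-SB worsens at stage-specific annual rates; MMSE is
  coupled linearly to the CDR-SB increment; dementia conversion at a
  CDR-SB threshold; severity staged from MMSE bands (`adcea.progression`).
  Treatment reduces the CDR-SB change rate by 25 % while on drug, with a
  10 %/year discontinuation hazard and a hard stop at moderate dementia.
* **Hazards** — life-table mortality with a proportional-hazards
  adjustment in cognition and decline rate; time-at-stage/age/sex-adjusted
  institutionalization (absorbing) (`adcea.hazards`).
* **Utilities** — additive EQ-5D-style patient utility regression;
  caregiver utility by patient MMSE band, reverting to age-specific
  population norms at institutionalization or death (`adcea.utility`).
* **Costs** — published per-stage monthly costs for patient health care,
  patient non-health-care, caregiver health care and caregiver
  productivity; $16,000/year drug price or one-time pricing
  (`adcea.costs`).
* **CEA engine** — paired arms simulated under common random numbers;
  perspectives composed as post-processing of shared trajectories; ICERs
  with dominance labelling (`adcea.cea`).

Several upstream regression coefficients are proprietary and unpublished;
where that is the case the implementation uses transparent, documented
placeholder defaults, all overridable in the run configuration (see
docstrings in `adcea.progression` and `adcea.hazards`).

Note on the patient utility regression: the published table typesets the
regression with "×" signs between terms, which is dimensionally
incoherent; the standard additive linear reading is implemented
(0.408 + 0.010·MMSE − 0.04·NPI − 0.159·institutionalized +
0.051·lives-with-caregiver, clamped to [0, 1]).

## Command line

```sh
adcea show-config                      # print the fully-resolved defaults (YAML)
adcea scenarios --seed 1 --n 2000 --outdir results   # perspectives A-F + one-time sweep
adcea simulate --seed 1 --n 100 --out traj.csv       # per patient-cycle-arm trajectories
```

`scenarios` writes `results.txt` (formatted tables, ICERs rounded to the
nearest $1,000), `results.csv` (raw values) and `results.json` (full
detail, seed and config hash).  Any subset of the configuration can be
overridden from a YAML/JSON file passed via `--config`; an empty file
means "all defaults".

## Layout

```
src/adcea/
  cohort.py        synthetic baseline cohorts + CSV I/O
  progression.py   CDR-SB/MMSE/NPI progression, staging, treatment rules
  hazards.py       mortality and institutionalization hazards (+ bundled life table)
  utility.py       patient/caregiver utilities, QALY accrual
  costs.py         cost table, drug pricing, cost accrual
  cea.py           paired simulation, perspective composition, ICERs
  config.py        run configuration (pydantic), YAML/JSON loading, hashing
  report.py        table rendering, CSV/JSON serialization
  cli.py           click-based CLI
  data/            life_table.csv, population_norms.csv
```
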