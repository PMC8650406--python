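# trd-cea

A Markov cohort cost-utility model comparing electroconvulsive therapy
(ECT) — with and without maintenance ECT — against intranasal
esketamine for adults with treatment-resistant depression (TRD), in
the UK setting (GBP 2019).

## Who this is for

Health economists and psychiatry researchers who want a transparent,
tested, fully configurable implementation of the ECT-vs-esketamine
cost-utility comparison: every transition probability, utility, wage,
employment fraction and per-state cost is typed, validated
configuration; the cohort engine, costing rules, scenario catalogue
and an independent microsimulation oracle are importable library code.

## The model in brief

A cohort enters depressed at age 45 and is followed for 35 years in
30-day cycles through states A (depressed, index treatment), B
(remission on the treatment's follow-up schedule — a six-month tunnel
for esketamine, an open-ended maintenance-ECT tunnel in the
maintenance variant), C (relapse, re-treatment), D (treatment failed,
standard care), E (remission from standard care), F (post-esketamine
remission) and death. Source-trial proportions are converted to
per-cycle probabilities via the constant-hazard equations
r = −ln(1−P)/t and p = 1 − exp(−rt). Costs follow a societal
perspective (direct healthcare + productivity loss by the
human-capital approach + informal care + travel) with a healthcare
perspective switch; utilities are 0.81/0.57 QALY per year for
remission/depression. Strategies are compared by incremental cost per
QALY against the NICE £20,000–£30,000 band. Full model description:
[docs/methods.md](docs/methods.md).

## Worked example

```python
from trd_cea import (Arm, Perspective, Variant,
                     default_parameters, incremental, run_arm)

bundle = default_parameters()          # the full published input table
ect = run_arm(Arm.ECT, Variant.MAIN, Perspective.SOCIETAL, bundle)
esk = run_arm(Arm.ESKETAMINE, Variant.MAIN, Perspective.SOCIETAL, bundle)
ce = incremental(ect, esk)
print(f"ECT  {ect.total_cost:,.0f} GBP / {ect.total_qaly:.2f} QALY")
print(f"esk  {esk.total_cost:,.0f} GBP / {esk.total_qaly:.2f} QALY")
print(ce.verdict.value, f"(delta {ce.delta_cost:,.0f} GBP, {ce.delta_qaly:.2f} QALY)")
```

prints

```
ECT  321,649 GBP / 9.89 QALY
esk  327,779 GBP / 9.46 QALY
ECT_DOMINATES (delta -6,130 GBP, 0.43 QALY)
```

ECT is cheaper and yields more QALYs than esketamine — it dominates —
under the default conventions (3.5%/yr discounting with per-cycle
compounding). In the maintenance variant, ECT followed by maintenance
ECT gains 1.50 QALYs over esketamine at 43,068 GBP extra, an ICER of
£28,636/QALY: cost-effective at the £30,000 threshold but not at
£20,000. Note that the published 35-year tables carry an effectively
null discount (docs/methods.md derives this); with discounting
disabled the same code reproduces the published no-discounting rows to
within 0.1% on costs.

The numbered drivers replay the full analysis and write their tables
under `results/`:

```bash
python analysis/01_rate_conversions.py     # source trials -> per-cycle probabilities
python analysis/02_base_case.py            # all arms/variants/perspectives + traces
python analysis/03_sensitivity_tables.py   # scenarios 1a-9b, both variants
python analysis/04_microsim_validation.py  # cohort vs individual-level oracle
python analysis/05_parameter_recovery.py   # synthetic trials -> input recovery
```

Configuration is a YAML file (`src/trd_cea/data/table1.yaml` ships the
published defaults); `load_config`/`save_config` round-trip any
override losslessly and `validate` reports invariant violations.

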