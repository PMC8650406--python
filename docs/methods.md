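# Methods

## The decision problem

Adults with treatment-resistant depression (TRD — major depression that
has failed at least two adequate antidepressant trials) can be offered
electroconvulsive therapy (ECT) or intranasal esketamine plus an oral
antidepressant. This package implements a cost-utility comparison of
the two strategies for the UK setting: a discrete-time Markov cohort
model tracking a cohort from age 45 for 35 years in 30-day cycles,
accruing costs (GBP 2019) and quality-adjusted life-years (QALYs), and
reporting incremental cost-effectiveness ratios (ICERs) against the
20,000–30,000 GBP/QALY willingness-to-pay band.

## Model structure

Health states (expanded per arm):

- **A** — depressed, first course of the index treatment.
- **B** — in remission on the index treatment's follow-up schedule.
  Under ECT (main variant) this is a single state: remission on
  standard antidepressant treatment, relapse 0.108/cycle. Under the
  maintenance variant, remitters receive maintenance ECT (M-ECT) in a
  two-phase tunnel (month 1, then ongoing) with relapse 0.0300/cycle.
  Under esketamine, B is a six-month tunnel (months 1, 2–5, 6) with
  phase-specific drug schedules and costs and relapse 0.0724/cycle;
  survivors of month 6 graduate to F.
- **C** — depressed after relapse from B or F; re-treated with the
  arm's therapy at the same remission probability as A (0.696 ECT,
  0.392 esketamine).
- **D** — depressed on standard treatment after the index treatment
  failed; remission 0.107/cycle to E.
- **E** — remission on standard treatment; relapse 0.232/cycle back to
  D (no re-treatment: E is reached only after the index treatment
  failed).
- **F** — (esketamine arm) remission on standard treatment after
  completing the maintenance schedule; relapse 0.232/cycle to C
  (re-treatment).
- **G** — dead; absorbing.

A and C are single-cycle treatment states — an eight-session ECT
course or the esketamine induction fits inside one 30-day cycle — so
their entire occupancy resolves each cycle into remission, death or
(residually) D. All printed exit probabilities of a state are applied
simultaneously as one stochastic row; the residual mass defines the
remaining transition, and a row whose named exits exceed 1 is an
error, not a renormalisation.

Mortality is 0.00304/cycle in the depressed states (all-cause death of
depressed individuals over 4.5 years, hazard multiplied by 1.35 for
TRD) and age-banded life-table mortality in the remission states
(five-year bands, 0.000180/cycle at 45–49 rising to 0.00285 at 75–79).
Ages beyond 79 clamp to the last band; the default horizon ends at 80
so the clamp is only a guard.

Utilities are 0.81/year in remission and 0.57/year in depression,
accrued as annual/12 per cycle (0.0675 / 0.0475). The published input
table displays these rounded to 0.07/0.05; the rounded values are
available behind a flag (`use_rounded_cycle_values`) but are not the
default, since 0.07 × 12 = 0.84 ≠ 0.81. Death accrues nothing.

## Rate conversions

Source trials report event proportions over heterogeneous windows.
Under a constant hazard, r = −ln(1−P)/t converts a proportion to a
daily rate and p = 1 − exp(−rt) re-expresses it over the 30-day cycle.
Day conventions: week = 7 d, month = 30 d, six months = 182.5 d, year
= 365 d. These conventions reproduce the five derivable published
inputs at their printed 3-significant-figure precision (0.108, 0.0300,
0.0724, 0.107, 0.00304 — the last after multiplying the hazard by the
1.35 TRD relative risk). Two inputs do **not** follow from their
stated sources under any convention tried: the standard-treatment
relapse probability 0.232 (64.6% over 3.1 months converts to ≈0.285)
and the esketamine remission probability 0.392 (36.0/38.8% over four
weeks converts to ≈0.395). The printed values are used as-is; the
engine never silently re-derives its inputs, and the conversion module
exists for verification, sensitivity work and synthetic-data recovery.

## Costing

The societal per-state per-cycle costs for ages <65 and ≥65 are model
inputs, taken verbatim from the published input table. The difference
between the two columns is the productivity loss, which the package
re-derives from the human-capital formula with the general wage rate:
the value of a lost month of work is the wage plus the payroll tax due
on it (12% of income between £702.01 and £3,863/month); with full-time
wage £2,340 and part-time £680, depression costs
0.54·V_ft + 0.13·(V_ft − V_pt) = £1,611/cycle (54% unemployed, 13%
part-time) and remission 0.23·V_ft = £583/cycle. These equal the
printed column differences within £1 at the table's integer precision.
Productivity loss is zero from the retirement age of 65.

The ≥65 column is therefore "societal minus productivity" and is
decomposed into direct healthcare + informal care + travel. The
published study prints only totals, so the split is an explicit calibration:

- **travel** = £18.80 per clinic visit (the London daily fare cap)
  times the visits each phase's schedule implies (8 in the treatment
  states, 4 in the first maintenance month, 2 in ongoing maintenance
  phases, 0 in states managed by the GP alone);
- **informal care** is treated as a property of the health state, not
  the treatment phase: £565 per depressed cycle and £0 in remission.
  The depressed-cycle amount is the single free parameter of the
  split; it was calibrated so the healthcare-perspective totals of all
  three arms (ECT, esketamine, ECT + M-ECT) match the published
  no-discounting healthcare rows, which they then do within 1.1%, and
  the main-model healthcare increment within 1%. At a mean hourly wage
  it corresponds to roughly 30 hours of informal care per depressed
  month, a plausible magnitude;
- **direct healthcare** is the remainder. The resulting direct costs
  agree within a few percent with independent bottom-up assembly from
  unit costs (£558/ECT session, £163/28 mg esketamine, GP £39,
  psychiatrist £176, nurse administration £44, plus residual TRD
  service use), which is kept in the package as a cross-check.

Any state's direct cost can be overridden in config (informal care
then becomes the residual; a negative residual is an error). The
healthcare perspective uses the direct component only; the societal
perspective uses the printed totals, with the productivity component
scalable by scenario.

## Discounting: why the package has two accounting modes

Costs and health are discounted at 3.5%/year. Two conventions are
implemented: per-cycle compounding, factor (1.035)^(−cycle/12), and
annual steps, factor (1.035)^(−⌊cycle/12⌋); cycle 0 is undiscounted.
The default is per-cycle compounding, which reproduces the published
properly-discounted rows — the five-year-horizon scenario costs — to
0.02–0.1% (computed 105,058 / 115,964 / 127,087 vs published 105,078 /
116,086 / 127,153).

The published **35-year** totals, however, cannot be produced by any
compound discounting scheme:

1. The published base-case totals sit only ~2.7% below the study's own
   no-discounting scenario (e.g. 453,693 vs 466,497 GBP), whereas
   3.5%/yr compounding over 35 years reduces these streams by ~30%.
2. The published maintenance-arm discounted QALY total, 16.83, exceeds
   the mathematical upper bound for *any* survival pattern under
   compound discounting: a cohort in perfect remission for all 35
   years accrues at most 0.81 × Σ(1.035)^(−c/12)/12 ≈ 16.2 QALYs
   (16.77 under annual steps).

The long-horizon tables therefore embody an effectively null discount,
and the package exposes a **published-equivalent mode** — the default
parameterisation with the discount rate set to 0 — in which it
reproduces all six published no-discounting totals within 0.1% (costs)
to 1.5% (QALYs), and in which every qualitative call of the published
main-model table (dominance vs ICER below £20,000, 22 rows × both
perspectives) reproduces exactly. Table-wide qualitative comparisons
and the reproduction of published 35-year quantities use this mode;
all forward-looking analysis uses the default 3.5% per-cycle mode.
The remaining discrepancies (main-model QALY totals ~1.4% high,
maintenance-arm cost ~0.9% low against the published no-discounting
rows) persist under every accounting variant tried — state-E utility,
relapse destinations, tunnel phase lengths, rounded per-cycle
utilities, accrual timing and half-cycle correction were each tested
and rejected as explanations — and are attributed to unidentifiable
internals of the original spreadsheet; they propagate to a +3%
deviation on the maintenance-model societal ICER (computed ≈27,900 vs
published 27,070 in published-equivalent mode; ≈28,600 under the
default conventions).

## Sensitivity scenarios

Nine one-at-a-time scenarios, each under the societal and/or
healthcare perspective as published: (1) productivity loss ×2 / ×0.5
(scales only the productivity component; healthcare totals are
bit-identical to base); (2) six or twelve ECT sessions per treatment
cycle, at £558/session plus travel under the societal perspective;
(3) esketamine remission raised to 0.5 (states A and C); (4) ECT
remission lowered to 0.5 (states A and C); (5) second-course remission
raised to 0.9 (state C only, both arms); (6) five-year horizon;
(7) alternative utilities — 0.3/yr while depressed under ECT (ECT-arm
A and C) and 0.85/yr for remission on an ordinary antidepressant after
esketamine or standard treatment (esketamine tunnel and F, plus E in
both arms); (8) esketamine continued for as long as remission lasts
(the tunnel stays at the months-2–5 schedule and cost; F unreachable);
(9) no discounting.

Two scenario readings were genuinely open and were resolved
numerically:

- **Scenario 7, ECT-arm state B.** Extending 0.85 to ECT-arm remission
  is defensible (B under the main variant is remission on an
  antidepressant), but the published QALY shifts (+0.19 main, +0.16
  maintenance) match the reading in which only E and the
  post-esketamine states are upgraded (+0.21 / +0.18 computed), and
  clearly reject the extended reading (+0.28 / +0.42). The narrow
  reading is the default; `scenario7_includes_ect_b=True` gives the
  other.
- **Scenario 8, maintenance table.** Continuing esketamine beyond
  month 6 replaces the cheap post-treatment remission state (701/cycle
  societal) with the dearer maintenance phase (1,583/cycle), so the
  arm's cost must rise — as the published main-model table shows
  (+2,538; the package computes +2,598). The published *maintenance*
  table nevertheless prints the same arm falling by ~31,000 under the
  identical scenario, and its above-threshold ICER of 41,660 rests on
  that value. No reading tried (including giving the drug at no cost
  after month 6) reproduces it; the package computes this scenario one
  way for both tables and its maintenance-model scenario-8 ICER
  (≈28,700–29,800 depending on mode) stays below the 30,000 threshold.

## Synthetic data and validation

`synthetic.simulate_trial` draws i.i.d. Bernoulli outcomes emulating
each source trial (a proportion over a follow-up window);
`recover_parameters` runs the published derivation chain in reverse on
the simulated data. Estimates are consistent (absolute error shrinks
through n = 10² → 10⁶) and Wilson score intervals on the window
proportion achieve ≥93% empirical coverage at n = 50 over 500 seeded
replicates (the Wilson form is used because Wald intervals undercover
at small n with rare events). The generator emulates only the summary
structure the model consumes — binary outcomes at a common assessment
time — not dropout, staggered follow-up or item-level resource use, so
passing recovery tests validate the conversion arithmetic, not the
epidemiology of the source trials.

`synthetic.microsimulate` pushes individual patients through the same
`CohortModel` arrays (transition matrices, cost and utility vectors,
discount factors) as the cohort recursion, so any disagreement
isolates the recursion rather than the accounting. Cohort totals agree
with a 200,000-individual microsimulation within 3 Monte-Carlo
standard errors (seconds of runtime; standard errors scale as 1/√n).
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state.

## Numerical choices and degenerate inputs

- Occupancy rows sum to 1 within 1e−9 at every cycle (property-tested
  over random valid bundles); death occupancy is non-decreasing.
- Zero horizon yields zero cost and QALYs. With remission certain and
  relapse and mortality zeroed, the discounted QALY total equals the
  closed-form geometric annuity within 1e−9.
- Half-cycle correction (averaging successive occupancy rows) is
  implemented but off by default, matching spreadsheet-model
  convention.
- ICERs are kept at full precision internally; table writers round to
  whole GBP and 2-decimal QALYs for display, with a raw option.

## Known limitations

- No probabilistic sensitivity analysis (none was published); the
  deterministic scenario set is the catalogue above.
- No individual heterogeneity, covariate-dependent transitions or
  time-varying treatment effects; transition probabilities are
  first-order Markov.
- The healthcare perspective depends on the calibrated cost split and
  is validated qualitatively (main-model ICER below £20,000;
  maintenance-model ICERs above £30,000), not as exact reproduction.
- The published 35-year discounted totals are irreproducible for the
  structural reasons derived above; reproduction claims are therefore
  anchored to the properly-discounted five-year rows and the
  no-discounting rows.
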