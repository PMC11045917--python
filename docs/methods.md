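# Methods

## Model structure

A deterministic cohort Markov state-transition model over four health
states — normoglycemia, prediabetes, T2D, death — run in monthly cycles.
The entire prevalent prediabetes cohort of a country (age-banded adult
population × a uniform prevalence) enters in the prediabetes state at
month 0 and is followed as a closed cohort for up to 15 years: no
entrants, death is an ordinary absorbing state, and total mass is
conserved (the engine raises on relative drift above 1e-6, which could
only be a bug). The stored population growth rate is deliberately inert;
it belongs to population-projection uses outside this model's scope, and
an open cohort would contradict the single-entry design.

Occupancy is real-valued throughout; rounding to whole persons happens
only in reports.

## Transition rates and the monthly root

Base-case annual probabilities: normoglycemia→prediabetes 1.5%,
normoglycemia→T2D 0.72%, normoglycemia→death 1.1%, prediabetes→
normoglycemia 45% (scenario alternatives 15% and 30%, reflecting the
11–59% regression range in the clinical literature), prediabetes→T2D
7.5%, prediabetes→death 1.2%, T2D→death 3%, and no recovery from T2D.
Diagonals are one minus the row outflow.

Monthly matrices are the 12th root of the annual matrix via eigen
decomposition. The annual matrices in this parameter space have real,
distinct, positive eigenvalues, so the root is exact to machine
precision; the generic embedding caveat — a stochastic matrix root may
carry small negative entries — is handled by clipping and row
renormalisation. Within the scenario space the clipped mass is below
1e-6 and the repaired root still satisfies M¹² = A entrywise to 1e-6
(property-tested over randomised valid parameter sets). Boundary
matrices with an exactly-zero transition that two-step paths would
recreate (e.g. full protection, where prediabetes→T2D is 0 while
prediabetes→normoglycemia→T2D is not) have no nonnegative root at all;
the function then warns and returns the clipped approximation rather
than failing, so that limiting cases such as a 100% risk reduction remain
simulable.

Scalar adherence probabilities use the constant-hazard conversion
1 − (1−p)^(1/12), which coincides exactly with the matrix root of the
corresponding two-state chain.

## Interventions, adherence, and cycle order

Treatment scales the *annual* prediabetes→T2D probability by (1 − RR)
before the monthly root is taken — the risk reductions are quoted in
annual units, and reducing the monthly rate instead would differ only at
third order. Two regimes: RR = 31%/58% (metformin/ILC) while time on
model is ≤ 36 months, 18%/34% afterwards. The switch is keyed to time
since model entry, not time on treatment.

Adherence is a layered sub-cohort structure. Metformin noncompliance
(10%/yr) and ILC defaulting (51%/yr, the complement of the 49% annual
usage rate) are constant annual hazards converted to monthly
probabilities — the minimal assumption given that only per-year rates are
stated. Defaulting applies to prediabetes-state mass only: progression to
T2D ends the intervention, and normoglycemic regressors keep their layer
assignment but accrue no intervention cost. The titration arm's
post-default layer carries the ILC-level effect with both drug and
programme costs; this is the reading under which titration is both the
most effective and the most expensive arm, consistent with the published
result ordering.

Cycle order of operations: health-state transition first, then adherence
flows, then cost accrual on the end-of-cycle occupancy (no half-cycle
correction). The ordering is an open modelling choice; it is isolated in
one function and the year-5 incidence reductions it produces
(−21.0/−24.0/−34.1/−40.5% for metformin/ILC/combination/titration) sit
within three percentage points of the published −21/−27/−36/−39%, with
the strategy ordering exact. The ILC arm carries the largest deviation
(−24.0 vs −27), attributable to the unspecified within-year timing of the
51%/yr default hazard.

Incident T2D per month is the mass entering the T2D state during that
cycle; prevalent T2D is the state occupancy at a time point. Both are
recorded, and comparisons report both differences; incidence is the
primary metric for "incident T2D patients".

## Costing

Disease-state annual per-capita costs follow the attributable-fraction
R-rate method: for an age band with population N, total projected
resource use U, disease prevalence P and relative cost ratio R,

    nondisease = U / (N (1 + P (R − 1))),   disease = R × nondisease,

which conserves total spend exactly; country-level state costs are
prevalence-weighted band averages, and with a single uniform band reduce
to R × the normoglycemia cost (R = 1.04 for prediabetes, 3 for T2D).
The Poland and Vietnam cost triples follow this reduction exactly; the
Saudi triple does not (its published prediabetes/T2D costs are not
1.04×/3× its normoglycemia cost), so the fixture carries the published
values verbatim.

Each cycle, every living member accrues 1/12 of their state's annual
cost (death accrues nothing), and prediabetic members of treated layers
accrue the monthly metformin and/or ILC price. Intervention costs are
restricted to prediabetes-state members to avoid double-counting: T2D
patients transfer to standard diabetes care and normoglycemic regressors
no longer need the programme. Costs are undiscounted cumulative sums in
USD (currency is treated as an opaque unit; no conversion logic).

## Country fixtures

The packaged prevalent cohorts are the published per-band counts, which
for all three countries equal population × 6.8% — including Saudi Arabia
and Vietnam, whose headline survey prevalences (12.8%, 13.8%) differ from
the effective rate their published cohort columns imply. The fixtures
store the effective 6.8% (what the model actually uses) and keep the
headline figure as `reported_prediabetes_prevalence` metadata. The Saudi
band populations sum to 24 741 034, one less than the printed total; the
bands are authoritative.

## Synthetic countries

`generate_synthetic_country` draws five age bands (1–20M people each),
an effective prediabetes prevalence in 5–15%, intervention prices and a
normoglycemia per-capita cost spanning the fixtures' range, and derives
the cost triple through the R-rate machinery, so synthetic countries pass
exactly the validation the fixtures do. It emulates the *structure* of
the case-study inputs, not their joint realism: prices and prevalences
are drawn independently, with no correlation between a country's wealth
and its cost levels, and age bands share one prevalence. Tests passing on
synthetic countries therefore demonstrate structural correctness
(ordering, conservation, population-independence of relative reductions),
not calibration to any real health system — calibration claims rest on
the three fixtures only.

## Sensitivity analyses

One-way scenarios re-simulate with exactly one input family perturbed:
disease-state costs ×0.8/×1.2, intervention costs ×0.8/×1.2, both
risk-reduction regimes ×0.8/×1.2 (capped at 1 with a logged warning), a
20% boost to the ILC-carried effect in the combination and titration
arms only, and removal of the ILC price. The reported metric is the
percent change in year-5 cumulative total expenditure against the same
strategy's base case, and the headline "average effect" is the unweighted
mean over the four treatment arms — the averaging set is stated here
because it is a design choice.

## Numerical and design notes

- Deterministic end to end; the only random number use in the package is
  the synthetic-country generator (seeded `numpy.random.default_rng`).
- Monthly matrices are cached per (risk reduction, regime) — at most two
  regimes exist per layer.
- Horizon 0 is accepted and yields the bare initial state; arbitrary
  positive integer horizons are accepted beyond the named 1/5/10/15.
- Metformin's 90% compliance is applied as an annual persistence hazard
  every year, not a one-time first-year filter; the latter reading would
  contradict compliance holding "throughout" the model lifetime.
- Whether metformin noncompliance should also drain the combination
  arm's on-both layer is unspecified; it is applied only to
  metformin-only layers here.

## Problem sizes

The default suite simulates 15-year horizons (181 monthly states) for
five strategies across three countries plus property tests over
randomised parameter sets; the full run takes a few seconds. The
analysis drivers use the same full-size cohorts — no scaling down is
needed because the model is a 4-state linear recursion.

## Known limitations

- Cohort-level (not microsimulation): no individual heterogeneity,
  re-initiation after default, or adverse events.
- No discounting, no indirect/societal costs, no utilities or QALYs.
- Single uniform prevalence per country; the age bands affect only the
  cohort size, not the dynamics (transition rates are age-independent).
- The exact published expenditure tables are not reproduced to the
  dollar: the cycle-order and cost-accrual conventions they used are not
  fully recoverable, so currency outputs agree in sign, ordering and
  order of magnitude rather than digit-for-digit.
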