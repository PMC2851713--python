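# Methods

## The decision problem

Universal ultrasound (US) screening of infant hips at three months is
to be organised within the existing Dutch infant health care (IHC)
system. Four organisational variables span the design space: number of
portable US machines purchased (one per site / a single shared machine
/ none, using machines already available where screening takes place),
consultation type (integrated into the regular three-month visit /
extra visit), screener discipline (IHC physician / IHC nurse /
radiographic technician / medical specialist) and location-time
(IHC daytime / external building / IHC evening). The full factorial
yields 72 scenarios, each evaluated by its cost per screen-detected
child (CE ratio) on a simulated cohort.

Three organisational rules link the variables: the IHC organises the
screening whenever IHC staff screen or IHC buildings are used; an
integrated consultation screened by a technician or specialist still
requires the IHC physician on site for the regular consultation (their
exam-time wage is added); and an integrated consultation screened by
the IHC nurse means the physician delegates the regular consultation
to the nurse (no extra staff time). An extra consultation carries no
physician-presence requirement, since the regular consultation happens
separately anyway.

Scenarios are identified by a canonical mixed-radix id (machines-major,
then consultation, screener, location; 1–72). Historical scenario
numberings for this problem follow no recoverable rule, so any
comparison with published scenario lists is by level tuple, never by id.

## Cohort model

One cohort holds 2,300 children arriving uniformly over 18 months
(the intake of the implementation study the figure derives from). Each
child independently has

- residence: urban with probability 2/3 (two of the three
  participating organisations are urban/suburban), rural otherwise;
- latent hip status: affected with prevalence π = 0.038, split over
  Graf types 2b/c, D and 3/4 with weights 1.4 : 1.5 : 0.5. The printed
  per-type rates sum to 3.4% while the screening operating point
  implies 3.8% (3.2% detected + 0.6% missed); the mix is therefore
  renormalised to the configured prevalence, and both are exposed in
  the configuration;
- travel distance to the IHC: uniform on 4–7 km (only the range is
  established); external locations use a fixed 10 km;
- attendance: first invitation with the region's rate (urban 0.85,
  rural 0.90), one reminder for non-attenders with re-attendance 0.80
  (urban) / 0.90 (rural). Reminders themselves are costless (no
  administrative price is established) and re-attenders incur the same
  visit costs as first attenders. Overall screening probability is
  therefore 0.97 (urban) and 0.99 (rural).

The cohort is the *post-exclusion* screening population: children
referred and treated in their first months of life never reach the
three-month screen. The model accounts for them as a pre-screening
stage — Binomial counts at 0.31% (treated at the first IHC
consultations, €571 each) and 0.61% − 0.31% (referred but refuted, one
€97 hospital visit each) of the cohort size — that adds programme cost
identical across scenarios without depleting the cohort. This keeps
the prevalence among screened children at the configured 3.8%, which
is what the published operating point (3.2% true positives of
screened) presumes.

## Screening test

Screener quality is stated as whole-cohort proportions — false
positives fp and missed cases m among all screened children
(physician 1.4/0.6%, nurse 1.5/0.7%, technician 1.3/0.6%, specialist
0.6/0.3%) — and converted to the conditional probabilities the
per-child simulation needs: P(miss | affected) = m/π and
P(positive | healthy) = fp/(1 − π). Parameters with m > π are rejected
as inconsistent. Detection is "detected and treated within a year":
every true positive is treated with probability 1 (no treatment-uptake
loss is modelled, and false positives are assumed not to receive
treatment).

The current-screening comparator applies its published whole-cohort
rates directly (2.8% true positive, 16.5% false positive, 0.9%
missed); the physical exam happens inside routine consultations, so
the comparator carries only downstream and pre-screening costs. It is
reported for context and for optional incremental ratios; the headline
statistic is each scenario's average CE ratio.

## Costs (euros, 2006 price level, societal perspective)

Per examination: screener wage × 10/60 h (wages 75/42/70/106 €/h),
plus the physician's 10-minute wage when presence is required. An
extra consultation doubles the salary cost and doubles travel and
parent time (one extra trip, one extra hour of productivity loss at
€36/h). Evening sessions raise salary costs by 35%. The documented
tables also carry a flat "€5 per child" evening overhead, which is the
same 35% applied to the €73 average wage per 10-minute exam; to avoid
double counting the wage uplift is applied and the flat fee is not,
with a configuration switch (`use_evening_flat_fee`) selecting the
flat-fee variant instead.

Travel is €0.20/km over the child's IHC distance (10 km external),
charged once per visit as the guideline applies the rate to the stated
distances directly. External locations add rent per screened child;
no rent figure is established anywhere, so the default is a nominal €5
per child, flagged as gap-filled and swept in the sensitivity
analysis. Scenarios that purchase no machine bill machine time at the
hospital ultrasound rate (€61/h, the only established price for
non-owned machines) pro-rated to the 10-minute exam.

Fixed per scenario: training of one screener per purchased machine
(minimum one) at €1,300 each — the rounded value of 16 h × €73 + €130
materials = €1,298; the rounded figure is used so cost audits match
the documented table. Machine ownership costs €11,178 per machine-year:
the five-year 5% annuity of the €32,725 purchase price (€7,558.65,
reported as €7,560 — the annual total uses the €10-rounded figure for
the same audit-matching reason), €1,000 insurance and 8% maintenance
(€2,618). "Many machines" purchases one per IHC site with a default of
7 sites (a config knob); one year's ownership cost is divided by the
full cohort, giving €4.86 ≈ €5 per child per machine.

Downstream: treatment €897 (type 2b/c), €717 (type D), €2,043 (type
3/4) for true positives; €1,217 (the average across types, reflecting
later and costlier treatment) per missed case; €97 (one hospital visit
€61 + one parent-hour €36) per false positive, applied to US screening
the same as to current screening. Treatment costs of Graf type 2a
(only assigned below two months of age, i.e. before this screen) have
no established value and are excluded.

## Simulation, oracle and randomness

The published formulation of the model is a station/sequence
(discrete-event) simulation; since no capacity constraints or queues
are modelled, children are independent and the model here is an
equivalent independent-child Monte-Carlo. Each scenario runs `n_reps`
fresh cohorts (default 100; the original replication count is not
documented) and reports means with a delta-method normal CI for the
ratio of means. All randomness flows from one root seed through
`numpy` `SeedSequence` spawn keys `(scenario_id, replication)`, so any
scenario's results are byte-reproducible and independent of execution
order; the comparator uses a reserved stream id.

Because totals are sums of per-stratum expectations,
`expected_scenario` evaluates every count and cost in closed form
(e.g. E[screened] = n·(a + (1−a)r) mixed over regions, E[TP] =
n·π·P(screened)·(1 − m/π)) with no randomness. It serves three roles:
verification oracle for the simulator (every scenario's simulated
mean total cost, TP, FP and FN must sit within 3 standard errors at
200 replications), fast engine for sensitivity sweeps, and the
deterministic mode of the full experiment. A scenario whose expected
or realised detection count is zero raises a degenerate-parameters
error rather than returning an undefined ratio.

Quartile groups are formed by rank (four contiguous groups of 18),
not by CE-value cuts, matching the definition of the groups; float CE
ties would break by canonical id. The incremental ratio against
current screening, (cost_US − cost_current)/(TP_US − TP_current), is
available from the comparator output, but the average CE per scenario
is the headline figure.

## What the synthetic cohorts do and do not emulate

The generator reproduces the cohort's size, intake window, latent
disease mix, urban/rural attendance behaviour and travel-distance
range. It does not emulate seasonal intake patterns, correlation
between residence and disease risk, capacity competition between
sites, attendance differences by location or time of day (no such
rates are established), treatment-effectiveness uncertainty, or
over-treatment of false positives. Passing tests therefore demonstrate
internal consistency of the cost model and ranking under the stated
conditions, not field performance of any screening programme.

## Numerical and design choices

- Annuity: closed form P·r/(1 − (1+r)^(−n)); straight-line P/n at zero
  (or sub-resolution) interest; verified against an independent
  amortisation-schedule iteration.
- Cost additivity is exact by construction: the per-child itemisation
  (staff, travel, parent time, rent, machine use, downstream) plus
  per-replication fixed costs (training, machines, pre-screening) sums
  to the replication total.
- Problem sizes: the default experiment is 72 scenarios × 100
  replications × 2,300 children; oracle-equivalence checks use 200
  replications; operating-characteristic convergence checks use a
  single 100,000-child cohort. These sizes make every claim testable
  in seconds on one CPU while leaving Monte-Carlo error far below the
  between-scenario differences (mean |simulated − expected| CE ≈ 0.7%).

## Known limitations

Scenario-level CE values shift with the two gap-filled parameters
(external rent, site count behind "many machines"); the reproducible
findings are structural — integrated consultations dominate the
cost-effective quartile, many-machines-plus-extra-consultation
scenarios are uniformly the least cost-effective, and the best-worst
spread is of order €2,000–3,000 per detected child. QALY-based
outcomes, probabilistic sensitivity analysis and resource-competition
(queueing) modelling are out of scope.
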