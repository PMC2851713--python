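# hipscreen

Scenario simulation of the cost-effectiveness of ultrasound screening
for developmental dysplasia of the hip (DDH) in Dutch infant health
care centres (IHC).

Universal ultrasound (US) screening at the age of three months detects
more affected hips with far fewer false positives than the current
physical-examination screening, but it can be organised in many ways:
buy a portable US machine for every IHC site, share one machine, or
use machines already available elsewhere; integrate the exam into the
regular three-month consultation or schedule an extra one; let IHC
physicians, IHC nurses, radiographic technicians or medical
specialists screen; and run sessions at the IHC by day, in the
evening, or in rented external buildings. The full factorial of these
four organisational variables (3 × 2 × 4 × 3) gives **72
implementation scenarios**. This package evaluates all of them, for
policy analysts and health-services researchers who need to know which
organisational choices drive the cost per detected child before
committing to one implementation.

## Model

A synthetic cohort of *n* = 2,300 children (18-month intake) carries a
latent Graf hip classification — healthy, or a treatable type 2b/c, D
or 3/4 hip — at prevalence π = 3.8%, urban/rural residence, and a 4–7 km
travel distance to the IHC. Each child attends the screen with the
region's attendance rate (urban 85%, rural 90%); non-attenders get one
reminder and re-attend with rate 80% (urban) or 90% (rural). Screener
quality is given as whole-cohort proportions of false positives *fp*
and missed cases *m*, converted to conditional probabilities

    P(miss | affected) = m / π,      P(positive | healthy) = fp / (1 − π).

Costs are itemised per child from a societal perspective (staff wages
per 10-minute exam, parents' travel and time, rent, hospital machine
usage) plus fixed costs per scenario (screener training €1,300 each;
machine ownership €11,178 per machine-year = €7,560 annuity over 5
years at 5% + €1,000 insurance + €2,618 maintenance), plus downstream
costs (treatment by Graf type for true positives, €1,217 per missed
case, €97 per false-positive referral). The headline statistic per
scenario is the cost-effectiveness ratio

    CE = E[total cost] / E[number of screen-detected children],

computed either by Monte-Carlo simulation over replicated cohorts or
by a closed-form expectation model (children are independent, so all
totals are sums of per-stratum expectations). Scenarios are ranked by
CE and split into quartile groups CE_A (most cost-effective) … CE_D
(least).

## Worked example

```python
from hipscreen import (CostParams, PopulationParams, enumerate_scenarios,
                       expected_scenario, quartile_groups, rank_extremes)

pop, costs = PopulationParams(), CostParams()
results = [expected_scenario(s, pop, costs) for s in enumerate_scenarios()]
top, bottom = rank_extremes(results, 5)
best, worst = top[0], bottom[0]
print(best.spec.level_codes, round(best.ce_ratio))
print(worst.spec.level_codes, round(worst.ce_ratio))
print({g: len(m) for g, m in quartile_groups(results).groups.items()})
```

prints

```
(2, 1, 2, 1) 2978
(1, 2, 1, 3) 5911
{'CE_A': 18, 'CE_B': 18, 'CE_C': 18, 'CE_D': 18}
```

i.e. the most cost-effective scenario (€2,978 per screen-detected
child) shares a single machine, integrates the exam in the regular
daytime consultation and lets the IHC nurse screen, while the least
cost-effective (€5,911) buys a machine for every site, adds an extra
consultation with the IHC physician and runs in the evening. All five
cheapest scenarios use an integrated consultation and none buys
machines for every site; all five most expensive combine many machines
with an extra consultation.

The full experiment, including result tables under `results/`, runs as
numbered drivers:

```sh
python analysis/01_enumerate_scenarios.py   # the 72-scenario grid
python analysis/02_expected_ce.py           # deterministic CE ranking
python analysis/03_monte_carlo.py           # 100-replication simulation
python analysis/04_sensitivity.py           # one-way parameter sweeps
```

or through the CLI (`hipscreen enumerate`, `hipscreen run`,
`hipscreen sensitivity`, `hipscreen report`, `hipscreen
dump-defaults`), configured by a single YAML file.

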