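# screencea

Cost-effectiveness analysis of annual screening mammography for a
low-income setting (parameterised for Ethiopia), comparing four
provider-mix policies — 0%, 10%, 50% and 100% of screens delivered at the
private-sector price — against no screening, for two age bands (40–49 and
50–59).

The model is a decision tree feeding a five-state Markov cohort
simulation:

- **Decision tree** (per annual cycle): women at risk are partitioned by
  disease status and test result into true/false positives and negatives
  using incidence, sensitivity and specificity. Screen-detected cancers
  draw their stage at diagnosis from a more favourable distribution than
  clinically detected ones — the *stage shift* is the sole mechanism of
  screening benefit.
- **Markov chain** (states: remission, local recurrence, distant
  recurrence, cancer death, other-cause death): each diagnosed cohort
  advances annually through a row-stochastic, progression-only transition
  matrix specific to its stage group (I, II/III, IV); stage IV enters
  directly in distant recurrence.
- **Economics**: screening, doctor-visit, diagnostic-confirmation (FNAC)
  and stage-specific treatment costs, discounted at 5% (costs) and 3%
  (effects); outcomes are deaths averted and life-years gained (LYG),
  summarised as ICER (USD/LYG), incremental net monetary benefit at a
  willingness-to-pay threshold (default 2808.5 USD/LYG, three times GDP
  per capita), cost per death averted, and number screened per death
  averted.

On top of the deterministic pipeline the package provides one-way
(tornado) sensitivity analysis, second-order Monte Carlo probabilistic
sensitivity analysis (Beta/Gamma/Dirichlet parameter distributions), a
synthetic-scenario generator, and an individual-level microsimulation
used as a statistical oracle for the cohort engine. See
[docs/methods.md](docs/methods.md) for the full model description and
numerical choices.

## Quick start

```python
from screencea import ScreeningCEA, Policy

model = ScreeningCEA()  # packaged Ethiopia baseline scenario
result = model.evaluate(Policy(name="government", private_share=0.0), "40-49")
print(result.icer, result.verdict)
```

Command line:

```console
$ screencea run --policy gov --age-group 40-49
{
  "policy": "government",
  "private_share": 0.0,
  "age_group": "40-49",
  "incremental_cost_usd": 10777075.763748363,
  "lyg": 2510.68734619946,
  "deaths_averted": 79.96889513327207,
  "icer_usd_per_lyg": 4292.480216647487,
  "inmb_usd": -3725810.351947179,
  "cost_per_death_averted_usd": 134765.84546763886,
  "number_screened_per_death_averted": 1250.486202583456,
  "verdict": "not_cost_effective",
  "wtp_usd_per_lyg": 2808.5
}
```

The full policy table (4 policies × 2 age bands), tornado and PSA:

```sh
screencea policy-table --output results/table.csv
screencea owsa --age-group 40-49 --top 10 --output results/tornado.csv
screencea psa --iterations 10000 --seed 1 --output results/psa.json
```

Every writing command also emits `<output>.manifest.json` recording the
invocation, a SHA-256 hash of the scenario, the package version and the
seeds. Exit codes: 0 success, 2 invalid input, 3 I/O error.

At the packaged baseline no policy is cost-effective at the default
threshold; the government-price policy has the lowest ICER in both age
bands (4292 USD/LYG at 40–49, 3490 at 50–59), and the ICER rises
linearly with the private share because the mammography price affects
costs only, never health outcomes.

## Custom scenarios

Scenarios are YAML/JSON documents validated by a pydantic schema
(`screencea.load_scenario`, `screencea.validate_scenario`). The packaged
baseline (`screencea.baseline_scenario()`) documents every field; a
companion provenance file maps each value to its upstream source. Stage
distributions are renormalised proportionally at load when their printed
sum deviates from 1 by rounding (at most 5%).

## Testing

```sh
python -m pytest -q tests/
```

The suite contains unit tests, seeded property-based tests (hypothesis)
and end-to-end acceptance tests covering: published-value metric
identities, the baseline pipeline envelope and tornado ranking, cohort
engine vs microsimulation equivalence over random scenarios, model
invariants, exact closed forms on a toy two-cycle fixture, and PSA
degeneracy/monotonicity.

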