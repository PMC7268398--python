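# Methods

## Cost model

`seqcost` implements bottom-up (micro-)costing of genomic sequencing
from the perspective of a public health provider: every resource a
workflow consumes is a line item valued per **patient** — not per
sample — so in tumour/germline pair designs an item's value already
covers both samples. Items carry either a per-patient cost directly or
`quantity × unit_price`; if both are given they must agree within half
a cent. Aggregation is a plain sum, performed twice over the same
items: by activity step (sampling → DNA extraction → library
preparation → sequencing → analysis → data storage → clinician
reporting) and by cost type (labour, consumables, testing, equipment,
other).

Two conventions matter for interpreting the outputs:

* **Step shares** divide by the total *excluding* capital equipment,
  because capital would not normally sit in an operating budget; the
  capital add-on is reported separately as a percentage of that same
  operating total.
* **Relative changes** in sensitivity analysis divide by the total
  *including* capital, since a price change is judged against
  everything the provider pays per patient.

Three workflow irregularities are modelled explicitly:

* **Merged steps.** When library preparation and sequencing are bought
  as one outsourced service the split is unrecoverable; such items are
  flagged `merged` and the breakdown reports a single combined step
  (`library_prep_and_sequencing`). Cross-project summaries always
  combine the two steps so merged and split projects stay comparable.
* **Absent vs zero-cost steps.** A step a project does not perform
  (e.g. clinician reporting in a pre-clinical study) is *absent* and
  renders `n/a`; a performed step whose cost is attributed elsewhere
  (a tumour biopsy taken during routine diagnosis) is a costed zero and
  renders `0.0%`. Both contribute zero to totals.
* **Software classification.** Computing software is grouped under
  `equipment` in the cost-type table (alongside the instruments it
  runs on), while remaining an ordinary operating item in the step
  table. The packaged fixtures record this at item level, so it can be
  overridden per project.

## Capital amortisation

An instrument acquired for `K` AUD with useful life `n` years at annual
interest rate `r` is converted to an equivalent annual cost
`EAC = K / a(r, n)` with the annuity factor
`a(r, n) = (1 − (1 + r)^−n) / r` (limit `n` at `r = 0`), divided by the
annual patient throughput, and maintenance is charged at
`maintenance_ratio` times the machine's per-patient cost. Defaults:
`n = 5` years, `r = 3%`, `maintenance_ratio = 0.5` — the packaged
fixtures' maintenance rows are exactly half their machine rows in every
project, so one configurable ratio carries that convention. A
straight-line alternative (`EAC = K/n`) is available behind an explicit
flag for sensitivity checks. Projects may instead state per-patient
machine and maintenance costs directly (`DirectCapital`), which the six
fixtures do because their acquisition prices and throughputs are not
public; the full annuity path is exercised on synthetic inputs.

The annuity factor is evaluated as `-expm1(-n·log1p(r))/r`, which is
exact in the `r → 0` limit where the naive closed form cancels
catastrophically.

## Storage and currency

Cloud storage is priced per GB per month in USD with three tier
presets — coldline 0.007, nearline 0.01, regional 0.025 — accumulated
over a retention window (default 60 months, the conventional
"short-term" horizon) and converted to AUD. The exchange rate is always
an explicit input expressed as **USD per AUD** (0.6929 for 2018, the
year of the packaged fixtures); it is never hard-coded into results.
The packaged fixtures carry their storage costs as observed per-patient
values rather than recomputing them from footprints, because the
observed values are not exactly recoverable from any single
footprint × tier × rate combination; the pricing formula is used by the
synthetic generator and for what-if scenarios. Rendering follows the
reporting convention of the source data: AUD to 2 decimals, USD to
whole dollars (half away from zero), percentages to 1 decimal.

## Sensitivity engine

One-way deterministic analysis only: resource quantities are point
estimates per project (aggregated, not patient-level), so bootstrap or
probabilistic analysis has no variation to draw on. A scenario pairs an
item selector (steps, cost type, case-insensitive label regex, and/or
the capital block; criteria conjunctive) with a multiplicative factor —
singly or as a low/high pair — or an absolute replacement value.
Applying a scenario returns a modified deep copy; the input project is
never mutated, and a selector that matches nothing raises an error
naming the scenario. Tornado rows are sorted by swing
(`|total_high − total_low|`) descending with ties broken by parameter
name ascending, so output is byte-reproducible. The default scenario
set varies library-prep+sequencing prices ±10%, all labour ±20%
(labour selectors deliberately include every labour-typed item, e.g.
multidisciplinary-team time), the storage tier (×0.7 coldline, ×2.5
regional relative to nearline) and capital ±20%.

## Synthetic generator

`SyntheticParams`/`generate_project` emulate the *cost structure* of
real projects for testing and what-if work: per-component costs are
lognormal (parameterised by median and log-sigma, medians set at the
targeted-panel scale), library preparation and sequencing are scaled by
a technology multiplier (panel ×1, exome ×4, genome ×7 — the relative
magnitudes observed across the packaged tiers), pair designs add a
second sampling item and double per-sample laboratory work, a rework
rate in [0, 0.5] inflates extraction consumables and QC by
`(1 + rework_rate)` (a 30% tumour-sample failure rate is a realistic
upper end), storage is priced from a per-technology GB footprint, and
equipment is drawn as a full acquisition spec so the annuity path is
exercised. Draws use one named `numpy` generator seeded by
`(seed, index)`, so each project is reproducible independently of
generation order and no global state is touched.

What the generator does **not** emulate: correlations between
components within a project, batch-size economies (the small-cohort
projects' high per-patient analysis labour arise from fixed costs over
few patients), negotiated commercial pricing, or any sequencing /
wet-lab content. Tests passing on synthetic cohorts therefore
demonstrate accounting correctness (conservation, linearity, symmetry,
round-trips), not realism of any particular cost level.

`expected_total_excl_capital` gives the analytic expectation of a
generated project's operating total (lognormal means marginalised over
the technology mix, pairing and reporting probabilities); the test
suite checks a 1000-draw Monte Carlo mean against it within three
standard errors.

## Numerical choices

* All arithmetic at full double precision; rounding only at rendering.
* Money comparisons use explicit tolerances: 0.005 AUD at item level,
  0.05 AUD for table-level sums. Fixture totals are asserted within
  0.011 AUD of their published renderings because several published
  tables carry one-cent rounding residues between components and
  totals; sums of printed components are authoritative here.
* Zero-cost projects: breakdowns are all-zero and well-defined, but
  *shares* of a zero total raise `UndefinedShareError` rather than
  return NaNs.
* Cross-project means are unweighted arithmetic means over projects
  (not patient-weighted): each project is one observation of a costing
  setting.
* Step and type labels parse case-insensitively with common aliases
  ("extraction", "library_prep", "storage", "labor"); unknown labels
  raise errors listing the valid values.

## Limitations

* Monetary inputs are prices, not true economic costs; commercial
  mark-ups are embedded in outsourced fees.
* The packaged fixtures encode observed per-patient component costs,
  not raw resource quantities, so quantity-level what-ifs (e.g. staff
  hours) on fixtures require editing item values or using
  `quantity × unit_price` inventories.
* No downstream modelling: patient management, cost-effectiveness,
  QALYs and budget impact are out of scope; the unit of output is the
  per-patient cost of sequencing itself.
* Uncertainty is scenario-based only; no distributions are placed over
  inputs.
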