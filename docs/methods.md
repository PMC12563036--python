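# Methods

## Scope and model

primorisk implements a first-tier, deterministic dietary risk assessment
for pesticide residues in a single food commodity, following the FAO/WHO
IESTI scheme as operationalized in EFSA's PRIMo model. It is deliberately
*not* probabilistic: exposures are point estimates built from worst-case
(acute) or average (chronic) residue levels, which is the standard
screening tier in EU practice. Only one commodity enters the diet; the
multi-commodity basket of a full PRIMo run is out of scope.

### Acute exposure

For a commodity whose unit weight is at or below 25 g (strawberries,
cherries — a single portion mixes many units), Case 1 applies:

    IESTI = LP_kg × HR × PF × CF / BW        [mg kg⁻¹ bw]

* `LP` — large portion, the high-end single-day consumption of the
  subgroup. Accepted in g/day (as consumption surveys publish it) and
  divided by 1000 internally.
* `HR` — highest residue of the substance **across the whole campaign**
  (worst-case single portion). This matters: an acute table built this way
  is a campaign-level worst case, not a per-sample one.
* `PF`, `CF` — processing and conversion factors, default 1 (commodity
  eaten raw and whole).
* `BW` — subgroup reference body weight, kg.

Units above 25 g use the unit-based variants with a variability factor ν
(unit-to-unit residue variability within a lot):

    Case 2a (unit < portion): (U_kg·HR·ν + (LP_kg − U_kg)·HR) × PF × CF / BW
    Case 2b (unit ≥ portion):  LP_kg·HR·ν × PF × CF / BW

The case is derived deterministically from the profile's unit weight; the
boundary value 25 g classifies as Case 1. The bundled strawberry profile
(unit weight 20 g) never triggers Case 2; those formulas are exercised by
unit tests only. ν defaults to 1 in the profile schema and must be set
explicitly (typically 3) for Case-2 commodities.

`%ARfD = IESTI × 100 / ARfD`; acceptable below 100%.

### Chronic exposure

    NEDI = APR × mean_consumption / 1000     [mg kg⁻¹ bw/day]
    %ADI = NEDI × 100 / ADI

`APR` is the arithmetic mean over **detected samples only**. This is the
convention of single-campaign assessments that lack supervised-trial
median residues (STMR), and it is conservative: non-detects are not
averaged in as zeros, so the APR over-states the long-term average
residue, the more so the lower the detection frequency.
`mean_consumption` is already per kg body weight (g/kg bw/day), so body
weight does not appear in the formula.

### MRL compliance and the hazard index

Compliance is `concentration / MRL × 100` per measurement; a sample is
non-compliant when any residue strictly exceeds 100% at full precision
(the legal limit is a threshold, not a display value — 100.4% flags even
though it prints as 100%). A concentration exactly at the MRL is
compliant.

The per-sample hazard index sums %ARfD over a sample's residues, each
residue's own concentration acting as its HR (the whole sample eaten in
one sitting), under dose additivity. Residues without an established ARfD
cannot contribute and are reported as exclusions; an index with
exclusions is a lower bound. This is a first-tier screen only — no
relative-potency or mechanism-based grouping is attempted.

### Unestablished reference values

ARfD and ADI are not defined for every substance. These are carried as an
explicit "not established" state (`None`, rendered "-" in reports), never
as zero or infinity; assessments return such substances in a separate
`not_assessable` list. In the bundled reference table 19 of 31 substances
carry an ARfD and 30 carry an ADI.

## Bundled campaign data

The packaged dataset reconstructs an 83-sample strawberry monitoring
campaign from southern Italy (2023–2024; 31 active substances — 17
fungicides, 5 acaricides, 9 insecticides; LOQ 0.010 mg/kg for all
analytes). Two files carry it:

* `residues.csv` — 149 per-sample detections. Concentrations transcribe
  the campaign's published per-substance residue lists; sample codes
  reproduce every published assignment (the four non-compliant samples
  A5/S2/V1/I4, the seven-residue sample D2, and the named single-sample
  detections), and the remaining assignments are plausible
  reconstructions, since full sample-level data were never deposited. The
  two fixed formulation pairs (trifloxystrobin with fluopyram,
  difenoconazole with fluxapyroxad) hold in every sample.
* `campaign_summary.csv` — the published per-substance summary (detection
  count, mean/min/max/total). For a few substances (notably cyflumetofen:
  15 published values vs 25 recorded detections) the published per-sample
  list is incomplete, so summary-level quantities (composition shares,
  detection frequencies, the cyflumetofen average of 0.112 mg/kg) are
  taken from this file rather than recomputed from `residues.csv`.

Two internal inconsistencies of the source report are carried as-is and
excluded from exact reproduction tests: the published acute row for
acetamiprid uses 0.013 mg/kg where the campaign maximum is 0.033 (the
package reports the max-based 10.79 %ARfD), and the published emamectin
%ADI of 15.136 is tenfold the value its own inputs produce (the package
reports the computed 1.514).

## Synthetic campaign generator

The generator emulates what a campaign summary constrains and nothing
more:

* **Detection** — per-substance Bernoulli at the campaign frequency
  (count/83 for the bundled study). Co-occurring companions are detected
  with probability 1 where their trigger is detected and with the
  adjusted residual probability elsewhere, preserving the companion's
  marginal frequency exactly (this requires the companion to be at least
  as frequent as its trigger, validated at config time).
* **Concentrations** — lognormal (right-skewed, positive), with μ, σ
  matched so the distribution mean equals the published mean and the
  published maximum sits at the 99th percentile. With only summary
  statistics published a formal fit is impossible; treating the maximum
  as P99 is a pragmatic anchor that reproduces the published spread to
  the extent it is knowable. Substances with a single detection carry no
  spread information and get σ = 0.2.
* **LOQ censoring** — draws below the LOQ are redrawn (up to 100
  attempts, then clamped to the LOQ), so censoring never thins the
  detection frequency.
* **Determinism** — each substance draws from `default_rng([seed,
  sha256(name) mod 2³¹])`, so campaigns are byte-reproducible and adding
  a substance does not perturb the others' draws.

What the generator does **not** model: farm/seasonal clustering, residue
correlations beyond the two fixed pairs, measurement uncertainty, and the
exact per-sample multiresidue distribution of the real campaign (the
published 17%/28%/55% split by residue count is not reconstructible from
published data). Tests passing on synthetic data therefore validate the
pipeline arithmetic and its statistical plumbing, not field realism.

## Numerical conventions

* Full float precision everywhere internally; rounding only at the
  reporting boundary, **half-up** (122.5% → 123%): concentrations 3 dp,
  exposure percentages 2 dp (3 dp for %ADI, whose values are small),
  MRL% integer, residues-per-sample percentages integer. The half-up
  helper absorbs binary-float noise within 10⁻⁹ of a decimal tie.
* MRL exceedance and the %ARfD/%ADI < 100 acceptability checks use
  unrounded values.
* Sums use `math.fsum`; per-substance totals satisfy
  |total − mean × n| < 10⁻⁹.
* Degenerate inputs fail loudly: non-positive concentrations or MRLs,
  duplicate (sample, substance) rows, a summary request for an undetected
  substance, and an exposure request for a substance without the relevant
  reference value are all hard errors, never silent zeros.

## Design choices

* The published large portion (166.70 g/day) is taken as a supplied
  constant; the derivation sometimes quoted for it (0.48 g/kg bw × BW)
  does not reproduce it and is not attempted.
* Where source tables disagree on a reference value, the bundled table
  keeps the value arithmetically consistent with the published exposure
  results (noted in the file's comments).
* Test-suite and acceptance problem sizes — 5000 samples for parameter
  recovery, 100 seeded campaigns of 30 samples for oracle equivalence,
  20 seeds for pipeline closure — were chosen as the smallest sizes at
  which the binomial/lognormal error bands are decisively narrower than
  the tested tolerances.

## Known limitations

* Single commodity, single population subgroup per run; no diet-wide
  aggregation.
* Deterministic point estimates only; no Monte-Carlo exposure
  distributions.
* No measurement-uncertainty expansion on MRL decisions (EU enforcement
  applies a default 50% analytical uncertainty before prosecuting; the
  package compares raw values, which flags more samples).
* The hazard index assumes dose additivity across substances with
  heterogeneous mechanisms; it is a screen, not a cumulative risk
  assessment.
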