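# Methods

## Scope and model

The package implements a semi-quantitative risk–benefit assessment at the
food-product level. Five pork products form the study set: grilled pork
(unprocessed reference scenario), Chouriço and Salame (fermented),
Presunto (dry-cured) and Fiambre (heat-treated). Each product carries
twelve nutrients and seven hazards; assessment proceeds in four traceable
steps — identification (the component registry), characterization
(benchmarks), exposure (per-serving intake) and risk/benefit
characterization (classification) — and ends in a harmonized heatmap.

**Benefits.** A nutrient's per-serving amount is divided by the applicable
Dietary Reference Value and expressed in percent. Three DRV classes exist:

* *absolute*, possibly sex-specific (e.g. magnesium 350/300 mg M/F, zinc
  10.13/8.23 mg; calcium uses the ≥ 25 y adequate intake of 750 mg, iron's
  female value is the premenopausal requirement);
* *energy-relative*: lipid (20 %) and linoleic acid (4 %) of daily energy,
  converted to grams at 9 kcal per g of lipid. Daily energy intakes
  default to 2500 kcal (male) and 2000 kcal (female) — the unique values
  that reproduce the tabulated lipid references (55.55/44.44 g) and
  linoleic references (11.11/8.89 g) under those fractions;
* *as low as possible* (trans and saturated fatty acids): no number, no
  percentage; cells are classified by presence/absence instead.

The protein DRV is carried as the absolute 46.2 g; it equals the
0.66 g/kg bw recommendation at the default 70 kg body weight.

**Risks.** Each hazard declares its own comparison mode. *L.
monocytogenes* (limit 100 CFU/g) and histamine (150 mg/kg) compare on the
concentration basis. Nitrite compares on the intake basis against its ADI
of 0.07 mg/kg bw/day: the tabulated Fiambre occurrence (100 mg/kg in the
product, 0.03 mg/kg bw/day intake) is below the limit only under the
intake reading, which is also how the published heatmap colors it. The
four genotoxic/carcinogenic contaminants use the Margin of Exposure
MoE = BMDL10/exposure with reference points 0.0004 (aflatoxins), 0.01
(ochratoxin A), 0.34 (PAH4) and 0.07 (benzo(a)pyrene) mg/kg bw/day and a
decision threshold of 10,000. Exposure assumes one serving per day
(`servings_per_day` is a config multiplier) and a 70 kg adult.

**Not reported.** A hazard never quantified in a product is the state
`NOT_REPORTED`, distinct from zero and from every number; it propagates —
no arithmetic is performed on it and every downstream quantity (intake,
MoE, exceedance) is the `NA` state. An MoE at exactly zero exposure is
likewise `NA`, not infinity.

## The packaged dataset

All component amounts, occurrence values, DRVs, limits and reference
points of the study tables are stored verbatim: nutrients per serving,
hazards on their comparison basis. Serving sizes were taken from a
national consumption survey and never published; the values stored here
are back-derived from printed concentration/intake pairs (≈ 52.07 g for
grilled pork from its histamine row; 21 g for the processed products from
their nitrite or histamine rows) and exist only to exercise the
concentration→exposure path. The Salame rows imply mutually inconsistent
serving sizes (histamine ⇒ 21 g, ochratoxin A ⇒ 10.5 g, nitrite ⇒ 4.4 g);
the printed intakes are preserved verbatim and win over any
concentration-derived exposure. Consequently recomputed MoE values can
differ from the published ones by the rounding of the printed intake
(e.g. PAH4 in grilled pork: 0.34/0.00008 = 4250 vs the published 4011.68,
which used the unrounded intake); the red/green classification at 10,000
is identical either way. A handful of published iron, zinc and lipid
contribution percentages do not satisfy the contribution formula as
printed; those cells are stored as printed but excluded from recomputation
checks.

Aflatoxins are `NOT_REPORTED` in every product. They remain in the
registry and in the 35-row risk table, but the heatmap omits hazard rows
with no reported value in any column, matching the published summary
(six hazard rows).

## Heatmap rules

* Nutrient gradients are normalized per component row across products
  (intensity = value / row maximum): the published table specifies the
  direction of darkness but no scale, and row-wise normalization makes
  intensities comparable within a row. Sodium uses the same gradient in
  yellow (higher is undesirable). "As low as possible" components: zero is
  flat green; any non-zero amount is red with darkness by amount. A
  contribution above 100 % of the DRV forces a flat red exceedance flag.
* Regulated hazards: below the limit, green with intensity 1 − ratio;
  above it, red scaled by the row's worst exceedance,
  (ratio − 1)/(ratio_max − 1), so a sole exceeder is fully dark.
* MoE hazards: green at or above 10,000 with intensity
  min(1, log₁₀(MoE/10⁴)); red below with intensity
  min(1, log₁₀(10⁴/MoE)/4). The rule "intensity proportional to distance
  from the threshold" fixes no scale; a log scale capped at four decades
  was chosen because observed margins span 0.62–129,990 and linear scaling
  would saturate immediately.
* `NOT_REPORTED` cells are flat green labelled "NR" in every render.
* Rows are ordered nutrients-then-hazards in registry order, sex-split
  (M before F) where the resolved DRV differs by sex; columns follow the
  published scenario order (Grilled Pork, Chouriço, Presunto, Fiambre,
  Salame) for the packaged dataset and input order otherwise.
* Rendered colors interpolate linearly between fixed palette endpoints
  (green `#e8f5e9→#1b5e20`, yellow `#fffde7→#f9a825`, red
  `#ffebee→#b71c1c`); the endpoints are a package choice, the source
  tables print no colors.

## Numerical choices

Internal arithmetic is full precision; display and comparison rounding is
half-up at two decimals via decimal arithmetic (plain float rounding is
banker's and turns e.g. 26.985 into 26.98 where the tables print 26.99).
The male lipid DRV computes to 55.56 at two decimals against the tabulated
55.55 (a truncation in the source); it is accepted within one display ulp.
Values below 0.01 are labelled with two significant digits so tiny intakes
stay legible. Ranged measurements evaluate at value_min/value_max for the
extreme scenarios; contributions are monotone in the amount and MoE is
antitone in the exposure, so min ≤ point ≤ max holds for benefits and
reverses for margins.

## Synthetic data

The generator emulates the statistical shape of the study tables, not
their biology: nutrients uniform within the observed per-serving spread,
hazards reported with probability 0.5 (the study tables have 15 of 35
hazard cells not reported) and log-uniform within bounds chosen to
straddle each benchmark (observed hazard levels span nearly seven orders
of magnitude, so uniform sampling would under-represent the low decades),
serving sizes uniform on 20–60 g, optional min/max ranges bracketing the
point value. It models no covariance between nutrients and no effect of
processing technology on hazards; generated products are draws, not
simulated foods. Passing property tests on synthetic data therefore
demonstrates pipeline correctness (units, states, ordering, totality), not
real-world representativeness. Product names never collide with the study
products. Identical specs (including the seed) yield identical datasets.

## Problem sizes

The default test and verification runs use the five-product packaged
dataset (35 hazard cells, 85 benefit rows, a 23 × 5 heatmap) and
synthetic sweeps of 25–100 seeds at 3–4 products each; these sizes
exercise every code path while keeping runs essentially instantaneous.

## Known limitations

Single-serving, single-day exposure only; no dose–response modelling, no
probabilistic (Monte Carlo) exposure, no bioavailability adjustment, no
whole-diet modelling, and no nitrosamine chemistry (nitrite is assessed
against its ADI; regulatory nitrite limits already account for nitrosamine
formation). Back-derived serving sizes are approximations, and the
published intake column is not exactly reproducible from the published
concentrations (see above). The assessment is comparative under stated
assumptions, not a universal ranking of product risk.
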