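# meatrba

Semi-quantitative **Risk–Benefit Assessment (RBA)** of meat products, as a
tested, reusable pipeline. The package compares an unprocessed reference
food (grilled pork) with processed alternatives — fermented (Chouriço,
Salame), dry-cured (Presunto) and heat-treated (Fiambre) products — by
jointly characterizing:

* **benefits** — nutrient amounts per serving and their percentage
  contribution to Dietary Reference Values (DRVs), and
* **risks** — microbiological and chemical hazard levels judged against
  regulatory limits or, for genotoxic carcinogens, Margins of Exposure,

and integrating both into a harmonized red/yellow/green heatmap. It is
aimed at food-safety and nutrition scientists who want the bookkeeping of
an RBA (units, bases, sex-specific reference values, not-reported states,
extreme scenarios) handled rigorously and reproducibly.

## The model

For a nutrient with per-serving amount $a$ and reference value $\mathrm{DRV}$:

$$\text{contribution} = 100 \cdot \frac{a}{\mathrm{DRV}} \,\%$$

Per-100 g composition values convert as $a = c_{100} / 100 \times s$ for a
serving of $s$ grams. Energy-relative DRVs (lipid: 20 %, linoleic acid: 4 %
of daily energy) resolve to grams via
$\mathrm{DRV} = f \cdot E_{\text{sex}} / 9\ \text{kcal g}^{-1}$ with
default energy intakes of 2500 kcal (male) and 2000 kcal (female). Trans
and saturated fatty acids carry the EFSA class "as low as possible": no
percentage is defined and any non-zero amount is flagged.

For a hazard with a regulatory limit, the observed level (concentration,
or daily intake for nitrite's ADI of 0.07 mg/kg bw/day) is compared
directly with the limit. For hazards with a BMDL10 reference point
(aflatoxins, ochratoxin A, PAH4, benzo(a)pyrene):

$$\mathrm{MoE} = \frac{\mathrm{BMDL10}}{\text{exposure}}, \qquad
\text{exposure} = \frac{c \cdot s/1000}{\mathrm{bw}}\ \text{mg kg}^{-1}\,\text{bw day}^{-1}$$

assuming one serving per day and a 70 kg adult; MoE ≥ 10,000 is
conventionally low concern. Components never quantified in a product carry
the explicit `NOT_REPORTED` state — distinct from zero — and no arithmetic
is ever performed on it.

## Worked example

```sh
meatrba benefits | head -4
```

```
product,component,sex,amount,drv,contribution_pct,exceeds_drv
Grilled Pork,Protein,both,8.53,46.2,18.46,False
Grilled Pork,Lipid,male,21.35,55.56,38.43,False
Grilled Pork,Lipid,female,21.35,44.44,48.04,False
```

One serving of grilled pork covers 18.46 % of the 46.2 g adult protein
requirement; its lipid content covers 38 % (male) / 48 % (female) of the
energy-derived lipid reference. On the risk side:

```sh
meatrba risks | grep '^Salame,Ochratoxin'
```

```
Salame,Ochratoxin A,moe,0.01556,0.01,mg_per_kg_bw_day,0.01556,0.64,True,False
```

Salame's ochratoxin A exposure of 0.01556 mg/kg bw/day against a BMDL10 of
0.01 gives a Margin of Exposure of 0.64 — five orders of magnitude below
the 10,000 threshold, hence a fully dark red heatmap cell. The full
pipeline (`meatrba assess --dataset fixture --out out/`) writes the
heatmap as CSV, JSON, HTML and SVG plus a structured `report.json`. The
same library surface is available in Python:

```python
import meatrba as m
ds = m.load_fixture()
matrix = m.build_heatmap(m.assess_benefits(*ds), m.assess_risks(*ds),
                         ds.products, ds.components, ds.config)
```

Datasets other than the packaged one are read from a directory of CSVs
(`products.csv`, `measurements.csv`, `references.csv`, optional
`config.yaml`) or a single JSON document; `meatrba synth --n 5 --seed 42
--out dir` generates schema-valid random datasets for testing. Ranged
measurements enable `--scenario min|max|all` extreme-scenario runs.

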