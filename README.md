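# wareamd — wet-AMD genetic risk evaluation

`wareamd` computes individual risk profiles for exudative (wet) age-related
macular degeneration from a panel of eight risk variants validated in the
Italian population (*CFH* rs1061170, *ARMS2* rs10490924, *IL8* rs2227306,
*TIMP3* rs5749482, *SLC16A8* rs8135665, *RAD51B* rs8017304, *VEGFA*
rs943080, *COL8A1* rs13081855), combined multiplicatively with two binary
non-genetic factors (smoking habit, positive family history). It is aimed
at clinical-genetics and biostatistics users who need a scriptable,
auditable risk calculator rather than an interactive dashboard.

## The model

Each variant *i* carries one odds ratio per diploid genotype class
*g* ∈ {hom-ref, het, hom-alt}. Raw case–control ORs are anchored to the
study's reference genotype; `wareamd` instead works with
**population-normalized** ORs: with genotype frequencies *f<sub>ig</sub>*,

&nbsp;&nbsp;&nbsp;&nbsp;m<sub>i</sub> = Σ<sub>g</sub> f<sub>ig</sub>·OR<sub>ig</sub>,&nbsp;&nbsp;&nbsp;
ñ<sub>ig</sub> = OR<sub>ig</sub> / m<sub>i</sub>,

so E<sub>f</sub>[ñ<sub>i</sub>] = 1: a normalized OR is risk relative to
the population average. A subject's **genetic risk** is the product
R = Π<sub>i</sub> ñ<sub>i,g(i)</sub>, and the **overall risk** multiplies in
the smoking OR (level "yes") and familiarity OR (level "present"); the
lowest levels ("no"/"absent") contribute exactly 1.

Under linkage equilibrium the population distribution of R is discrete
with at most 3<sup>k</sup> atoms and is enumerated **exactly**: atom risks
are products of normalized ORs, weights products of genotype frequencies.
The distribution among cases follows by risk tilting,
w<sup>case</sup> ∝ w·r (normalizing constant 1 when the population mean is
1). Reports place a subject by right-closed CDF percentile, by the mass of
subjects with "equal" risk (±0.15 on the OR scale), and by risk zone: low
(OR ≤ 0.7), high (OR ≥ 2.0), intermediate between.

The packaged panel `italian_wet_amd_v1` ships the published normalized ORs
with 95% CIs. No genotype frequencies are hard-coded; by default the tool
derives, per variant, the HWE allele frequency that is exactly consistent
with the normalized ORs (the root of
(1−q)²ñ<sub>rr</sub> + 2q(1−q)ñ<sub>het</sub> + q²ñ<sub>aa</sub> = 1), and
any 1000-Genomes-style frequency file can be supplied instead.

## Worked example

`subject.csv` (genotype allele order is free; `TC` ≡ `CT`):

```
subject_id,PT-001
rs1061170,TC
rs10490924,TT
rs2227306,CT
rs5749482,CC
rs8135665,CT
rs8017304,AG
rs943080,CT
rs13081855,GG
smoking,yes
familiarity,absent
```

`factors.json` — the non-genetic ORs are study-specific configuration with
no shipped defaults; these are synthetic illustration values:

```json
{"smoking_or": 1.9, "familiarity_or": 2.2}
```

```console
$ ware-risk score --profile subject.csv --factors factors.json --out report
subject: PT-001
genetic risk (OR scale): 5.44
overall risk (OR scale): 10.33
risk zone: high
percentile vs population: 96.9%
percentile vs cases: 26.9%
population with equal risk (±0.15): 0.2% (lower 96.8%, greater 3.0%)
cases with equal risk (±0.15): 1.0% (lower 26.5%, greater 72.5%)
```

The genetic risk 5.44 is the product 2.19 × 8.3 × 1.32 × 0.63 × 1.59 ×
1.15 × 1.23 × 0.16 of the subject's per-genotype normalized ORs — 5.4×
the population-average risk, higher than 96.9% of the general population
but only 26.9% of cases; being a smoker multiplies it by 1.9 to an overall
10.33, in the high-risk zone (≥ 2.0). `report/` contains `report.json`
(full precision, schema in `src/wareamd/data/report.schema.json`),
`report.txt`, two pie charts (lower/equal/greater risk in green/grey/red)
and two density plots with the low/high-risk zones shaded and a red
vertical line at the subject's risk, each as SVG and PNG.

Profiles can also come from a single-sample VCF (matched by rsID, alleles
checked against the panel): `ware-risk score --profile subject.vcf ...`.
Other subcommands: `ware-risk distribution` exports the exact risk
distributions as CSV; `ware-risk validate` checks panel/profile files.

From Python, the same computation is a scikit-learn-style estimator:

```python
import pandas as pd
from wareamd import MultiplicativeRiskScorer

scorer = MultiplicativeRiskScorer().fit()          # packaged Italian panel
X = pd.DataFrame([{"rs1061170": "TC", "rs10490924": "TT", "rs2227306": "CT",
                   "rs5749482": "CC", "rs8135665": "CT", "rs8017304": "AG",
                   "rs943080": "CT", "rs13081855": "GG"}])
scorer.predict(X)                                   # array([5.43724...])
```

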