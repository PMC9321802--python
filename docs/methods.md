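# Methods

## Model and assumptions

The package implements a multiplicative odds-ratio model for wet AMD risk.
Each panel variant is a biallelic SNP with one OR per genotype class; the
subject's genetic risk is the product of the ORs of their genotype classes,
and the overall risk additionally multiplies in the smoking and familiarity
ORs. Implicit assumptions:

- **Normalized ORs approximate relative risks.** Products of ORs across
  loci, and the case-tilting identity below, are exact for relative risks
  and a good approximation for ORs when the disease is uncommon at any
  single genotype stratum. The package reports everything on the OR scale
  and makes no prevalence conversion (no formula for one is defined here;
  an "absolute risk" probability would need the population prevalence and
  is out of scope).
- **No gene–gene or gene–environment interaction.** The model is strictly
  multiplicative.
- **Linkage equilibrium between panel variants.** The eight packaged loci
  lie on different chromosomes or chromosome arms (1q, 10q, 4q, 22q12,
  22q13, 14q, 6p, 3q), so independence of genotypes across loci is a
  defensible approximation; exact enumeration relies on it.

## Normalization

For a variant with genotype frequencies f = (f_rr, f_het, f_aa) and raw
ORs r = (r_rr, r_het, r_aa), the population mean risk is m = f·r and the
normalized ORs are r/m, so the frequency-weighted expectation of the
normalized OR is 1 — the module's defining contract, asserted to 1e-12
relative (the computation is one dot product and one division; 1e-9 is
used where several such contracts compose). Consequences used throughout:
normalization is invariant to rescaling all of a variant's raw ORs and is
idempotent. CI bounds are divided by the same per-variant mean as the
point value — the only transformation consistent with treating the CI as a
ratio interval around the point estimate; this is an assumption, since
published normalized CIs come without a stated recipe.

The packaged panel's normalized ORs are shipped as authoritative constants
and are never regenerated by the normalization routine (the underlying raw
ORs are not distributed with this package).

## Implied genotype frequencies

No genotype frequencies are shipped as ground truth: published panels cite
population databases whose exact release/superpopulation is not pinned
down, so every frequency table carries a mandatory free-text `source`
label, and files may give either genotype triples or alt-allele
frequencies (expanded as p², 2pq, q² under Hardy–Weinberg equilibrium).

For a panel that is already normalized there is a canonical choice: the
per-variant HWE alt-allele frequency q solving

    (1-q)^2 n_rr + 2q(1-q) n_het + q^2 n_aa = 1,

a quadratic with (generically) a single root in [0, 1] whenever
n_rr < 1 < n_aa. `implied_frequencies` applies this per variant, yielding
the unique HWE table under which the panel's mean-1 contract holds exactly
— self-consistent by construction, and the default for distribution
building (`--freqs implied`). A constant OR triple leaves q unidentifiable
and is rejected. Users with a preferred reference table (e.g. a specific
1000 Genomes superpopulation) should supply it explicitly.

## Exact distributions, percentiles, windows, zones

The population risk distribution enumerates all 3^k genotype combinations
(6561 for the packaged panel; vectorized outer products, well under a
second), merging identical risk values by exact float equality — a display
and storage economy that changes no probability. Case weights are obtained
by risk tilting, w_case ∝ w_pop·r, the standard case-enrichment identity;
its normalizing constant is the population mean, hence exactly 1 for a
normalized panel. How the shipped dashboard's case curves were originally
derived is not documented; tilting is this package's model-based choice,
and a user-supplied case frequency table through the same file format is
the supported alternative.

Reported statistics, all from the exact discrete distribution:

- **percentile** — right-closed CDF, P(R ≤ r); an atom exactly at the
  queried risk is included.
- **equal-risk window** — mass in the closed interval r ± h, default
  h = 0.15 OR units (the tool's published constant); "lower"/"greater"
  are the strict complements, and the three fractions partition the mass.
- **risk zones** — low for OR ≤ 0.7, high for OR ≥ 2.0 (the published
  boundaries), intermediate between; both boundaries are inclusive toward
  the more cautious label, and classification is monotone in risk.
- The subject's **genetic** risk is placed in the genotype-only
  distributions; the **overall** risk (genetic × non-genetic) only
  receives a zone label, since the enumerated distributions do not model
  the factor levels' population frequencies.

Density plots are a Gaussian-KDE view (Silverman bandwidth, weighted by
the atom probabilities) of the discrete distribution, for display only —
no probability is ever read off the smoothed curve.

The Monte-Carlo sampler (`sample_risks`) draws genotypes per variant and
serves as an independent oracle for the enumerator; the acceptance suite
checks the Kolmogorov–Smirnov distance of 10^5 samples against the exact
CDF at the asymptotic 99% bound 1.6276/√n, evaluating both one-sided
limits at every atom (both CDFs are step functions on the same support).

## Inputs and constraints

A risk estimate requires a genotype for **every** panel variant — missing
genotypes are an error naming the rsIDs, never imputed. Overall risk
requires both non-genetic levels; the guidance for an unknown factor is to
set its lowest level ("no"/"absent"), which leaves the risk unchanged
(exact equality, since the lowest levels multiply by the literal 1.0).
Genotype strings are unordered allele pairs, canonicalized alphabetically.
VCF profiles are matched by the ID column only (positional matching across
genome builds is out of scope); REF/ALT must equal the panel alleles —
allele swaps and strand flips are rejected, not auto-resolved, because
silent flipping is unsafe for ambiguous-strand SNPs. Multi-allelic records
and multi-sample batch scoring are out of scope (one sample per run). The
smoking and familiarity ORs ship with **no defaults**: they are mandatory
configuration, since their published values are study-specific.

Computation keeps full float precision; rounding to 2 decimals happens
only in the human-readable rendering. `report.json` carries full
precision and validates against the pydantic-generated schema in
`src/wareamd/data/report.schema.json`.

## Synthetic data generator

`wareamd.fixtures` draws raw panels under a log-additive allelic model
(reference OR 1, heterozygote OR uniform in a configurable range, default
[1, 3]; homozygote-alt its square — the dominant convention in the
risk-variant literature, chosen for the generator only and not a claim
about the packaged panel), alt-allele frequencies uniform in [0.05, 0.95]
(kept off the boundaries so all three genotype classes occur), HWE
genotype expansion, and cohorts with genotypes drawn from the frequency
table and factor levels Bernoulli(0.5). Everything is reproducible under a
seed. What it does **not** emulate about real data: linkage
disequilibrium, genotyping error and missingness, deviation from HWE,
correlation between genetic and non-genetic factors, and OR uncertainty
(synthetic CIs are a fixed ±20–25% band). Passing tests therefore
establish the internal consistency of normalization, scoring, enumeration
and sampling — not calibration of the packaged ORs against any cohort.

## Numerical choices and problem sizes

- Mean-1 contract: 1e-12 (single variant) / 1e-9 (composed across
  variants); frequency triples must sum to 1 within 1e-6 on input and are
  renormalized exactly.
- Window fractions are renormalized by their sum (≈1 up to float dust) so
  lower+equal+greater = 1 to 1e-12 for any risk and half-width.
- CSV floats are parsed with pandas' round-trip parser so canonical
  write→read cycles are bit-exact; canonical serialization uses shortest
  float repr.
- Quadratic root selection in `implied_allele_frequency`: the root in
  [0, 1] (clipped at 1e-12 tolerance); a near-zero quadratic coefficient
  falls back to the linear solution.
- Test/validation sizes: exact enumeration at k = 8 (6561 atoms); the
  normalization contract is swept over 1000 random panels; the sampler
  oracle uses 10^5 draws; cohort calibration uses n = 3000–4000 with
  chi-square goodness-of-fit at a 1e-4 floor. These sizes give tight
  statistical bounds while keeping the whole suite in seconds.

## Known limitations

- OR-scale output only; no conversion to absolute (probability-scale)
  risk, no age covariate, no CI on the combined product (the product of
  per-genotype CIs has no defensible joint coverage without the source
  covariance).
- The implied-frequency default is self-consistent but inherits any error
  in the published normalized ORs; it is not a substitute for a chosen
  reference population table when one is available.
- Case distribution by tilting assumes OR ≈ RR; for very high-risk
  genotype combinations this overstates enrichment.
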