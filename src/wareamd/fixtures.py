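"""Seeded synthetic panels, frequency tables and cohorts.

These generators make every layer of the package testable without external
data: raw panels follow a log-additive allelic model (heterozygote OR drawn
uniformly, homozygote-alt OR its square, reference OR 1), allele
frequencies are uniform in a configurable range and expanded under HWE,
and cohorts are drawn per-variant from the frequency table.  Everything is
reproducible under a fixed seed and writable through the same file formats
as real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import WareError
from .panel import (
    GenotypeFrequencyTable,
    GenotypeOR,
    RiskPanel,
    Variant,
    hwe_triple,
)
from .scoring import FAMILIARITY_LEVELS, SMOKING_LEVELS, SubjectProfile

__all__ = ["FixtureSpec", "random_raw_panel", "random_cohort"]

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic raw panel.

    allele_freq_range keeps alt frequencies away from 0/1 by default so
    all three genotype classes occur; raw_or_range is the heterozygote OR
    range of the log-additive model.
    """

    n_variants: int = 8
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    raw_or_range: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.allele_freq_range
        rlo, rhi = self.raw_or_range
        if self.n_variants < 1:
            raise WareError("n_variants must be >= 1")
        if not (0.0 < lo <= hi < 1.0):
            raise WareError("allele_freq_range must be a non-empty interval in (0, 1)")
        if not (0.0 < rlo <= rhi):
            raise WareError("raw_or_range must be a non-empty positive interval")


def random_raw_panel(spec: FixtureSpec) -> tuple[RiskPanel, GenotypeFrequencyTable]:
    """Draw a raw (un-normalized) panel and a matching HWE frequency table."""
    rng = np.random.default_rng(spec.seed)
    variants = []
    ors: dict[str, dict[str, GenotypeOR]] = {}
    freqs: dict[str, np.ndarray] = {}
    for i in range(spec.n_variants):
        ref, alt = rng.choice(_ALLELES, size=2, replace=False)
        v = Variant(rs_id=f"rs{9000000 + i}", gene=f"GENE{i + 1}",
                    ref=str(ref), alt=str(alt))
        variants.append(v)
        q = float(rng.uniform(*spec.allele_freq_range))
        freqs[v.rs_id] = hwe_triple(q)
        het = float(rng.uniform(*spec.raw_or_range))
        triple = (1.0, het, het * het)
        ors[v.rs_id] = {
            g: GenotypeOR(genotype=g, or_point=o, ci_low=o * 0.8, ci_high=o * 1.25)
            for g, o in zip(v.genotype_classes, triple)
        }
    panel = RiskPanel(variants, ors, provenance=f"synthetic raw panel (seed={spec.seed})")
    table = GenotypeFrequencyTable(freqs, source=f"synthetic HWE (seed={spec.seed})")
    return panel, table


def random_cohort(panel: RiskPanel, freqs: GenotypeFrequencyTable, n: int,
                  seed: int) -> list[SubjectProfile]:
    """Draw n subjects: genotypes from *freqs*, factor levels Bernoulli(0.5)."""
    if n < 1:
        raise WareError("n must be >= 1")
    freqs.require_panel(panel)
    rng = np.random.default_rng(seed)
    idx = {rs: rng.choice(3, size=n, p=freqs.triple(rs)) for rs in panel.rs_ids}
    smoking = rng.integers(0, 2, size=n)
    familiarity = rng.integers(0, 2, size=n)
    cohort = []
    for j in range(n):
        genotypes = {
            v.rs_id: v.genotype_classes[idx[v.rs_id][j]] for v in panel.variants
        }
        cohort.append(
            SubjectProfile(
                genotypes=genotypes,
                smoking=SMOKING_LEVELS[smoking[j]],
                familiarity=FAMILIARITY_LEVELS[familiarity[j]],
                subject_id=f"synthetic-{j}",
            )
        )
    return cohort
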