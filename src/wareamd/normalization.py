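"""Odds-ratio normalization to the population-average risk.

Raw per-genotype odds ratios are anchored to the reference genotype of the
source case-control study (OR = 1), which ignores how common each genotype
actually is.  Normalization rescales them so that the *population mean* risk
is 1: the genotype frequencies are multiplied by the raw ORs to obtain the
average risk m = sum_g f_g * OR_g, and every OR (and its CI bounds) is
divided by m.  After normalization, E_f[OR] = 1 exactly, so a subject's
multiplicative risk is directly interpretable relative to the population
average.

The inverse view is also useful: given an already-normalized OR triple, the
alt-allele frequency consistent with it under Hardy-Weinberg equilibrium is
the root in [0, 1] of the quadratic (1-q)^2 n_rr + 2q(1-q) n_het + q^2 n_aa
= 1.  :func:`implied_frequencies` applies this per variant, yielding the
frequency table that is exactly self-consistent with a packaged normalized
panel without hard-coding any external frequency estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FrequencyError, PanelValidationError
from .panel import GenotypeFrequencyTable, GenotypeOR, RiskPanel, hwe_triple

__all__ = [
    "NormalizationResult",
    "normalize_ors",
    "normalize_panel",
    "implied_allele_frequency",
    "implied_frequencies",
]


@dataclass(frozen=True)
class NormalizationResult:
    """Population-average risk and the rescaled (hom-ref, het, hom-alt) ORs."""

    mean_population_risk: float
    normalized: np.ndarray


def _check_triple(freqs) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if f.shape != (3,):
        raise FrequencyError("genotype frequencies must be a triple")
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise FrequencyError(f"genotype frequencies {f} do not form a probability triple")
    return f


def normalize_ors(raw, freqs) -> NormalizationResult:
    """Rescale a raw OR triple so its expectation under *freqs* is 1.

    Parameters
    ----------
    raw
        (hom-ref, het, hom-alt) raw odds ratios, all positive.
    freqs
        Matching genotype probabilities, summing to 1.
    """
    r = np.asarray(raw, dtype=float)
    if r.shape != (3,):
        raise PanelValidationError("raw odds ratios must be a triple")
    if (r <= 0).any() or not np.isfinite(r).all():
        raise PanelValidationError(f"raw odds ratios {r} must be positive and finite")
    f = _check_triple(freqs)
    mean = float(f @ r)
    return NormalizationResult(mean_population_risk=mean, normalized=r / mean)


def normalize_panel(raw_panel: RiskPanel, freqs: GenotypeFrequencyTable) -> RiskPanel:
    """Normalize every variant of *raw_panel* by its own population mean.

    CI bounds are divided by the same per-variant mean as the point values,
    the only rescaling consistent with treating the CI as a ratio interval.
    Normalizing an already-normalized panel is a no-op (each mean is 1).
    """
    freqs.require_panel(raw_panel)
    extra = [rs for rs in freqs.freqs if rs not in set(raw_panel.rs_ids)]
    if extra:
        raise FrequencyError(
            "frequency table covers variants absent from the panel: " + ", ".join(extra)
        )
    ors: dict[str, dict[str, GenotypeOR]] = {}
    for v in raw_panel.variants:
        res = normalize_ors(raw_panel.or_triple(v.rs_id), freqs.triple(v.rs_id))
        m = res.mean_population_risk
        ors[v.rs_id] = {
            g: GenotypeOR(
                genotype=g,
                or_point=raw_panel.ors[v.rs_id][g].or_point / m,
                ci_low=raw_panel.ors[v.rs_id][g].ci_low / m,
                ci_high=raw_panel.ors[v.rs_id][g].ci_high / m,
            )
            for g in v.genotype_classes
        }
    provenance = raw_panel.provenance
    if provenance and "normalized" not in provenance:
        provenance += f" [normalized; freqs: {freqs.source}]"
    return RiskPanel(raw_panel.variants, ors, provenance=provenance)


def implied_allele_frequency(normalized) -> float:
    """Alt-allele frequency q in [0, 1] consistent with a normalized triple.

    Solves (1-q)^2 n_rr + 2 q(1-q) n_het + q^2 n_aa = 1 (HWE genotype
    probabilities, population mean 1).  Raises if the triple is constant
    (any q satisfies the identity, so q is unidentifiable) or if no root
    lies in [0, 1].
    """
    n = np.asarray(normalized, dtype=float)
    if n.shape != (3,) or (n <= 0).any():
        raise PanelValidationError("normalized odds ratios must be a positive triple")
    n_rr, n_het, n_aa = n
    a = n_rr - 2.0 * n_het + n_aa
    b = 2.0 * (n_het - n_rr)
    c = n_rr - 1.0
    if abs(a) < 1e-14 and abs(b) < 1e-14:
        raise PanelValidationError(
            "constant odds-ratio triple: implied frequency is unidentifiable"
        )
    if abs(a) < 1e-14:
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise PanelValidationError("no real implied allele frequency")
        sq = float(np.sqrt(disc))
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    valid = [q for q in roots if -1e-12 <= q <= 1.0 + 1e-12]
    if not valid:
        raise PanelValidationError(
            f"no implied allele frequency in [0, 1] for triple {n.tolist()}"
        )
    return float(min(max(valid[0], 0.0), 1.0)) if len(valid) == 1 else float(
        min(max(min(valid), 0.0), 1.0)
    )


def implied_frequencies(panel: RiskPanel) -> GenotypeFrequencyTable:
    """HWE genotype frequencies exactly self-consistent with *panel*.

    For each variant the alt-allele frequency solving the mean-1 identity is
    expanded to (p^2, 2pq, q^2).  Only meaningful for a panel whose ORs are
    already population-normalized.
    """
    freqs = {
        v.rs_id: hwe_triple(implied_allele_frequency(panel.or_triple(v.rs_id)))
        for v in panel.variants
    }
    return GenotypeFrequencyTable(freqs, source=f"implied:{panel.provenance or 'panel'} (HWE)")
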