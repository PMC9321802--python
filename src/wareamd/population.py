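"""Exact risk distributions over all genotype combinations.

With k independent biallelic variants (the panel loci sit on different
chromosomes or chromosome arms, so linkage equilibrium is assumed), the
multiplicative genetic risk takes at most 3^k values.  The population
distribution enumerates them exactly: each combination's risk is the
product of normalized ORs and its weight the product of genotype
frequencies.  The distribution among cases follows by risk tilting,
w_case ∝ w_pop * r — the standard case-enrichment identity when the
normalized ORs approximate relative risks; for a population distribution
with mean exactly 1 the tilting constant is 1.

All probabilities reported downstream (percentiles, equal-risk-window pie
fractions) are computed from the exact discrete distribution; kernel
density smoothing is used for display only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ProfileError, WareError
from .panel import GenotypeFrequencyTable, RiskPanel

__all__ = [
    "RiskDistribution",
    "WindowFractions",
    "ZoneConfig",
    "DEFAULT_HALF_WIDTH",
    "population_distribution",
    "case_distribution",
    "window_fractions",
    "percentile",
    "classify_zone",
    "sample_risks",
    "ks_distance",
]

#: Half-width (OR units) of the "equal risk" window used for pie charts.
DEFAULT_HALF_WIDTH = 0.15

ZONE_ORDER = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ZoneConfig:
    """Risk-zone boundaries on the OR scale.

    Defaults: the low-risk zone ends at OR 0.7 and the high-risk zone
    starts at OR 2.0; both boundaries are inclusive toward the more
    cautious label (<=0.7 is low, >=2.0 is high).
    """

    low_boundary: float = 0.7
    high_boundary: float = 2.0

    def __post_init__(self):
        if not 0 < self.low_boundary < self.high_boundary:
            raise WareError(
                f"invalid zone boundaries ({self.low_boundary}, {self.high_boundary})"
            )


@dataclass(frozen=True)
class WindowFractions:
    """Probability mass below / inside / above the equal-risk window."""

    lower: float
    equal: float
    greater: float
    half_width: float = DEFAULT_HALF_WIDTH


class RiskDistribution:
    """Weighted discrete distribution of multiplicative risk.

    Parameters
    ----------
    support
        Distinct positive risk values, sorted ascending.
    weights
        Matching probabilities (non-negative, summing to 1 within 1e-9).
    kind
        "population" or "case".
    """

    def __init__(self, support, weights, kind: str = "population"):
        s = np.asarray(support, dtype=float)
        w = np.asarray(weights, dtype=float)
        if s.shape != w.shape or s.ndim != 1:
            raise WareError("support and weights must be matching 1-d arrays")
        if (s <= 0).any():
            raise WareError("risk values must be positive")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise WareError(f"weights must be non-negative and sum to 1 (got {w.sum()})")
        if kind not in ("population", "case"):
            raise WareError(f"kind must be 'population' or 'case', got {kind!r}")
        order = np.argsort(s)
        self.support = s[order]
        self.weights = w[order]
        self.kind = kind

    def mean(self) -> float:
        return float(self.support @ self.weights)

    def cdf(self, x: float) -> float:
        """Right-closed CDF: total mass at risk values <= x."""
        return float(self.weights[self.support <= x].sum())

    def __len__(self) -> int:
        return len(self.support)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"risk": self.support, "weight": self.weights, "kind": self.kind}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _merge_atoms(risks: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    support, inverse = np.unique(risks, return_inverse=True)
    merged = np.zeros_like(support)
    np.add.at(merged, inverse, weights)
    return support, merged


def population_distribution(panel: RiskPanel, freqs: GenotypeFrequencyTable
                            ) -> RiskDistribution:
    """Exact enumeration of the 3^k genotype-combination risk distribution.

    Each combination's risk is the product of the per-variant normalized
    ORs, weighted by the product of genotype frequencies (inter-variant
    independence).  Identical risk values are merged with summed weights.
    Built from a normalized panel the result has mean 1.
    """
    freqs.require_panel(panel)
    if len(panel) == 0:
        return RiskDistribution([1.0], [1.0], kind="population")
    or_arrays = [panel.or_triple(rs) for rs in panel.rs_ids]
    freq_arrays = [freqs.triple(rs) for rs in panel.rs_ids]
    risks = reduce(np.multiply.outer, or_arrays).ravel()
    weights = reduce(np.multiply.outer, freq_arrays).ravel()
    keep = weights > 0
    support, merged = _merge_atoms(risks[keep], weights[keep])
    return RiskDistribution(support, merged / merged.sum(), kind="population")


def case_distribution(pop: RiskDistribution) -> RiskDistribution:
    """Risk-tilted distribution among cases: w_case_i = w_i * r_i / sum(w r).

    The normalizing constant sum(w r) is the population mean risk, so it is
    exactly 1 for a distribution built from a normalized panel.
    """
    if pop.kind != "population":
        raise WareError("case_distribution expects a population-kind distribution")
    tilt = pop.weights * pop.support
    return RiskDistribution(pop.support, tilt / tilt.sum(), kind="case")


def window_fractions(dist: RiskDistribution, risk: float,
                     half_width: float = DEFAULT_HALF_WIDTH) -> WindowFractions:
    """Mass below, within (closed interval), and above risk +/- half_width."""
    if not half_width > 0:
        raise WareError("half_width must be positive")
    lower = float(dist.weights[dist.support < risk - half_width].sum())
    greater = float(dist.weights[dist.support > risk + half_width].sum())
    equal = float(
        dist.weights[
            (dist.support >= risk - half_width) & (dist.support <= risk + half_width)
        ].sum()
    )
    # renormalize float dust so the three parts partition the mass exactly
    total = lower + equal + greater
    return WindowFractions(lower=lower / total, equal=equal / total,
                           greater=greater / total, half_width=half_width)


def percentile(dist: RiskDistribution, risk: float) -> float:
    """Fraction of the distribution at or below *risk* (right-closed CDF)."""
    return dist.cdf(risk)


def classify_zone(risk: float, zones: ZoneConfig = ZoneConfig()) -> str:
    """"low" (<= low boundary), "high" (>= high boundary), else "intermediate"."""
    if not risk > 0:
        raise ProfileError(f"risk must be positive, got {risk}")
    if risk <= zones.low_boundary:
        return "low"
    if risk >= zones.high_boundary:
        return "high"
    return "intermediate"


def sample_risks(panel: RiskPanel, freqs: GenotypeFrequencyTable, n: int,
                 seed: int) -> np.ndarray:
    """Monte-Carlo oracle: risks of n random profiles drawn from *freqs*.

    Genotypes are sampled independently per variant; the empirical CDF of
    the result converges to the exact enumeration of
    :func:`population_distribution`.  Deterministic under a fixed seed.
    """
    if n <= 0:
        raise WareError("n must be positive")
    freqs.require_panel(panel)
    rng = np.random.default_rng(seed)
    risks = np.ones(n)
    for rs in panel.rs_ids:
        ors = panel.or_triple(rs)
        idx = rng.choice(3, size=n, p=freqs.triple(rs))
        risks *= ors[idx]
    return risks


def ks_distance(samples, dist: RiskDistribution) -> float:
    """Kolmogorov-Smirnov distance between an empirical sample and *dist*.

    Both CDFs are step functions jumping only at the support values, so the
    supremum of |F_n - F| is attained at a support point, approached from
    the left or the right; both sides are checked.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    cdf = np.cumsum(dist.weights)
    fn_right = np.searchsorted(x, dist.support, side="right") / n
    fn_left = np.searchsorted(x, dist.support, side="left") / n
    return float(
        max(
            np.abs(fn_right - cdf).max(),
            np.abs(fn_left - (cdf - dist.weights)).max(),
        )
    )
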