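"""Risk report assembly, JSON serialization and plot rendering.

The JSON report carries full float precision; the human-readable summary
rounds to 2 decimals.  Pie fractions and percentiles come from the exact
discrete distributions; the density curves are a Gaussian-kernel smoothed
view (Silverman bandwidth) used for display only, with the low-risk zone
shaded green, the high-risk zone red, and a red vertical line at the
subject's genetic risk.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Annotated

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from pydantic import BaseModel, Field
from scipy.stats import gaussian_kde

from .errors import WareError
from .panel import GenotypeFrequencyTable, NonGeneticFactors, RiskPanel
from .population import (
    DEFAULT_HALF_WIDTH,
    RiskDistribution,
    WindowFractions,
    ZoneConfig,
    case_distribution,
    classify_zone,
    percentile,
    population_distribution,
    window_fractions,
)
from .scoring import MultiplicativeRiskScorer, SubjectProfile

__all__ = ["RiskReport", "RiskReportModel", "compute_report", "render_report"]

Prob = Annotated[float, Field(ge=0.0, le=1.0)]


class WindowFractionsModel(BaseModel):
    lower: Prob
    equal: Prob
    greater: Prob
    half_width: Annotated[float, Field(gt=0.0)]


class RiskReportModel(BaseModel):
    """Schema of report.json (shipped as data/report.schema.json)."""

    subject_id: str
    genetic_risk: Annotated[float, Field(gt=0.0)]
    overall_risk: Annotated[float, Field(gt=0.0)]
    zone: Annotated[str, Field(pattern="^(low|intermediate|high)$")]
    percentile_population: Prob
    percentile_cases: Prob
    window_fractions_population: WindowFractionsModel
    window_fractions_cases: WindowFractionsModel
    panel_provenance: str
    inputs_echo: dict[str, str]


class RiskReport(RiskReportModel):
    """A computed risk report (validated pydantic model).

    ``genetic_risk`` is compared against the genotype-only population and
    case distributions (percentiles, window fractions); the zone label
    classifies the ``overall_risk`` that also includes the non-genetic
    factors.
    """


def compute_report(profile: SubjectProfile, panel: RiskPanel,
                   freqs: GenotypeFrequencyTable, factors: NonGeneticFactors,
                   zones: ZoneConfig = ZoneConfig(),
                   half_width: float = DEFAULT_HALF_WIDTH,
                   ) -> tuple[RiskReport, RiskDistribution, RiskDistribution]:
    """Score *profile* and situate it in the population and case distributions.

    Returns the report plus the two exact distributions (for rendering or
    export).
    """
    scorer = MultiplicativeRiskScorer(panel=panel, factors=factors).fit()
    values = scorer.score_profile(profile)
    pop = population_distribution(panel, freqs)
    cases = case_distribution(pop)
    echo = dict(profile.genotypes)
    echo["smoking"] = profile.smoking or ""
    echo["familiarity"] = profile.familiarity or ""
    report = RiskReport(
        subject_id=profile.subject_id,
        genetic_risk=values.genetic_risk,
        overall_risk=values.overall_risk,
        zone=classify_zone(values.overall_risk, zones),
        percentile_population=percentile(pop, values.genetic_risk),
        percentile_cases=percentile(cases, values.genetic_risk),
        window_fractions_population=_wf_model(
            window_fractions(pop, values.genetic_risk, half_width)),
        window_fractions_cases=_wf_model(
            window_fractions(cases, values.genetic_risk, half_width)),
        panel_provenance=panel.provenance,
        inputs_echo=echo,
    )
    return report, pop, cases


def _wf_model(wf: WindowFractions) -> WindowFractionsModel:
    return WindowFractionsModel(lower=wf.lower, equal=wf.equal, greater=wf.greater,
                                half_width=wf.half_width)


def _pie(wf: WindowFractionsModel, title: str, path_base: Path) -> list[Path]:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.pie(
        [wf.lower, wf.equal, wf.greater],
        labels=["lower risk", "equal risk", "greater risk"],
        colors=["forestgreen", "grey", "firebrick"],
        autopct="%1.1f%%",
        startangle=90,
    )
    ax.set_title(title)
    return _save(fig, path_base)


def _density(dist: RiskDistribution, risk: float, zones: ZoneConfig, title: str,
             path_base: Path) -> list[Path]:
    fig, ax = plt.subplots(figsize=(6, 4))
    hi = max(dist.support.max(), risk, zones.high_boundary) * 1.05
    xs = np.linspace(0.0, hi, 512)
    if len(dist) > 1:
        kde = gaussian_kde(dist.support, weights=dist.weights, bw_method="silverman")
        ax.plot(xs, kde(xs), color="black", lw=1.5)
    else:
        ax.axvline(dist.support[0], color="black", lw=1.5)
    ax.axvspan(0.0, zones.low_boundary, color="forestgreen", alpha=0.25,
               label=f"low-risk zone (OR ≤ {zones.low_boundary})")
    ax.axvspan(zones.high_boundary, hi, color="firebrick", alpha=0.25,
               label=f"high-risk zone (OR ≥ {zones.high_boundary})")
    ax.axvline(risk, color="red", lw=2, label=f"subject risk = {risk:.2f}")
    ax.set_xlabel("multiplicative risk (OR scale)")
    ax.set_ylabel("density")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    return _save(fig, path_base)


def _save(fig, path_base: Path) -> list[Path]:
    out = []
    for ext in ("svg", "png"):
        p = path_base.with_suffix(f".{ext}")
        fig.savefig(p, dpi=120, bbox_inches="tight")
        out.append(p)
    plt.close(fig)
    return out


def render_report(report: RiskReport, pop: RiskDistribution, cases: RiskDistribution,
                  out_dir: str | Path, zones: ZoneConfig = ZoneConfig(),
                  plots: bool = True) -> dict[str, Path]:
    """Write report.json, a text summary, and the four plots to *out_dir*.

    Returns a name -> path map of everything written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise WareError(f"cannot create output directory {out_dir}: {exc}") from exc
    files: dict[str, Path] = {}

    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report.model_dump(), indent=2) + "\n")
    files["report_json"] = json_path

    txt_path = out_dir / "report.txt"
    txt_path.write_text(_text_summary(report))
    files["report_txt"] = txt_path

    if plots:
        for kind, dist, wf, pct in (
            ("population", pop, report.window_fractions_population,
             report.percentile_population),
            ("cases", cases, report.window_fractions_cases, report.percentile_cases),
        ):
            for p in _pie(wf, f"risk relative to {kind}", out_dir / f"pie_{kind}"):
                files[p.name] = p
            for p in _density(dist, report.genetic_risk, zones,
                              f"risk distribution: {kind}", out_dir / f"density_{kind}"):
                files[p.name] = p
    return files


def _text_summary(report: RiskReport) -> str:
    wp, wc = report.window_fractions_population, report.window_fractions_cases
    return (
        f"subject: {report.subject_id}\n"
        f"genetic risk (OR scale): {report.genetic_risk:.2f}\n"
        f"overall risk (OR scale): {report.overall_risk:.2f}\n"
        f"risk zone: {report.zone}\n"
        f"percentile vs population: {100 * report.percentile_population:.1f}%\n"
        f"percentile vs cases: {100 * report.percentile_cases:.1f}%\n"
        f"population with equal risk (±{wp.half_width:g}): {100 * wp.equal:.1f}%"
        f" (lower {100 * wp.lower:.1f}%, greater {100 * wp.greater:.1f}%)\n"
        f"cases with equal risk (±{wc.half_width:g}): {100 * wc.equal:.1f}%"
        f" (lower {100 * wc.lower:.1f}%, greater {100 * wc.greater:.1f}%)\n"
        f"panel: {report.panel_provenance}\n"
    )
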