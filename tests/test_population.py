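"""Exact risk distributions: enumeration, tilting, windows, zones, MC oracle."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from wareamd import (
    GenotypeFrequencyTable,
    ProfileError,
    RiskDistribution,
    ZoneConfig,
    case_distribution,
    classify_zone,
    ks_distance,
    normalize_panel,
    percentile,
    population_distribution,
    sample_risks,
    window_fractions,
)
from wareamd.fixtures import FixtureSpec, random_raw_panel
from conftest import make_panel


@pytest.fixture()
def four_point(two_variant_panel):
    panel, freqs = two_variant_panel
    return population_distribution(panel, freqs)


def test_two_variant_enumeration(four_point):
    # hand enumeration: {0.5,1.5} x {0.8,1.2} each with weight 0.25
    assert four_point.support == pytest.approx([0.4, 0.6, 1.2, 1.8], abs=1e-15)
    assert four_point.weights == pytest.approx([0.25] * 4, abs=1e-15)
    assert four_point.mean() == pytest.approx(1.0, abs=1e-15)


def test_degenerate_frequency_is_point_mass():
    panel = make_panel({("rs1", "G1", "A", "G"): (1.0, 2.0, 4.0)})
    freqs = GenotypeFrequencyTable({"rs1": (1.0, 0.0, 0.0)}, source="hand")
    norm = normalize_panel(panel, freqs)
    dist = population_distribution(norm, freqs)
    assert len(dist) == 1
    assert dist.support[0] == pytest.approx(1.0, abs=1e-15)  # mean-1 contract


def test_identical_risks_merge():
    # two identical variants: products 0.25, 0.5 (x2 paths), 1 -> 3 atoms
    panel = make_panel({
        ("rs1", "G1", "A", "G"): (0.5, 1.0, 2.0),
        ("rs2", "G2", "C", "T"): (0.5, 1.0, 2.0),
    })
    freqs = GenotypeFrequencyTable(
        {"rs1": (0.5, 0.0, 0.5), "rs2": (0.5, 0.0, 0.5)}, source="hand"
    )
    dist = population_distribution(panel, freqs)
    assert dist.support == pytest.approx([0.25, 1.0, 4.0])
    assert dist.weights == pytest.approx([0.25, 0.5, 0.25])


def test_case_tilting_example(four_point):
    cases = case_distribution(four_point)
    assert cases.kind == "case"
    assert cases.weights == pytest.approx([0.10, 0.15, 0.30, 0.45], abs=1e-12)


def test_case_of_point_mass_is_point_mass():
    pop = RiskDistribution([1.0], [1.0])
    cases = case_distribution(pop)
    assert cases.support == pytest.approx([1.0])
    assert cases.weights == pytest.approx([1.0])


def test_case_requires_population_kind(four_point):
    with pytest.raises(Exception, match="population"):
        case_distribution(case_distribution(four_point))


def test_window_fractions_example(four_point):
    wf = window_fractions(four_point, risk=1.2, half_width=0.15)
    assert (wf.lower, wf.equal, wf.greater) == pytest.approx((0.5, 0.25, 0.25))


def test_window_far_above_support(four_point):
    wf = window_fractions(four_point, risk=100.0)
    assert (wf.lower, wf.equal, wf.greater) == pytest.approx((1.0, 0.0, 0.0))
    assert wf.half_width == 0.15  # packaged default


@settings(deadline=None, derandomize=True, max_examples=50,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(st.floats(0.01, 3.0), st.floats(0.01, 2.0))
def test_window_partitions_mass(four_point, risk, h):
    wf = window_fractions(four_point, risk, h)
    assert wf.lower + wf.equal + wf.greater == pytest.approx(1.0, abs=1e-12)
    assert min(wf.lower, wf.equal, wf.greater) >= 0.0


def test_percentile_right_closed(four_point):
    assert percentile(four_point, 1.0) == pytest.approx(0.5)
    # querying exactly at an atom includes its mass (right-closed CDF)
    assert percentile(four_point, four_point.support[2]) == pytest.approx(0.75)
    assert percentile(four_point, 0.1) == 0.0
    assert percentile(four_point, four_point.support[-1]) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "risk, zone",
    [(0.5, "low"), (0.7, "low"), (0.71, "intermediate"), (1.0, "intermediate"),
     (1.99, "intermediate"), (2.0, "high"), (2.5, "high")],
)
def test_classify_zone(risk, zone):
    assert classify_zone(risk) == zone


def test_zone_monotone_and_validated():
    order = {"low": 0, "intermediate": 1, "high": 2}
    risks = np.linspace(0.05, 4.0, 200)
    zones = [order[classify_zone(r)] for r in risks]
    assert all(a <= b for a, b in zip(zones, zones[1:]))
    with pytest.raises(ProfileError):
        classify_zone(0.0)
    with pytest.raises(Exception):
        ZoneConfig(low_boundary=2.0, high_boundary=0.7)


@settings(deadline=None, derandomize=True, max_examples=10)
@given(st.integers(0, 10_000), st.integers(1, 6))
def test_population_mean_one_and_bounds(seed, k):
    raw, freqs = random_raw_panel(FixtureSpec(n_variants=k, seed=seed))
    panel = normalize_panel(raw, freqs)
    dist = population_distribution(panel, freqs)
    assert len(dist) <= 3**k
    assert dist.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.mean() == pytest.approx(1.0, abs=1e-9)
    cases = case_distribution(dist)
    assert cases.mean() >= dist.mean() - 1e-12


def test_sampling_deterministic_and_unbiased(two_variant_panel):
    panel, freqs = two_variant_panel
    a = sample_risks(panel, freqs, 2000, seed=7)
    b = sample_risks(panel, freqs, 2000, seed=7)
    assert np.array_equal(a, b)
    dist = population_distribution(panel, freqs)
    se = np.sqrt(np.average((dist.support - 1.0) ** 2, weights=dist.weights) / a.size)
    assert abs(a.mean() - dist.mean()) < 3 * se


def test_sampling_degenerate_single_draw():
    panel = make_panel({("rs1", "G1", "A", "G"): (1.0, 2.0, 4.0)})
    freqs = GenotypeFrequencyTable({"rs1": (1.0, 0.0, 0.0)}, source="hand")
    assert sample_risks(panel, freqs, 1, seed=0) == pytest.approx([1.0])


def test_empirical_cdf_matches_enumeration():
    raw, freqs = random_raw_panel(FixtureSpec(n_variants=8, seed=123))
    panel = normalize_panel(raw, freqs)
    dist = population_distribution(panel, freqs)
    n = 100_000
    samples = sample_risks(panel, freqs, n, seed=456)
    # 99% one-sample KS bound, asymptotic
    assert ks_distance(samples, dist) < 1.6276 / np.sqrt(n)


def test_distribution_export(tmp_path, four_point):
    path = tmp_path / "dist.csv"
    four_point.to_csv(path)
    header, first = path.read_text().splitlines()[:2]
    assert header == "risk,weight,kind"
    assert first.endswith("population")
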