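"""Risk engine: multiplicative scoring, constraints, estimator surface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from wareamd import (
    MissingGenotypeError,
    MultiplicativeRiskScorer,
    NonGeneticFactors,
    PanelValidationError,
    ProfileError,
    SubjectProfile,
    UnsetFactorError,
    genetic_risk,
    normalize_panel,
    overall_risk,
)
from wareamd.fixtures import FixtureSpec, random_cohort, random_raw_panel
from conftest import HET_GENOTYPES, make_panel


def test_two_variant_product(packaged_panel):
    # brute-force oracle: 2.38 * 2.19 multiplied by hand
    sub = make_panel({
        ("rs10490924", "ARMS2", "G", "T"): tuple(packaged_panel.or_triple("rs10490924")),
        ("rs1061170", "CFH", "T", "C"): tuple(packaged_panel.or_triple("rs1061170")),
    })
    profile = SubjectProfile(genotypes={"rs10490924": "GT", "rs1061170": "CT"})
    assert genetic_risk(profile, sub) == pytest.approx(5.2122, abs=1e-12)


def test_identity_product():
    panel = make_panel({("rs1", "G1", "A", "G"): (1.0, 1.0, 1.0)})
    profile = SubjectProfile(genotypes={"rs1": "AG"})
    assert genetic_risk(profile, panel) == 1.0


def test_missing_genotypes_named(packaged_panel):
    genotypes = dict(HET_GENOTYPES)
    del genotypes["rs943080"], genotypes["rs1061170"]
    with pytest.raises(MissingGenotypeError) as exc:
        genetic_risk(SubjectProfile(genotypes=genotypes), packaged_panel)
    assert exc.value.rs_ids == ["rs1061170", "rs943080"]


def test_foreign_genotype_rejected(packaged_panel):
    genotypes = dict(HET_GENOTYPES, rs1061170="AA")
    with pytest.raises(PanelValidationError, match="rs1061170"):
        genetic_risk(SubjectProfile(genotypes=genotypes), packaged_panel)


def test_lowest_levels_are_exactly_neutral(synthetic_factors):
    for g in (0.1, 1.0, 2.5, 431.7):
        assert overall_risk(g, "no", "absent", synthetic_factors) == g


def test_overall_risk_product(synthetic_factors):
    assert overall_risk(2.0, "yes", "present", synthetic_factors) == pytest.approx(
        2.0 * 1.9 * 2.2, abs=1e-12
    )
    f1 = NonGeneticFactors(smoking_or=1.0, familiarity_or=1.0)
    assert overall_risk(1.0, "yes", "present", f1) == 1.0


def test_unset_levels_error_with_guidance(synthetic_factors):
    with pytest.raises(UnsetFactorError, match="lowest level"):
        overall_risk(2.0, None, "absent", synthetic_factors)
    with pytest.raises(UnsetFactorError, match="familiarity"):
        overall_risk(2.0, "no", None, synthetic_factors)
    with pytest.raises(ProfileError):
        overall_risk(-1.0, "no", "absent", synthetic_factors)


def test_invalid_levels_rejected(synthetic_factors):
    with pytest.raises(ProfileError):
        overall_risk(2.0, "sometimes", "absent", synthetic_factors)
    with pytest.raises(ProfileError):
        SubjectProfile(genotypes={}, smoking="maybe")


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000), st.integers(0, 2), st.integers(0, 7))
def test_monotone_in_genotype_or(seed, cls, pos):
    """Swapping a genotype for one with a larger OR never lowers the risk."""
    raw, freqs = random_raw_panel(FixtureSpec(n_variants=8, seed=seed))
    panel = normalize_panel(raw, freqs)
    profile = random_cohort(panel, freqs, 1, seed=seed + 1)[0]
    base = genetic_risk(profile, panel)
    v = panel.variants[pos]
    old = panel.ors[v.rs_id][profile.genotypes[v.rs_id]].or_point
    new_g = v.genotype_classes[cls]
    profile.genotypes[v.rs_id] = new_g
    swapped = genetic_risk(profile, panel)
    if panel.ors[v.rs_id][new_g].or_point >= old:
        assert swapped >= base
    else:
        assert swapped <= base


@settings(deadline=None, derandomize=True, max_examples=15)
@given(st.integers(0, 10_000))
def test_order_independence(seed):
    raw, freqs = random_raw_panel(FixtureSpec(n_variants=6, seed=seed))
    panel = normalize_panel(raw, freqs)
    profile = random_cohort(panel, freqs, 1, seed=seed + 1)[0]
    base = genetic_risk(profile, panel)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(panel.variants))
    shuffled = type(panel)(
        [panel.variants[i] for i in perm], panel.ors, provenance=panel.provenance
    )
    assert genetic_risk(profile, shuffled) == pytest.approx(base, rel=1e-12)


class TestEstimatorSurface:
    def test_sklearn_protocol(self, packaged_panel, synthetic_factors):
        scorer = MultiplicativeRiskScorer(panel=packaged_panel,
                                          factors=synthetic_factors)
        assert scorer.get_params() == {
            "panel": packaged_panel, "factors": synthetic_factors
        }
        cloned = clone(scorer)  # clone deep-copies non-estimator params
        assert cloned.get_params()["panel"] == packaged_panel
        with pytest.raises(ProfileError, match="not fitted"):
            scorer.predict(pd.DataFrame([HET_GENOTYPES]))
        fitted = scorer.fit()
        assert fitted is scorer and fitted.rs_ids_ == packaged_panel.rs_ids

    def test_default_panel_resolved_at_fit(self):
        scorer = MultiplicativeRiskScorer().fit()
        assert len(scorer.panel_) == 8

    def test_predict_matches_functional_path(self, packaged_panel):
        scorer = MultiplicativeRiskScorer(panel=packaged_panel).fit()
        X = pd.DataFrame([HET_GENOTYPES, dict(HET_GENOTYPES, rs10490924="TT")])
        expected = [
            genetic_risk(SubjectProfile(genotypes=dict(r)), packaged_panel)
            for _, r in X.iterrows()
        ]
        assert scorer.predict(X) == pytest.approx(expected, rel=1e-15)

    def test_predict_with_factor_columns(self, packaged_panel, synthetic_factors):
        scorer = MultiplicativeRiskScorer(panel=packaged_panel,
                                          factors=synthetic_factors).fit()
        X = pd.DataFrame([
            dict(HET_GENOTYPES, smoking="no", familiarity="absent"),
            dict(HET_GENOTYPES, smoking="yes", familiarity="present"),
        ])
        risks = scorer.predict(X)
        assert risks[1] == pytest.approx(risks[0] * 1.9 * 2.2, rel=1e-12)

    def test_one_factor_column_is_an_error(self, packaged_panel, synthetic_factors):
        scorer = MultiplicativeRiskScorer(panel=packaged_panel,
                                          factors=synthetic_factors).fit()
        X = pd.DataFrame([dict(HET_GENOTYPES, smoking="yes")])
        with pytest.raises(UnsetFactorError, match="familiarity"):
            scorer.predict(X)

    def test_score_profile(self, packaged_panel, synthetic_factors, het_profile):
        scorer = MultiplicativeRiskScorer(panel=packaged_panel,
                                          factors=synthetic_factors).fit()
        values = scorer.score_profile(het_profile)
        assert values.overall_risk == values.genetic_risk  # lowest levels
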