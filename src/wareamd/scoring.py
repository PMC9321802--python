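"""Individual risk scoring: the product of associated odds ratios.

The genetic risk of a subject is the product, over the panel variants, of
the normalized OR of the subject's genotype class.  The overall risk then
multiplies in the non-genetic factor ORs (smoking, familiarity), with the
lowest levels ("no", "absent") contributing a factor of exactly 1, so they
never change the genetic risk.  The model is strictly multiplicative: no
interaction terms.

Scoring refuses to guess: a missing genotype, or an unset non-genetic
level when the overall risk is requested, is an error that names what is
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import MissingGenotypeError, ProfileError, UnsetFactorError
from .panel import NonGeneticFactors, RiskPanel, default_panel

__all__ = [
    "SubjectProfile",
    "RiskValues",
    "genetic_risk",
    "overall_risk",
    "MultiplicativeRiskScorer",
    "SMOKING_LEVELS",
    "FAMILIARITY_LEVELS",
]

SMOKING_LEVELS = ("no", "yes")
FAMILIARITY_LEVELS = ("absent", "present")


@dataclass
class SubjectProfile:
    """One subject: a genotype per panel variant plus non-genetic levels.

    ``smoking`` / ``familiarity`` stay ``None`` when unset; the overall
    risk cannot be computed until both are set.
    """

    genotypes: dict[str, str] = field(default_factory=dict)
    smoking: str | None = None
    familiarity: str | None = None
    subject_id: str = "subject"

    def __post_init__(self):
        if self.smoking is not None and self.smoking not in SMOKING_LEVELS:
            raise ProfileError(f"smoking level must be one of {SMOKING_LEVELS}")
        if self.familiarity is not None and self.familiarity not in FAMILIARITY_LEVELS:
            raise ProfileError(f"familiarity level must be one of {FAMILIARITY_LEVELS}")


@dataclass(frozen=True)
class RiskValues:
    """Genetic and overall multiplicative risk on the OR scale."""

    genetic_risk: float
    overall_risk: float


def genetic_risk(profile: SubjectProfile, panel: RiskPanel) -> float:
    """Product of the normalized ORs of the subject's genotype classes.

    Raises :class:`MissingGenotypeError` naming every panel variant for
    which the profile has no genotype (all genotypes are required), and
    :class:`~wareamd.errors.PanelValidationError` for a genotype outside
    the variant's three classes.
    """
    missing = [rs for rs in panel.rs_ids if rs not in profile.genotypes]
    if missing:
        raise MissingGenotypeError(missing)
    risk = 1.0
    for v in panel.variants:
        risk *= panel.lookup(v.rs_id, profile.genotypes[v.rs_id]).or_point
    return risk


def overall_risk(genetic: float, smoking_level: str | None, familiarity_level: str | None,
                 factors: NonGeneticFactors) -> float:
    """Combine a genetic risk with the non-genetic factor ORs.

    overall = genetic * (smoking_or if "yes" else 1)
                      * (familiarity_or if "present" else 1)

    Both levels must be set; the documented guidance for an unknown factor
    is to set its lowest level, which leaves the risk unchanged.
    """
    if not genetic > 0:
        raise ProfileError(f"genetic risk must be positive, got {genetic}")
    if smoking_level is None:
        raise UnsetFactorError("smoking")
    if familiarity_level is None:
        raise UnsetFactorError("familiarity")
    if smoking_level not in SMOKING_LEVELS:
        raise ProfileError(f"smoking level must be one of {SMOKING_LEVELS}")
    if familiarity_level not in FAMILIARITY_LEVELS:
        raise ProfileError(f"familiarity level must be one of {FAMILIARITY_LEVELS}")
    risk = genetic
    if smoking_level == "yes":
        risk *= factors.smoking_or
    if familiarity_level == "present":
        risk *= factors.familiarity_or
    return risk


class MultiplicativeRiskScorer(BaseEstimator):
    """Multiplicative OR risk scorer with a scikit-learn estimator surface.

    Parameters
    ----------
    panel : RiskPanel or None, default=None
        Normalized risk panel; ``None`` selects the packaged
        ``italian_wet_amd_v1`` panel at :meth:`fit` time.
    factors : NonGeneticFactors or None, default=None
        ORs for smoking and familiarity.  Required only when the input
        carries non-genetic factor columns.

    Attributes
    ----------
    panel_ : RiskPanel
        The resolved panel after :meth:`fit`.
    rs_ids_ : list of str
        Panel variant identifiers, in panel order.

    Examples
    --------
    >>> scorer = MultiplicativeRiskScorer().fit()
    >>> X = pd.DataFrame([{rs: gt for rs, gt in [
    ...     ("rs1061170", "TC"), ("rs10490924", "GT"), ("rs2227306", "CT"),
    ...     ("rs5749482", "CG"), ("rs8135665", "CT"), ("rs8017304", "AG"),
    ...     ("rs943080", "CT"), ("rs13081855", "GT")]}])
    >>> scorer.predict(X).round(2)
    array([28.63])
    """

    def __init__(self, panel: RiskPanel | None = None,
                 factors: NonGeneticFactors | None = None):
        self.panel = panel
        self.factors = factors

    def fit(self, X=None, y=None) -> "MultiplicativeRiskScorer":
        """Resolve and validate the panel; X and y are ignored.

        The scorer carries no sample-estimated state: "fitting" binds the
        panel (packaged default when ``panel=None``) so the estimator obeys
        the fit-then-predict protocol and composes with sklearn tooling.
        """
        self.panel_ = self.panel if self.panel is not None else default_panel()
        self.rs_ids_ = list(self.panel_.rs_ids)
        return self

    def _check_fitted(self):
        if not hasattr(self, "panel_"):
            raise ProfileError("scorer is not fitted; call fit() first")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Genetic (or overall) risk for each row of *X*.

        *X* must have one column per panel rsID holding genotype strings
        (allele order free).  If columns ``smoking`` and ``familiarity``
        are both present, the overall risk is returned instead and
        ``factors`` must be set; if only one is present that is an error,
        mirroring the both-levels-required constraint.
        """
        self._check_fitted()
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        has_smoking = "smoking" in X.columns
        has_familiarity = "familiarity" in X.columns
        if has_smoking != has_familiarity:
            raise UnsetFactorError("familiarity" if has_smoking else "smoking")
        out = np.empty(len(X), dtype=float)
        for i, (_, row) in enumerate(X.iterrows()):
            profile = self._row_profile(row, with_factors=has_smoking)
            g = genetic_risk(profile, self.panel_)
            if has_smoking:
                if self.factors is None:
                    raise ProfileError(
                        "factor columns present but no NonGeneticFactors configured"
                    )
                g = overall_risk(g, profile.smoking, profile.familiarity, self.factors)
            out[i] = g
        return out

    def _row_profile(self, row: pd.Series, with_factors: bool) -> SubjectProfile:
        genotypes = {rs: str(row[rs]) for rs in self.rs_ids_ if rs in row.index
                     and not pd.isna(row[rs])}
        profile = SubjectProfile(genotypes=genotypes)
        if with_factors:
            profile.smoking = None if pd.isna(row["smoking"]) else str(row["smoking"])
            profile.familiarity = (
                None if pd.isna(row["familiarity"]) else str(row["familiarity"])
            )
            if profile.smoking is None:
                raise UnsetFactorError("smoking")
            if profile.familiarity is None:
                raise UnsetFactorError("familiarity")
            if profile.smoking not in SMOKING_LEVELS:
                raise ProfileError(f"smoking level must be one of {SMOKING_LEVELS}")
            if profile.familiarity not in FAMILIARITY_LEVELS:
                raise ProfileError(f"familiarity level must be one of {FAMILIARITY_LEVELS}")
        return profile

    def score_profile(self, profile: SubjectProfile) -> RiskValues:
        """Genetic and overall risk for one :class:`SubjectProfile`.

        The overall risk requires both non-genetic levels set and
        ``factors`` configured; the genetic risk is always computed first
        (the overall value is a multiple of it by construction).
        """
        self._check_fitted()
        g = genetic_risk(profile, self.panel_)
        if self.factors is None:
            raise ProfileError("no NonGeneticFactors configured on this scorer")
        o = overall_risk(g, profile.smoking, profile.familiarity, self.factors)
        return RiskValues(genetic_risk=g, overall_risk=o)
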