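"""Exception hierarchy.

Every error the library raises on bad user input derives from
:class:`WareError`, so callers (and the CLI) can catch one type and turn it
into a single-line diagnostic.
"""


class WareError(Exception):
    """Base class for all wareamd input/validation errors."""


class PanelValidationError(WareError):
    """A risk-panel file or object violates the panel schema."""


class FrequencyError(WareError):
    """A genotype-frequency table is missing variants or has invalid values."""


class ProfileError(WareError):
    """A subject genotype profile is malformed or inconsistent with the panel."""


class MissingGenotypeError(ProfileError):
    """A risk estimate was requested with one or more panel genotypes unset."""

    def __init__(self, rs_ids):
        self.rs_ids = sorted(rs_ids)
        super().__init__(
            "cannot compute a risk estimate: missing genotype(s) for "
            + ", ".join(self.rs_ids)
        )


class UnsetFactorError(WareError):
    """Overall risk was requested with a non-genetic factor level unset."""

    def __init__(self, factor):
        self.factor = factor
        super().__init__(
            f"non-genetic factor '{factor}' is unset; set its lowest level "
            "('no' for smoking, 'absent' for familiarity) if unknown"
        )
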