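"""Subject genotype profile readers (CSV key-value and VCF).

Both readers produce the same :class:`~wareamd.scoring.SubjectProfile` for
equivalent inputs.  VCF matching is by the ID column (rsID) only, with the
record's REF/ALT checked against the panel alleles: a mismatch (including a
swapped or strand-flipped site) is rejected rather than silently resolved.
"""

from __future__ import annotations

from pathlib import Path

from cyvcf2 import VCF

from .errors import MissingGenotypeError, ProfileError
from .panel import RiskPanel
from .scoring import FAMILIARITY_LEVELS, SMOKING_LEVELS, SubjectProfile

__all__ = ["read_profile_csv", "read_profile_vcf"]

_FACTOR_KEYS = ("smoking", "familiarity")


def read_profile_csv(path: str | Path, panel: RiskPanel | None = None) -> SubjectProfile:
    """Read a profile CSV of ``rs_id,genotype`` rows.

    Optional rows: ``smoking,<yes|no>``, ``familiarity,<present|absent>``
    and ``subject_id,<label>``.  Heterozygote allele order is normalized.
    When *panel* is given, genotypes are validated against it and unknown
    rsIDs rejected; completeness is enforced at scoring time.
    """
    path = Path(path)
    genotypes: dict[str, str] = {}
    smoking = familiarity = None
    subject_id = path.stem
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower() == "rs_id,genotype":
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise ProfileError(f"{path}:{lineno}: expected 'key,value', got {raw!r}")
        key, value = parts
        if key == "smoking":
            if smoking is not None:
                raise ProfileError(f"{path}: duplicate smoking row")
            if value not in SMOKING_LEVELS:
                raise ProfileError(f"{path}: smoking must be one of {SMOKING_LEVELS}")
            smoking = value
        elif key == "familiarity":
            if familiarity is not None:
                raise ProfileError(f"{path}: duplicate familiarity row")
            if value not in FAMILIARITY_LEVELS:
                raise ProfileError(
                    f"{path}: familiarity must be one of {FAMILIARITY_LEVELS}"
                )
            familiarity = value
        elif key == "subject_id":
            subject_id = value
        elif key.startswith("rs"):
            if key in genotypes:
                raise ProfileError(f"{path}: duplicate genotype row for {key}")
            genotypes[key] = value.upper()
        else:
            raise ProfileError(f"{path}:{lineno}: unrecognized key {key!r}")
    if panel is not None:
        known = set(panel.rs_ids)
        unknown = sorted(set(genotypes) - known)
        if unknown:
            raise ProfileError(
                f"{path}: rsID(s) not in panel: " + ", ".join(unknown)
            )
        genotypes = {
            rs: panel.variant(rs).canonical_genotype(g) for rs, g in genotypes.items()
        }
    else:
        genotypes = {rs: "".join(sorted(g)) for rs, g in genotypes.items()}
    return SubjectProfile(genotypes=genotypes, smoking=smoking,
                          familiarity=familiarity, subject_id=subject_id)


def read_profile_vcf(path: str | Path, panel: RiskPanel,
                     sample: str | None = None) -> SubjectProfile:
    """Extract the panel genotypes of one sample from a VCF.

    Records are matched to panel variants by the ID column.  Every panel
    variant must be present, biallelic, allele-consistent with the panel
    and called (no ./.) — anything else is an error, mirroring the
    all-genotypes-required constraint of scoring.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ProfileError(f"{path}: VCF has no sample columns")
    if sample is None:
        if len(samples) > 1:
            raise ProfileError(
                f"{path}: multi-sample VCF; choose one of {samples} via sample="
            )
        sample = samples[0]
    if sample not in samples:
        raise ProfileError(f"{path}: sample {sample!r} not in VCF (has {samples})")
    sidx = samples.index(sample)

    wanted = {v.rs_id: v for v in panel.variants}
    genotypes: dict[str, str] = {}
    for rec in vcf:
        rid = rec.ID
        if rid not in wanted:
            continue
        v = wanted[rid]
        if len(rec.ALT) != 1:
            raise ProfileError(f"{path}: {rid} is not biallelic (ALT={rec.ALT})")
        if rec.REF != v.ref or rec.ALT[0] != v.alt:
            raise ProfileError(
                f"{path}: {rid} REF/ALT {rec.REF}/{rec.ALT[0]} does not match panel "
                f"{v.ref}/{v.alt}; strand flips and allele swaps are not auto-resolved"
            )
        a, b = rec.genotypes[sidx][0], rec.genotypes[sidx][1]
        if a < 0 or b < 0:
            raise ProfileError(f"{path}: uncalled genotype for {rid} in sample {sample}")
        alleles = sorted((v.ref, v.alt)[i] for i in (a, b))
        genotypes[rid] = "".join(alleles)
    missing = [rs for rs in panel.rs_ids if rs not in genotypes]
    if missing:
        raise MissingGenotypeError(missing)
    return SubjectProfile(genotypes=genotypes, subject_id=sample)
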