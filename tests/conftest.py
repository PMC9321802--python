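import json

import pytest

from wareamd import (
    GenotypeFrequencyTable,
    GenotypeOR,
    NonGeneticFactors,
    RiskPanel,
    SubjectProfile,
    Variant,
    default_panel,
)

# canonical genotypes of an unremarkable subject: heterozygous everywhere
HET_GENOTYPES = {
    "rs1061170": "CT",
    "rs10490924": "GT",
    "rs2227306": "CT",
    "rs5749482": "CG",
    "rs8135665": "CT",
    "rs8017304": "AG",
    "rs943080": "CT",
    "rs13081855": "GT",
}


@pytest.fixture(scope="session")
def packaged_panel():
    return default_panel()


@pytest.fixture()
def het_profile():
    return SubjectProfile(genotypes=dict(HET_GENOTYPES), smoking="no",
                          familiarity="absent", subject_id="het-subject")


@pytest.fixture(scope="session")
def synthetic_factors():
    # smoking / familiarity ORs are study-specific config; these are synthetic
    return NonGeneticFactors(smoking_or=1.9, familiarity_or=2.2)


def make_panel(entries, provenance="test panel"):
    """Build a RiskPanel from {(rs, gene, ref, alt): (or_rr, or_het, or_aa)}."""
    variants, ors = [], {}
    for (rs, gene, ref, alt), triple in entries.items():
        v = Variant(rs_id=rs, gene=gene, ref=ref, alt=alt)
        variants.append(v)
        ors[rs] = {
            g: GenotypeOR(genotype=g, or_point=o, ci_low=o * 0.9, ci_high=o * 1.1)
            for g, o in zip(v.genotype_classes, triple)
        }
    return RiskPanel(variants, ors, provenance=provenance)


@pytest.fixture()
def two_variant_panel():
    """Two variants with mean-1 ORs under (0.5, 0.5, 0) genotype frequencies."""
    panel = make_panel({
        ("rs1", "G1", "A", "G"): (0.5, 1.5, 2.0),
        ("rs2", "G2", "C", "T"): (0.8, 1.2, 1.5),
    })
    freqs = GenotypeFrequencyTable(
        {"rs1": (0.5, 0.5, 0.0), "rs2": (0.5, 0.5, 0.0)}, source="hand-built"
    )
    return panel, freqs


@pytest.fixture()
def profile_csv(tmp_path):
    def _write(rows, name="subject.csv"):
        path = tmp_path / name
        path.write_text("\n".join(f"{k},{v}" for k, v in rows) + "\n")
        return path

    return _write


@pytest.fixture()
def factors_json(tmp_path, synthetic_factors):
    path = tmp_path / "factors.json"
    path.write_text(json.dumps({
        "smoking_or": synthetic_factors.smoking_or,
        "familiarity_or": synthetic_factors.familiarity_or,
    }))
    return path


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
)

# arbitrary positions; matching is by the ID column only
VCF_SITES = {
    "rs1061170": ("1", 196659237, "T", "C"),
    "rs10490924": ("10", 124214448, "G", "T"),
    "rs2227306": ("4", 73740951, "C", "T"),
    "rs5749482": ("22", 32831939, "C", "G"),
    "rs8135665": ("22", 38105231, "C", "T"),
    "rs8017304": ("14", 68328176, "A", "G"),
    "rs943080": ("6", 43858108, "C", "T"),
    "rs13081855": ("3", 99180668, "G", "T"),
}


@pytest.fixture()
def vcf_writer(tmp_path):
    def _write(genotype_calls, sample="NA001", name="subject.vcf", sites=None):
        sites = sites or VCF_SITES
        lines = [VCF_HEADER.format(sample=sample).rstrip("\n")]
        for rs, gt in genotype_calls.items():
            chrom, pos, ref, alt = sites[rs]
            lines.append(f"{chrom}\t{pos}\t{rs}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}")
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
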