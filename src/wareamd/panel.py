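"""Risk-panel and genotype-frequency data model.

A *risk panel* is an ordered set of biallelic SNPs, each carrying one
odds ratio (with a 95% CI) per diploid genotype class.  The packaged
default, ``italian_wet_amd_v1``, is the eight-variant wet-AMD panel
validated in the Italian population, with odds ratios already normalized
so that the frequency-weighted population-average risk of every variant
equals 1.

Genotype labels are canonicalized to the alphabetized allele pair
("TG" == "GT" -> "GT"), so user input order never matters.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FrequencyError, PanelValidationError

__all__ = [
    "Variant",
    "GenotypeOR",
    "RiskPanel",
    "GenotypeFrequencyTable",
    "NonGeneticFactors",
    "hwe_triple",
    "load_panel",
    "write_panel",
    "load_frequencies",
    "write_frequencies",
    "default_panel",
    "DEFAULT_PANEL_NAME",
]

DEFAULT_PANEL_NAME = "italian_wet_amd_v1"

_RSID_RE = re.compile(r"^rs[0-9]+$")
_PANEL_COLUMNS = ["rs_id", "gene", "ref", "alt", "genotype", "or_point", "ci_low", "ci_high"]


def _canonical_genotype(genotype: str) -> str:
    """Alphabetize an unordered diploid genotype string ('TG' -> 'GT')."""
    g = genotype.strip().upper()
    if len(g) != 2 or not g.isalpha():
        raise PanelValidationError(f"invalid genotype string {genotype!r}")
    return "".join(sorted(g))


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP identified by rsID, with its panel ref/alt alleles."""

    rs_id: str
    gene: str
    ref: str
    alt: str

    def __post_init__(self):
        if not _RSID_RE.match(self.rs_id):
            raise PanelValidationError(f"rs_id {self.rs_id!r} does not match ^rs[0-9]+$")
        for allele in (self.ref, self.alt):
            if len(allele) != 1 or allele not in "ACGT":
                raise PanelValidationError(
                    f"{self.rs_id}: allele {allele!r} is not a single A/C/G/T base"
                )
        if self.ref == self.alt:
            raise PanelValidationError(f"{self.rs_id}: ref and alt alleles are identical")

    @property
    def genotype_classes(self) -> tuple[str, str, str]:
        """(hom-ref, het, hom-alt) canonical genotype labels."""
        return (
            self.ref + self.ref,
            "".join(sorted(self.ref + self.alt)),
            self.alt + self.alt,
        )

    def canonical_genotype(self, genotype: str) -> str:
        """Validate *genotype* against this variant's three classes."""
        g = _canonical_genotype(genotype)
        if g not in self.genotype_classes:
            raise PanelValidationError(
                f"{self.rs_id}: genotype {genotype!r} is not one of "
                f"{self.genotype_classes}"
            )
        return g


@dataclass(frozen=True)
class GenotypeOR:
    """Odds ratio (point value and 95% CI) for one genotype class."""

    genotype: str
    or_point: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.or_point > 0 and self.ci_low > 0 and self.ci_high > 0):
            raise PanelValidationError(
                f"odds ratio for {self.genotype} must be positive"
            )
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise PanelValidationError(
                f"{self.genotype}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket point value {self.or_point}"
            )


class RiskPanel:
    """Ordered set of variants with per-genotype odds ratios.

    Parameters
    ----------
    variants
        Ordered variants.
    ors
        Mapping ``rs_id -> {genotype_class -> GenotypeOR}``; every variant
        must have exactly its three genotype classes.
    provenance
        Free-text source note carried through reports.
    """

    def __init__(self, variants: Iterable[Variant], ors: Mapping[str, Mapping[str, GenotypeOR]],
                 provenance: str = ""):
        self.variants = list(variants)
        self.provenance = provenance
        seen = set()
        for v in self.variants:
            if v.rs_id in seen:
                raise PanelValidationError(f"duplicate rs_id {v.rs_id}")
            seen.add(v.rs_id)
        self.ors: dict[str, dict[str, GenotypeOR]] = {}
        for v in self.variants:
            if v.rs_id not in ors:
                raise PanelValidationError(f"{v.rs_id}: no odds ratios provided")
            entry = {_canonical_genotype(g): o for g, o in ors[v.rs_id].items()}
            if set(entry) != set(v.genotype_classes):
                raise PanelValidationError(
                    f"{v.rs_id}: expected exactly genotype classes "
                    f"{v.genotype_classes}, got {sorted(entry)}"
                )
            self.ors[v.rs_id] = entry

    @property
    def rs_ids(self) -> list[str]:
        return [v.rs_id for v in self.variants]

    def variant(self, rs_id: str) -> Variant:
        for v in self.variants:
            if v.rs_id == rs_id:
                return v
        raise PanelValidationError(f"unknown rs_id {rs_id}")

    def lookup(self, rs_id: str, genotype: str) -> GenotypeOR:
        """The GenotypeOR for *rs_id* at *genotype* (order-insensitive)."""
        v = self.variant(rs_id)
        return self.ors[rs_id][v.canonical_genotype(genotype)]

    def or_triple(self, rs_id: str) -> np.ndarray:
        """(hom-ref, het, hom-alt) odds-ratio point values."""
        v = self.variant(rs_id)
        return np.array([self.ors[rs_id][g].or_point for g in v.genotype_classes])

    def __len__(self) -> int:
        return len(self.variants)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RiskPanel)
            and self.variants == other.variants
            and self.ors == other.ors
            and self.provenance == other.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            for g in v.genotype_classes:
                o = self.ors[v.rs_id][g]
                rows.append((v.rs_id, v.gene, v.ref, v.alt, g, o.or_point, o.ci_low, o.ci_high))
        return pd.DataFrame(rows, columns=_PANEL_COLUMNS)


def hwe_triple(alt_freq: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (p^2, 2pq, q^2) for alt frequency q."""
    if not 0.0 <= alt_freq <= 1.0:
        raise FrequencyError(f"allele frequency {alt_freq} outside [0, 1]")
    p = 1.0 - alt_freq
    q = alt_freq
    return np.array([p * p, 2.0 * p * q, q * q])


class GenotypeFrequencyTable:
    """Per-variant genotype-class probabilities (hom-ref, het, hom-alt).

    The ``source`` label is mandatory provenance (e.g. a database and
    superpopulation, or 'implied:<panel>'): no frequency set is treated as
    canonical by the package itself.
    """

    def __init__(self, freqs: Mapping[str, Iterable[float]], source: str):
        if not source:
            raise FrequencyError("frequency table requires a non-empty source label")
        self.source = source
        self.freqs: dict[str, np.ndarray] = {}
        for rs_id, triple in freqs.items():
            t = np.asarray(list(triple), dtype=float)
            if t.shape != (3,):
                raise FrequencyError(f"{rs_id}: expected 3 genotype probabilities")
            if (t < 0).any() or (t > 1).any():
                raise FrequencyError(f"{rs_id}: frequencies outside [0, 1]")
            s = t.sum()
            if abs(s - 1.0) > 1e-6:
                raise FrequencyError(f"{rs_id}: genotype frequencies sum to {s}, not 1")
            self.freqs[rs_id] = t / s  # exact renormalization within tolerance

    @classmethod
    def from_allele_freqs(cls, alt_freqs: Mapping[str, float], source: str
                          ) -> "GenotypeFrequencyTable":
        """Expand alt-allele frequencies to genotype triples under HWE."""
        return cls({rs: hwe_triple(q) for rs, q in alt_freqs.items()}, source=source)

    def triple(self, rs_id: str) -> np.ndarray:
        try:
            return self.freqs[rs_id]
        except KeyError:
            raise FrequencyError(f"no frequencies for {rs_id}") from None

    def require_panel(self, panel: RiskPanel) -> None:
        missing = [rs for rs in panel.rs_ids if rs not in self.freqs]
        if missing:
            raise FrequencyError(
                "frequency table does not cover panel variant(s): " + ", ".join(missing)
            )


@dataclass(frozen=True)
class NonGeneticFactors:
    """Odds ratios for the two binary non-genetic factors.

    ``smoking_or`` applies at level "yes", ``familiarity_or`` at level
    "present"; the lowest levels ("no" / "absent") always carry OR = 1, so
    they leave the genetic risk unchanged.  No defaults are shipped: the
    values are study-specific configuration.
    """

    smoking_or: float
    familiarity_or: float

    def __post_init__(self):
        if not (self.smoking_or > 0 and self.familiarity_or > 0):
            raise PanelValidationError("non-genetic factor ORs must be positive")

    @classmethod
    def load(cls, path: str | Path) -> "NonGeneticFactors":
        """Read a JSON config ``{"smoking_or": ..., "familiarity_or": ...}``."""
        with open(path) as fh:
            doc = json.load(fh)
        try:
            return cls(smoking_or=float(doc["smoking_or"]),
                       familiarity_or=float(doc["familiarity_or"]))
        except KeyError as exc:
            raise PanelValidationError(f"factors config missing key {exc}") from None


# ---------------------------------------------------------------------------
# file formats


def _panel_from_frame(df: pd.DataFrame, provenance: str) -> RiskPanel:
    missing_cols = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"panel file missing column(s): {missing_cols}")
    variants: list[Variant] = []
    ors: dict[str, dict[str, GenotypeOR]] = {}
    for rs_id, grp in df.groupby("rs_id", sort=False):
        head = grp.iloc[0]
        v = Variant(rs_id=str(rs_id), gene=str(head["gene"]),
                    ref=str(head["ref"]), alt=str(head["alt"]))
        variants.append(v)
        entry: dict[str, GenotypeOR] = {}
        for _, row in grp.iterrows():
            g = v.canonical_genotype(str(row["genotype"]))
            if g in entry:
                raise PanelValidationError(f"{rs_id}: duplicate genotype row {g}")
            entry[g] = GenotypeOR(genotype=g, or_point=float(row["or_point"]),
                                  ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]))
        ors[str(rs_id)] = entry
    return RiskPanel(variants, ors, provenance=provenance)


def load_panel(path: str | Path) -> RiskPanel:
    """Read a risk panel from CSV (canonical) or an equivalent JSON document.

    CSV: optional first line ``# provenance=<text>``, then columns
    rs_id,gene,ref,alt,genotype,or_point,ci_low,ci_high (one row per
    genotype class).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        df = pd.DataFrame(doc["rows"], columns=_PANEL_COLUMNS)
        return _panel_from_frame(df, provenance=doc.get("provenance", ""))
    provenance = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance="):
            provenance = first[len("# provenance="):].strip()
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    return _panel_from_frame(df, provenance=provenance)


def write_panel(panel: RiskPanel, path: str | Path) -> None:
    """Write *panel* in canonical CSV form (byte-stable round trip)."""
    lines = [f"# provenance={panel.provenance}", ",".join(_PANEL_COLUMNS)]
    for v in panel.variants:
        for g in v.genotype_classes:
            o = panel.ors[v.rs_id][g]
            lines.append(
                f"{v.rs_id},{v.gene},{v.ref},{v.alt},{g},"
                f"{o.or_point!r},{o.ci_low!r},{o.ci_high!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def load_frequencies(path: str | Path, panel: RiskPanel) -> GenotypeFrequencyTable:
    """Read a frequency CSV and check it covers every panel variant.

    Format: a header comment line ``# source=<label>``, then either
    ``rs_id,alt_freq`` rows (expanded via HWE) or
    ``rs_id,f_refref,f_het,f_altalt`` rows (stored as given, renormalized
    to sum to 1).  The two row styles may not be mixed.
    """
    path = Path(path)
    source = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# source="):
            source = first[len("# source="):].strip()
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    if not source:
        raise FrequencyError(f"{path}: missing mandatory '# source=<label>' header line")
    if "alt_freq" in df.columns:
        freqs = {str(r.rs_id): hwe_triple(float(r.alt_freq)) for r in df.itertuples()}
    elif {"f_refref", "f_het", "f_altalt"} <= set(df.columns):
        freqs = {str(r.rs_id): (float(r.f_refref), float(r.f_het), float(r.f_altalt))
                 for r in df.itertuples()}
    else:
        raise FrequencyError(
            f"{path}: expected column 'alt_freq' or columns f_refref,f_het,f_altalt"
        )
    table = GenotypeFrequencyTable(freqs, source=source)
    table.require_panel(panel)
    return table


def write_frequencies(table: GenotypeFrequencyTable, path: str | Path) -> None:
    """Write a genotype-triple frequency CSV with its source header."""
    lines = [f"# source={table.source}", "rs_id,f_refref,f_het,f_altalt"]
    for rs_id, t in table.freqs.items():
        lines.append(f"{rs_id},{float(t[0])!r},{float(t[1])!r},{float(t[2])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_panel() -> RiskPanel:
    """The packaged ``italian_wet_amd_v1`` eight-variant wet-AMD panel."""
    ref = resources.files("wareamd.data") / f"{DEFAULT_PANEL_NAME}.csv"
    with resources.as_file(ref) as path:
        return load_panel(path)
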