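"""Domain types for the HBOC germline-variant analysis pipeline.

The types mirror what a hereditary-cancer panel analysis actually touches:
clinical records of the enrolled patient (:class:`CohortCase`), annotated
germline variant observations (:class:`GermlineVariant`), paired
tumor/germline measurements (:class:`TumorObservation`) and the result
containers for pathogenicity classification, exact-test statistics and
wildtype-allele-loss verdicts.

Conventions
-----------
* Genomic coordinates are 1-based inclusive.
* HGVS strings are stored verbatim from the input and never re-normalized.
* A population allele frequency that is *missing* means "the variant is
  absent from that database"; it is represented by the key being absent
  from ``pop_af`` / ``pop_ac``, never by ``0.0``.  The distinction matters:
  the PM2 evidence code fires on absence, while an observed count of zero
  would be an explicit (and different) statement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "VARIANT_CLASSES",
    "TRUNCATING_CLASSES",
    "CohortCase",
    "RelativeRecord",
    "RelativeCancer",
    "TumorRecord",
    "GermlineVariant",
    "FilterThresholds",
    "PopulationDBRecord",
    "ClassificationResult",
    "TumorObservation",
    "WildtypeLossCall",
    "ContingencyTable",
    "FisherResult",
]

#: recognized functional classes of a germline variant
VARIANT_CLASSES = frozenset(
    {
        "frameshift_indel",
        "stopgain",
        "splice_site",
        "missense",
        "inframe_indel",
        "synonymous",
        "cnv_deletion",
        "other",
    }
)

#: classes treated as "null" / truncating for PVS1 and second-hit logic
TRUNCATING_CLASSES = frozenset(
    {"frameshift_indel", "stopgain", "splice_site", "cnv_deletion"}
)

_SITES = {"breast", "ovary", "synchronous"}
_BRCA_STATUS = {"wildtype", "positive", "vus", "untested"}


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass
class RelativeCancer:
    """One cancer diagnosis in a relative."""

    site: str  # e.g. "breast", "ovary", "colon" ...
    age_at_dx: Optional[int] = None
    bilateral: bool = False
    multiple_primary: bool = False


@dataclass
class RelativeRecord:
    """A first- or second-degree relative with their cancer history."""

    degree: int
    cancers: list[RelativeCancer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise ValidationError(f"relative degree must be 1 or 2, got {self.degree}")


@dataclass
class TumorRecord:
    """One primary breast tumor of a patient.

    ``tumor_id`` follows the T1/T2/T3 convention ordered by age at surgery.
    ``independent_primary`` is a computed field (see
    :func:`hboc.eligibility.classify_independent_primary`).
    """

    tumor_id: str
    age_at_surgery: Optional[int] = None
    laterality_side: str = "unknown"  # left / right / unknown
    histology: Optional[str] = None
    hormonal_subtype: Optional[str] = None
    nuclear_grade: Optional[int] = None
    margin_negative: Optional[bool] = None
    independent_primary: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.laterality_side not in ("left", "right", "unknown"):
            raise ValidationError(f"bad laterality side {self.laterality_side!r}")

    @property
    def has_data(self) -> bool:
        """False for placeholder rows that carry no tumor information."""
        return any(
            v is not None
            for v in (self.age_at_surgery, self.histology, self.hormonal_subtype, self.nuclear_grade)
        )


@dataclass
class CohortCase:
    """Clinical record of one enrolled index patient."""

    case_id: str
    sex: str = "female"
    primary_site: str = "breast"
    age_at_primary_dx: Optional[int] = None
    brca_test_status: str = "wildtype"
    tumors: list[TumorRecord] = field(default_factory=list)
    relatives: list[RelativeRecord] = field(default_factory=list)
    additional_cancers: list[str] = field(default_factory=list)
    history_level: Optional[int] = None  # derived; see eligibility module

    def __post_init__(self) -> None:
        if self.primary_site not in _SITES:
            raise ValidationError(f"bad primary site {self.primary_site!r}")
        if self.brca_test_status not in _BRCA_STATUS:
            raise ValidationError(f"bad BRCA test status {self.brca_test_status!r}")
        if self.age_at_primary_dx is not None and self.age_at_primary_dx <= 0:
            raise ValidationError("age_at_primary_dx must be positive")


@dataclass
class GermlineVariant:
    """One annotated germline variant observation in one case.

    ``pop_af`` maps database name -> allele frequency in [0, 1]; ``pop_ac``
    maps database name -> ``(alt_count, total_alleles)``.  Databases the
    variant is absent from simply do not appear in either map.
    """

    case_id: str
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    variant_class: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    exon_span: Optional[str] = None  # CNVs only, e.g. "5-7"
    depth: Optional[int] = None
    alt_reads: Optional[int] = None
    called_by: frozenset[str] = frozenset()
    pop_af: dict[str, float] = field(default_factory=dict)
    pop_ac: dict[str, tuple[int, int]] = field(default_factory=dict)
    clinvar_assertion: str = "absent"
    hgmd_present: bool = False
    in_functional_domain: Optional[bool] = None
    in_repeat_region: Optional[bool] = None
    insilico_deleterious_fraction: Optional[float] = None
    functional_assay: str = "none"  # damaging / benign_effect / none
    prevalence_evidence: bool = False  # PS4 input flag
    same_aa_change_pathogenic: bool = False  # PS1
    novel_missense_at_pathogenic_residue: bool = False  # PM5
    splice_distance_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant_class is not None and self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant class {self.variant_class!r}")
        if self.depth is not None and self.depth < 0:
            raise ValidationError(f"negative depth for {self.case_id}/{self.gene}")
        if self.alt_reads is not None:
            if self.alt_reads < 0:
                raise ValidationError(f"negative alt_reads for {self.case_id}/{self.gene}")
            if self.depth is not None and self.alt_reads > self.depth:
                raise ValidationError(
                    f"alt_reads > depth ({self.alt_reads} > {self.depth}) "
                    f"for {self.case_id}/{self.gene}"
                )
        for db, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValidationError(f"allele frequency out of range for {db}: {af}")
        for db, (ac, an) in self.pop_ac.items():
            if ac < 0 or an <= 0 or ac > an:
                raise ValidationError(f"bad allele counts for {db}: {ac}/{an}")
        if self.clinvar_assertion not in {
            "pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign", "absent",
        }:
            raise ValidationError(f"bad ClinVar assertion {self.clinvar_assertion!r}")

    @property
    def vaf(self) -> Optional[float]:
        """Variant allele fraction (alt reads / depth); None when unknown."""
        if self.depth in (None, 0) or self.alt_reads is None:
            return None
        return self.alt_reads / self.depth

    def max_af(self, databases: Optional[list[str]] = None) -> float:
        """Maximum allele frequency over ``databases`` (absent -> 0.0).

        Frequencies are taken from ``pop_af`` and derived from ``pop_ac``
        where only counts are known.
        """
        afs = [0.0]
        keys = databases if databases is not None else sorted(set(self.pop_af) | set(self.pop_ac))
        for db in keys:
            if db in self.pop_af:
                afs.append(self.pop_af[db])
            elif db in self.pop_ac:
                ac, an = self.pop_ac[db]
                afs.append(ac / an)
        return max(afs)

    def absent_from(self, databases: list[str]) -> bool:
        """True iff the variant is registered in none of ``databases``."""
        return all(db not in self.pop_af and db not in self.pop_ac for db in databases)

    def identity(self) -> tuple:
        """Identity key for set operations: genomic for SNVs/indels,
        (gene, exon span) for CNVs."""
        if self.variant_class == "cnv_deletion" or self.exon_span is not None:
            return ("cnv", self.gene, self.exon_span)
        if self.chrom is not None and self.pos is not None:
            return (self.chrom, self.pos, self.ref, self.alt)
        return (self.gene, self.hgvs_c)


@dataclass
class FilterThresholds:
    """Significance-filter thresholds for germline variants."""

    min_depth: int = 20
    min_vaf: float = 0.2
    max_maf: float = 0.01
    splice_window_bp: int = 2
    maf_databases: tuple[str, ...] = ("exac_global", "esp6500", "1000g")

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.splice_window_bp <= 0:
            raise ValidationError("thresholds must be positive")
        if not (0.0 < self.min_vaf < 1.0 and 0.0 < self.max_maf < 1.0):
            raise ValidationError("min_vaf and max_maf must lie in (0, 1)")


@dataclass
class PopulationDBRecord:
    """Per-gene allele counts from one population database panel."""

    db_name: str
    ethnicity_label: str = ""
    sex_label: str = "combined"  # combined / female / male
    n_subjects: Optional[int] = None
    alt_counts: dict[str, int] = field(default_factory=dict)  # gene -> alt alleles
    total_alleles: dict[str, int] = field(default_factory=dict)  # gene -> max high-quality AN

    def __post_init__(self) -> None:
        if self.sex_label not in ("combined", "female", "male"):
            raise ValidationError(f"bad sex label {self.sex_label!r}")
        for gene, ac in self.alt_counts.items():
            an = self.total_alleles.get(gene)
            if an is None:
                raise ValidationError(f"missing total alleles for {gene} in {self.db_name}")
            if not 0 <= ac <= an:
                raise ValidationError(f"alt_count > total_alleles for {gene} in {self.db_name}")


@dataclass
class ClassificationResult:
    """Fired evidence codes with the 5-tier and collapsed 3-tier calls."""

    variant: GermlineVariant
    fired_codes: frozenset[str] = frozenset()
    tier5: str = "VUS"  # P / LP / VUS / LB / B
    tier3: str = "VUS"  # pathogenic / VUS / benign
    raw_tier5: Optional[str] = None  # pre-review call when review changed it
    manual_review: bool = False
    review_reasons: tuple[str, ...] = ()
    audit: tuple[str, ...] = ()  # codes skipped for missing annotations


@dataclass
class TumorObservation:
    """Paired tumor/germline measurements for one (tumor, gene)."""

    case_id: str
    tumor_id: str
    gene: str
    germline_vaf: Optional[float] = None
    tumor_vaf: Optional[float] = None
    exon_counts_tumor: Optional[list[float]] = None
    exon_counts_germline: Optional[list[float]] = None
    affected_exons: Optional[list[int]] = None  # indices of the germline-deleted span
    somatic_calls: dict[str, list] = field(default_factory=dict)  # caller -> variants
    assay_available: bool = True

    def __post_init__(self) -> None:
        for name, v in (("germline_vaf", self.germline_vaf), ("tumor_vaf", self.tumor_vaf)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} out of [0,1]: {v}")
        for counts in (self.exon_counts_tumor, self.exon_counts_germline):
            if counts is not None and any(c < 0 for c in counts):
                raise ValidationError("negative exon read count")


@dataclass
class WildtypeLossCall:
    """Verdict on loss of the wildtype allele for one (tumor, gene)."""

    case_id: str
    tumor_id: str
    gene: str
    verdict: str  # LOH / AST / ND / NA
    mechanism_detail: str = ""
    supporting_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in ("LOH", "AST", "ND", "NA"):
            raise ValidationError(f"bad verdict {self.verdict!r}")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = case/control, columns = mutant/other alleles."""

    a: int  # case, mutant
    b: int  # case, other
    c: int  # control, mutant
    d: int  # control, other

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, (int,)) or v < 0:
                raise ValidationError("contingency cells must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        """Swap the mutant/other columns (maps OR to 1/OR)."""
        return ContingencyTable(self.b, self.a, self.d, self.c)


@dataclass
class FisherResult:
    """Exact Fisher test output: conditional-MLE OR, p and exact CI."""

    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    method_note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValidationError(f"p-value out of range: {self.p_value}")
        self.p_value = min(self.p_value, 1.0)
        if (
            not math.isnan(self.odds_ratio)
            and math.isfinite(self.odds_ratio)
            and math.isfinite(self.ci_low)
            and math.isfinite(self.ci_high)
        ):
            if not (self.ci_low <= self.odds_ratio + 1e-9 and self.odds_ratio <= self.ci_high + 1e-9):
                raise ValidationError("CI does not bracket the odds ratio")
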