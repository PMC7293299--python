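"""Restricted ACMG-AMP pathogenicity rule engine.

Of the 27 standard evidence codes, nine that require de-novo status,
phasing, segregation data or syndrome-specific phenotype matching (PS2,
PM3, PM6, PP1, PP4, BS2, BS4, BP2, BP5) are disabled: the cohort is
family-history ascertained, the disease is not monogenic, common variants
are already frequency-filtered, and identical variants must classify
identically across analyses.  The remaining 18 codes produce a raw 5-tier
call (P / LP / VUS / LB / B) through the standard combining rules; raw
calls that are truncating, pathogenic-side, or discordant with ClinVar
are flagged for manual review.  A deterministic review-resolution step
reproduces the documented review outcome for truncations: a raw-VUS null
variant in a loss-of-function-mechanism gene that is rare in every
population database and carries no benign evidence is upgraded to LP.

The 5-tier call collapses to a 3-tier system (pathogenic / VUS / benign)
for downstream burden and second-hit analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .data_model import ClassificationResult, GermlineVariant, TRUNCATING_CLASSES
from .filtering import classify_variant_type

__all__ = [
    "EngineConfig",
    "ALL_CODES",
    "ENABLED_CODES",
    "PANEL_GENES",
    "assign_evidence_codes",
    "combine_codes",
    "collapse_to_3tier",
    "flag_manual_review",
    "resolve_manual_review",
    "classify_variant",
    "classify_variants",
]

#: the 27 recognized ACMG-AMP evidence codes
ALL_CODES = frozenset(
    {
        "PVS1",
        "PS1", "PS2", "PS3", "PS4",
        "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
        "PP1", "PP2", "PP3", "PP4", "PP5",
        "BA1",
        "BS1", "BS2", "BS3", "BS4",
        "BP1", "BP2", "BP3", "BP4", "BP5", "BP6",
    }
)

#: the 18 codes enabled by default (see module docstring for the exclusions)
ENABLED_CODES = frozenset(
    {
        "PVS1", "PS1", "PS3", "PS4",
        "PM1", "PM2", "PM4", "PM5",
        "PP2", "PP3", "PP5",
        "BA1", "BS1", "BS3",
        "BP1", "BP3", "BP4", "BP6",
    }
)

#: default 28-gene hereditary breast/ovarian cancer susceptibility panel
#: (the 12 genes mutated in the packaged cohort, the four syndromic
#: high-penetrance genes, and twelve conventional panel members);
#: config-overridable, and treated as loss-of-function-mechanism genes.
PANEL_GENES = frozenset(
    {
        "ATM", "BARD1", "BLM", "BRIP1", "CHEK2", "FANCM", "NF1", "PALB2",
        "RAD50", "RAD51C", "RAD51D", "RECQL",
        "TP53", "PTEN", "STK11", "CDH1",
        "MLH1", "MSH2", "MSH6", "PMS2", "EPCAM",
        "MRE11A", "NBN", "RAD51B", "XRCC2", "FANCC", "MUTYH", "PIK3CA",
    }
)

#: population panel used for the absence rule (PM2) and the frequency
#: codes by default: the east-Asian control construction
DEFAULT_PM2_DATABASES = ("HGVD", "TMM", "ExAC_EastAsian")


@dataclass
class EngineConfig:
    """Tunables of the rule engine (all exposed, defaults per the study design)."""

    enabled_codes: frozenset[str] = ENABLED_CODES
    lof_mechanism_genes: frozenset[str] = PANEL_GENES
    missense_constrained_genes: frozenset[str] = frozenset()  # PP2
    truncating_mechanism_genes: frozenset[str] = frozenset()  # BP1
    ba1_threshold: float = 0.05
    bs1_threshold: float = 0.01
    pm2_databases: tuple[str, ...] = DEFAULT_PM2_DATABASES
    pp3_threshold: float = 0.8  # fraction of in-silico predictors calling deleterious
    bp4_threshold: float = 0.2
    review_upgrade: bool = True  # apply the deterministic review resolution
    review_maf_ceiling: float = 0.01

    def __post_init__(self) -> None:
        unknown = self.enabled_codes - ALL_CODES
        if unknown:
            raise ValueError(f"unrecognized evidence codes: {sorted(unknown)}")


def assign_evidence_codes(
    variant: GermlineVariant, config: EngineConfig | None = None
) -> tuple[frozenset[str], tuple[str, ...]]:
    """Fire evidence codes for one variant.

    Returns ``(codes, audit)`` where ``audit`` lists codes that were *not*
    evaluated because the required annotation was missing.
    """
    config = config or EngineConfig()
    codes: set[str] = set()
    audit: list[str] = []
    vclass = classify_variant_type(variant)
    is_null = vclass in TRUNCATING_CLASSES
    max_af_any = variant.max_af()

    # --- pathogenic side -------------------------------------------------
    if is_null and variant.gene in config.lof_mechanism_genes:
        codes.add("PVS1")
    if variant.same_aa_change_pathogenic:
        codes.add("PS1")
    if variant.functional_assay == "damaging":
        codes.add("PS3")
    if variant.prevalence_evidence:
        codes.add("PS4")
    if variant.in_functional_domain:
        codes.add("PM1")
    elif variant.in_functional_domain is None:
        audit.append("PM1")
    if variant.absent_from(list(config.pm2_databases)):
        codes.add("PM2")
    if variant.variant_class == "inframe_indel":
        codes.add("PM4")
    if variant.novel_missense_at_pathogenic_residue:
        codes.add("PM5")
    if variant.variant_class == "missense" and variant.gene in config.missense_constrained_genes:
        codes.add("PP2")
    if variant.insilico_deleterious_fraction is None:
        audit.extend(["PP3", "BP4"])
    else:
        if variant.insilico_deleterious_fraction >= config.pp3_threshold:
            codes.add("PP3")
        if variant.insilico_deleterious_fraction <= config.bp4_threshold:
            codes.add("BP4")
    if variant.clinvar_assertion in ("pathogenic", "likely_pathogenic") or variant.hgmd_present:
        codes.add("PP5")

    # --- benign side ------------------------------------------------------
    if max_af_any >= config.ba1_threshold:
        codes.add("BA1")
    if max_af_any >= config.bs1_threshold:
        codes.add("BS1")
    if variant.functional_assay == "benign_effect":
        codes.add("BS3")
    if variant.variant_class == "missense" and variant.gene in config.truncating_mechanism_genes:
        codes.add("BP1")
    if variant.variant_class == "inframe_indel":
        if variant.in_repeat_region:
            codes.add("BP3")
        elif variant.in_repeat_region is None:
            audit.append("BP3")
    if variant.clinvar_assertion in ("benign", "likely_benign"):
        codes.add("BP6")

    return frozenset(codes & config.enabled_codes), tuple(audit)


def _counts(codes: Iterable[str]) -> dict[str, int]:
    n = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for c in codes:
        for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
            if c.startswith(prefix):
                n[prefix] += 1
                break
    return n


def combine_codes(codes: Iterable[str]) -> str:
    """Combine fired evidence codes into the 5-tier call.

    Follows the standard combining rules; a set satisfying both a
    pathogenic-side and a benign-side rule is a conflict and returns VUS.
    """
    codes = set(codes)
    unknown = codes - ALL_CODES
    if unknown:
        raise ValueError(f"unrecognized evidence codes: {sorted(unknown)}")
    n = _counts(codes)
    pvs, ps, pm, pp = n["PVS"], n["PS"], n["PM"], n["PP"]
    bs, bp = n["BS"], n["BP"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and 1 <= pm <= 2)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = "BA1" in codes or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return "VUS"
    if pathogenic:
        return "P"
    if likely_pathogenic:
        return "LP"
    if benign:
        return "B"
    if likely_benign:
        return "LB"
    return "VUS"


def collapse_to_3tier(tier5: str) -> str:
    """Collapse the 5-tier call: P/LP -> pathogenic, B/LB -> benign."""
    mapping = {"P": "pathogenic", "LP": "pathogenic", "VUS": "VUS", "LB": "benign", "B": "benign"}
    try:
        return mapping[tier5]
    except KeyError:
        raise ValueError(f"unknown 5-tier value {tier5!r}") from None


_ASSERTION_TIER3 = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "pathogenic",
    "vus": "VUS",
    "likely_benign": "benign",
    "benign": "benign",
}


def flag_manual_review(
    raw_tier5: str, variant: GermlineVariant
) -> tuple[bool, tuple[str, ...]]:
    """Flag a raw call for manual inspection.

    Reasons: the raw 3-tier call disagrees with the ClinVar assertion
    (``discordant_with_clinvar``), the raw call is LP or P
    (``tier_LP_or_P``), or the variant is truncating (``truncating``).
    """
    reasons = []
    if variant.clinvar_assertion != "absent":
        if collapse_to_3tier(raw_tier5) != _ASSERTION_TIER3[variant.clinvar_assertion]:
            reasons.append("discordant_with_clinvar")
    if raw_tier5 in ("P", "LP"):
        reasons.append("tier_LP_or_P")
    if classify_variant_type(variant) in TRUNCATING_CLASSES:
        reasons.append("truncating")
    return bool(reasons), tuple(reasons)


def resolve_manual_review(
    raw_tier5: str,
    codes: frozenset[str],
    variant: GermlineVariant,
    config: EngineConfig,
) -> str:
    """Deterministic post-review tier.

    Emulates the documented outcome of the manual inspection of truncating
    raw calls: a raw-VUS null variant in a loss-of-function-mechanism gene
    that is rare (below the review MAF ceiling) in every database and fired
    no benign code is upgraded to LP.  Everything else is returned as-is.
    """
    if not config.review_upgrade or raw_tier5 != "VUS":
        return raw_tier5
    benign_codes = {c for c in codes if c.startswith(("BA", "BS", "BP"))}
    if (
        "PVS1" in codes
        and not benign_codes
        and variant.max_af() < config.review_maf_ceiling
    ):
        return "LP"
    return raw_tier5


def classify_variant(
    variant: GermlineVariant, config: EngineConfig | None = None
) -> ClassificationResult:
    """Full per-variant classification: codes, raw and reviewed tiers."""
    config = config or EngineConfig()
    codes, audit = assign_evidence_codes(variant, config)
    raw = combine_codes(codes)
    review, reasons = flag_manual_review(raw, variant)
    final = resolve_manual_review(raw, codes, variant, config)
    return ClassificationResult(
        variant=variant,
        fired_codes=codes,
        tier5=final,
        tier3=collapse_to_3tier(final),
        raw_tier5=raw if raw != final else None,
        manual_review=review,
        review_reasons=reasons,
        audit=audit,
    )


def classify_variants(
    variants: Iterable[GermlineVariant], config: EngineConfig | None = None
) -> list[ClassificationResult]:
    config = config or EngineConfig()
    return [classify_variant(v, config) for v in variants]
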