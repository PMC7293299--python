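"""Rule-based cohort eligibility: family-history levels, breast-cancer
laterality categories and independent-primary determination.

Enrollment stratifies probands by the strength of their family history of
breast/ovarian cancer.  *History level 1* is the stronger criterion:
either two or more affected first-degree relatives, or a single affected
first-degree relative whose cancer was early-onset (before age 40),
bilateral primary breast cancer, or part of a multiple-primary cancer.
*Level 2* requires at least one affected first- or second-degree relative.
The age/bilaterality/multiple-primary qualifiers attach to the relative's
cancer (the grammatical subject of the criterion); both synchronous and
asynchronous bilateral disease qualify, with no time-window parameter.
"""

from __future__ import annotations

from typing import Optional

from .data_model import CohortCase, TumorRecord

__all__ = [
    "classify_history_level",
    "classify_independent_primary",
    "categorize_laterality",
    "IndeterminateMargin",
]

_BREAST_OVARY = {"breast", "ovary"}


class IneligibleCaseError(ValueError):
    """Proband lacks a qualifying breast/ovarian cancer diagnosis."""


class IndeterminateMargin(Exception):
    """Margin status of the first tumor is unknown; the independent-primary
    call cannot be made and must not silently default to False."""


def _affected_bo(relative) -> list:
    return [c for c in relative.cancers if c.site in _BREAST_OVARY]


def classify_history_level(case: CohortCase) -> Optional[int]:
    """Classify a proband's family-history level (1, 2 or None).

    Level 1 takes precedence over level 2.  Returns None when no first-
    or second-degree relative had breast or ovarian cancer.
    """
    if case.primary_site not in ("breast", "ovary", "synchronous"):
        raise IneligibleCaseError(
            f"case {case.case_id} has no qualifying breast/ovarian diagnosis"
        )

    first_degree_affected = [r for r in case.relatives if r.degree == 1 and _affected_bo(r)]
    any_degree_affected = [r for r in case.relatives if r.degree in (1, 2) and _affected_bo(r)]

    if len(first_degree_affected) >= 2:
        return 1
    for rel in first_degree_affected:
        for cancer in _affected_bo(rel):
            early = cancer.age_at_dx is not None and cancer.age_at_dx < 40
            bilateral_breast = cancer.bilateral and cancer.site == "breast"
            if early or bilateral_breast or cancer.multiple_primary:
                return 1
    if any_degree_affected:
        return 2
    return None


def classify_independent_primary(first: TumorRecord, second: TumorRecord) -> bool:
    """Decide whether ``second`` is an independent primary rather than a
    local recurrence of ``first``.

    True iff the first tumor's surgical margin was free of cancer cells
    AND the second tumor differs in at least one of: position of
    occurrence (side), histology, hormonal status, or HER2 expression.
    Unknown margin status raises :class:`IndeterminateMargin` rather than
    silently returning False.
    """
    if first.margin_negative is None:
        raise IndeterminateMargin(
            f"margin status unknown for tumor {first.tumor_id}; cannot call independent primary"
        )
    if not first.margin_negative:
        return False

    def her2(subtype: Optional[str]) -> Optional[bool]:
        if subtype is None or "Unk" in subtype:
            return None
        return "HER2" in subtype and "Unk" not in subtype

    def hormonal(subtype: Optional[str]) -> Optional[str]:
        if subtype is None:
            return None
        if "Luminal" in subtype:
            return "luminal"
        if subtype == "Triple Negative":
            return "negative"
        return subtype

    differs = False
    if "unknown" not in (first.laterality_side, second.laterality_side):
        differs |= first.laterality_side != second.laterality_side
    if first.histology is not None and second.histology is not None:
        differs |= first.histology != second.histology
    h1, h2 = hormonal(first.hormonal_subtype), hormonal(second.hormonal_subtype)
    if h1 is not None and h2 is not None:
        differs |= h1 != h2
    e1, e2 = her2(first.hormonal_subtype), her2(second.hormonal_subtype)
    if e1 is not None and e2 is not None:
        differs |= e1 != e2
    return differs


def categorize_laterality(tumors: list[TumorRecord]) -> str:
    """Categorize a patient's independent primary breast tumors.

    Returns one of ``Unilateral (n=1)``, ``Unilateral (n>=2)``,
    ``Bilateral (n>=2)`` or ``Not applicable`` (no breast tumors).
    Placeholder rows without any tumor data are ignored.
    """
    informative = [t for t in tumors if t.has_data]
    if not informative:
        return "Not applicable"
    if len(informative) == 1:
        return "Unilateral (n=1)"
    sides = {t.laterality_side for t in informative if t.laterality_side != "unknown"}
    if len(sides) >= 2:
        return "Bilateral (n>=2)"
    return "Unilateral (n>=2)"
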