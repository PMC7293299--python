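"""Germline significance filter cascade and caller-consensus rules.

Germline calls are considered genuine only when emitted by every
configured caller (dual-caller intersection); somatic calls when emitted
by at least two of the three configured callers.  Surviving germline
variants pass a four-rule significance cascade:

1. coding SNV / inframe indel / frameshift indel, or a splice-site variant
   within +-2 bp of an exon-intron boundary;
2. read depth >= 20;
3. variant read frequency (alt reads / depth) >= 0.2;
4. maximum minor allele frequency over the configured population
   databases < 0.01 (absence from a database counts as frequency 0).

Each rejected variant carries the first failing rule in this order, so the
audit output is reproducible.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Mapping, Optional

from .data_model import FilterThresholds, GermlineVariant

__all__ = [
    "intersect_germline_callsets",
    "consensus_somatic_calls",
    "filter_germline_variants",
    "classify_variant_type",
    "splice_offset",
]

_CODING_CLASSES = {"stopgain", "missense", "inframe_indel", "frameshift_indel", "synonymous"}

_SPLICE_RE = re.compile(r"c\.\*?\d+([+-]\d+)")


def splice_offset(hgvs_c: str) -> Optional[int]:
    """Intronic offset from the nearest exon boundary parsed from an HGVS
    c. string (e.g. ``c.4776+2T>A`` -> 2); None for exonic/unparseable."""
    s = hgvs_c.replace("–", "-").replace(" ", "")
    m = _SPLICE_RE.search(s)
    if not m:
        return None
    return abs(int(m.group(1)))


def classify_variant_type(variant: GermlineVariant, splice_window_bp: int = 2) -> str:
    """Deterministic functional-class call from HGVS/annotation fields.

    Returns one of ``frameshift_indel``, ``stopgain``, ``splice_site``,
    ``cnv_deletion`` or ``other``.
    """
    if variant.variant_class in ("frameshift_indel", "stopgain", "splice_site", "cnv_deletion"):
        return variant.variant_class
    if variant.exon_span is not None or "Deletion" in (variant.hgvs_c or ""):
        return "cnv_deletion"
    p = (variant.hgvs_p or "").strip()
    if p.endswith("fs"):
        return "frameshift_indel"
    if p.endswith("*"):  # terminal stop, including delins* events
        return "stopgain"
    offset = variant.splice_distance_bp
    if offset is None:
        offset = splice_offset(variant.hgvs_c or "")
    if offset is not None and offset <= splice_window_bp:
        return "splice_site"
    if variant.variant_class is not None:
        return "other"
    if not p and not variant.hgvs_c:
        warnings.warn(
            f"unparseable variant description for {variant.case_id}/{variant.gene}",
            stacklevel=2,
        )
    return "other"


def intersect_germline_callsets(
    calls_by_caller: Mapping[str, Iterable[GermlineVariant]],
) -> list[GermlineVariant]:
    """Variants detected by *every* caller (identity = chrom/pos/ref/alt;
    CNVs by gene + exon span)."""
    if len(calls_by_caller) < 2:
        raise ValueError("germline intersection requires at least two caller sets")
    sets = {name: {v.identity(): v for v in calls} for name, calls in calls_by_caller.items()}
    keys = set.intersection(*(set(s) for s in sets.values()))
    first = next(iter(sets.values()))
    return [first[k] for k in sorted(keys, key=repr)]


def consensus_somatic_calls(
    calls_by_caller: Mapping[str, Iterable[GermlineVariant]],
    min_callers: int = 2,
) -> list[GermlineVariant]:
    """Somatic variants detected by at least ``min_callers`` callers."""
    if min_callers > len(calls_by_caller):
        raise ValueError(
            f"min_callers={min_callers} exceeds the {len(calls_by_caller)} configured callers"
        )
    by_key: dict[tuple, GermlineVariant] = {}
    votes: dict[tuple, int] = {}
    for calls in calls_by_caller.values():
        for v in calls:
            k = v.identity()
            by_key.setdefault(k, v)
            votes[k] = votes.get(k, 0) + 1
    return [by_key[k] for k in sorted(votes, key=repr) if votes[k] >= min_callers]


def filter_germline_variants(
    variants: Iterable[GermlineVariant],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[GermlineVariant], list[tuple[GermlineVariant, str]]]:
    """Apply the significance cascade; returns (kept, rejected_with_reason).

    The reason attached to each rejected variant names the *first* failing
    rule among ``region``, ``depth``, ``vaf``, ``maf``.
    """
    thresholds = thresholds or FilterThresholds()
    kept: list[GermlineVariant] = []
    rejected: list[tuple[GermlineVariant, str]] = []
    for v in variants:
        reason = _first_failing_rule(v, thresholds)
        if reason is None:
            kept.append(v)
        else:
            rejected.append((v, reason))
    return kept, rejected


def _first_failing_rule(v: GermlineVariant, t: FilterThresholds) -> Optional[str]:
    vclass = v.variant_class or classify_variant_type(v, t.splice_window_bp)
    if vclass in _CODING_CLASSES:
        pass
    elif vclass == "splice_site":
        offset = v.splice_distance_bp
        if offset is None:
            offset = splice_offset(v.hgvs_c or "")
        if offset is None or offset > t.splice_window_bp:
            return "region"
    else:
        return "region"
    if v.depth is None or v.depth < t.min_depth:
        return "depth"
    if v.depth == 0 or v.alt_reads is None or v.alt_reads / v.depth < t.min_vaf:
        return "vaf"
    if v.max_af(list(t.maf_databases)) >= t.max_maf:
        return "maf"
    return None
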