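"""Second-hit analysis: loss of the wildtype allele in tumors.

A germline heterozygous loss-of-function carrier can lose the remaining
wildtype allele somatically by copy-number loss (LOH) or acquire a second,
somatic truncating variant in the same gene (AST).  Three detectors:

* **SNV-VAF LOH** — for a heterozygous germline variant (germline VAF in
  the closed window [0.2, 0.6]), copy loss of the wildtype allele inflates
  the tumor VAF; LOH is called when the tumor VAF is strictly greater
  than 0.6.  Germline VAFs outside the window are not evaluable.
* **CNV LOH** — for a germline exon-level deletion, additional somatic
  loss shows as a decrease of the per-exon log2(tumor/germline) read-count
  ratio over the deleted span.  Ratios are normalized with a LOWESS trend
  against overall exon abundance (estimated from the exons outside the
  deleted span) and LOH is called when the mean normalized log2 ratio over
  the span is at or below -0.5 with at least 3 informative exons.  The
  -0.5 cutoff detects a single-copy loss at >= 50% tumor purity
  (log2 of (1 - purity) at purity 0.5 is -1).
* **AST** — a consensus-filtered somatic truncating variant in the same
  gene at a position different from the germline variant.

A tumor with both LOH and AST evidence is reported as AST (the specific
second truncation identifies the mechanism) and counted once in summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import GermlineVariant, TumorObservation, WildtypeLossCall, TRUNCATING_CLASSES
from .filtering import classify_variant_type

__all__ = [
    "LohThresholds",
    "call_snv_loh",
    "call_cnv_loh",
    "detect_ast",
    "call_wildtype_loss",
    "summarize_wildtype_loss",
]


@dataclass
class LohThresholds:
    """Cutoffs for the second-hit detectors (all config-exposed)."""

    germline_vaf_low: float = 0.2   # inclusive
    germline_vaf_high: float = 0.6  # inclusive
    tumor_vaf_threshold: float = 0.6  # strict >
    lowess_fraction: float = 0.3
    log2_threshold: float = -0.5
    min_exons: int = 3


def call_snv_loh(
    germline_vaf: float,
    tumor_vaf: float,
    thresholds: LohThresholds | None = None,
) -> str:
    """VAF-window LOH call: ``LOH``, ``ND`` or ``not_evaluable``.

    The germline window [0.2, 0.6] is closed at both ends; the tumor
    threshold is strict (a tumor VAF of exactly 0.6 is ND).
    """
    t = thresholds or LohThresholds()
    for name, v in (("germline", germline_vaf), ("tumor", tumor_vaf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} VAF outside [0, 1]: {v}")
    if not t.germline_vaf_low <= germline_vaf <= t.germline_vaf_high:
        return "not_evaluable"
    return "LOH" if tumor_vaf > t.tumor_vaf_threshold else "ND"


def call_cnv_loh(
    exon_counts_tumor: Sequence[float],
    exon_counts_germline: Sequence[float],
    affected_exons: Sequence[int],
    thresholds: LohThresholds | None = None,
) -> str:
    """Exon log2-ratio LOH call over a germline-deleted span: LOH or ND."""
    t = thresholds or LohThresholds()
    tumor = np.asarray(exon_counts_tumor, dtype=float)
    germ = np.asarray(exon_counts_germline, dtype=float)
    if tumor.shape != germ.shape:
        raise ValueError("tumor and germline exon-count vectors differ in length")
    affected = np.zeros(len(tumor), dtype=bool)
    affected[list(affected_exons)] = True

    informative = (germ > 0) & (tumor > 0)
    dropped = affected & ~informative
    if dropped.any():
        warnings.warn(
            f"dropping {int(dropped.sum())} affected exon(s) with zero counts", stacklevel=2
        )
    if int((affected & informative).sum()) < t.min_exons:
        return "ND"

    m = np.log2(tumor[informative] / germ[informative])
    a = 0.5 * np.log2(tumor[informative] * germ[informative])
    aff_i = affected[informative]

    # trend vs abundance from the exons outside the deleted span
    if (~aff_i).sum() >= 5:
        fit = lowess(m[~aff_i], a[~aff_i], frac=t.lowess_fraction, return_sorted=True)
        trend = np.interp(a, fit[:, 0], fit[:, 1])
    else:
        trend = np.full_like(m, np.median(m[~aff_i]) if (~aff_i).any() else 0.0)
    normalized = m - trend
    mean_affected = float(normalized[aff_i].mean())
    return "LOH" if mean_affected <= t.log2_threshold else "ND"


def _same_site(a: GermlineVariant, b: GermlineVariant) -> bool:
    if a.pos is not None and b.pos is not None:
        return (a.chrom, a.pos) == (b.chrom, b.pos)
    return bool(a.hgvs_c) and a.hgvs_c == b.hgvs_c


def detect_ast(
    germline_variant: GermlineVariant,
    consensus_somatic_calls: Iterable[GermlineVariant],
    gene: Optional[str] = None,
) -> str:
    """AST iff a consensus somatic truncating variant hits the same gene
    at a different site than the germline variant."""
    gene = gene or germline_variant.gene
    for call in consensus_somatic_calls:
        if call.gene != gene:
            continue
        if classify_variant_type(call) not in TRUNCATING_CLASSES:
            continue
        if _same_site(germline_variant, call):
            continue
        return "AST"
    return "ND"


def call_wildtype_loss(
    obs: TumorObservation,
    germline_variant: GermlineVariant,
    thresholds: LohThresholds | None = None,
    consensus_calls: Optional[Iterable[GermlineVariant]] = None,
) -> WildtypeLossCall:
    """Combined verdict for one (tumor, gene) observation.

    Precedence: AST over LOH (dual-evidence tumors count once, as AST);
    an observation without an available assay is NA.
    """
    t = thresholds or LohThresholds()
    if not obs.assay_available:
        return WildtypeLossCall(obs.case_id, obs.tumor_id, obs.gene, "NA", "assay unavailable")

    support: dict = {}
    if consensus_calls is None:
        from .filtering import consensus_somatic_calls as consensus

        consensus_calls = consensus(obs.somatic_calls) if obs.somatic_calls else []
    ast = detect_ast(germline_variant, consensus_calls, obs.gene)
    if ast == "AST":
        return WildtypeLossCall(
            obs.case_id, obs.tumor_id, obs.gene, "AST", "additional somatic truncation"
        )

    if obs.exon_counts_tumor is not None and obs.exon_counts_germline is not None:
        verdict = call_cnv_loh(
            obs.exon_counts_tumor, obs.exon_counts_germline, obs.affected_exons or [], t
        )
        detail = "exon log2-ratio copy loss" if verdict == "LOH" else "no copy-loss signal"
        return WildtypeLossCall(obs.case_id, obs.tumor_id, obs.gene, verdict, detail)

    if obs.germline_vaf is not None and obs.tumor_vaf is not None:
        verdict = call_snv_loh(obs.germline_vaf, obs.tumor_vaf, t)
        support = {"germline_vaf": obs.germline_vaf, "tumor_vaf": obs.tumor_vaf}
        if verdict == "not_evaluable":
            return WildtypeLossCall(
                obs.case_id, obs.tumor_id, obs.gene, "ND",
                "germline VAF outside the evaluable window", support,
            )
        detail = "tumor VAF shift" if verdict == "LOH" else "no VAF shift"
        return WildtypeLossCall(obs.case_id, obs.tumor_id, obs.gene, verdict, detail, support)

    return WildtypeLossCall(obs.case_id, obs.tumor_id, obs.gene, "ND", "no informative assay")


def summarize_wildtype_loss(
    calls: Iterable[WildtypeLossCall],
    allele_counts: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Per-gene summary of second-hit verdicts with a ``Total`` row.

    ``analyzed`` counts evaluable tumors (NA excluded); ``ratio`` is
    (LOH + AST) / analyzed, NaN when nothing was analyzable.
    """
    rows: dict[str, dict[str, int]] = {}
    for call in calls:
        g = rows.setdefault(call.gene, {"LOH": 0, "AST": 0, "ND": 0, "NA": 0})
        g[call.verdict] += 1

    genes = sorted(rows)
    if allele_counts:
        genes = sorted(set(genes) | set(allele_counts), key=lambda g: (-allele_counts.get(g, 0), g))
    records = []
    for gene in genes + ["Total"]:
        if gene == "Total":
            loh = sum(r["LOH"] for r in rows.values())
            ast = sum(r["AST"] for r in rows.values())
            nd = sum(r["ND"] for r in rows.values())
            alleles = sum(allele_counts.values()) if allele_counts else None
        else:
            r = rows.get(gene, {"LOH": 0, "AST": 0, "ND": 0, "NA": 0})
            loh, ast, nd = r["LOH"], r["AST"], r["ND"]
            alleles = allele_counts.get(gene) if allele_counts else None
        analyzed = loh + ast + nd
        ratio = (loh + ast) / analyzed if analyzed else math.nan
        rec = {
            "gene": gene,
            "analyzed": analyzed,
            "LOH": loh,
            "AST": ast,
            "ND": nd,
            "ratio": ratio,
        }
        if allele_counts:
            rec["germline_mutant_alleles"] = alleles
        records.append(rec)
    return pd.DataFrame(records)
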