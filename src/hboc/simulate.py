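"""Seeded synthetic cohorts with known ground truth.

The generators emulate the structure of a family-history-ascertained,
BRCA1/2-wildtype panel-sequencing study so that every pipeline stage is
testable without access to the deposited data: clinical cases with
relatives sampled to produce history levels 1/2, germline carrier variants
planted per gene (pathogenic truncations absent from the population
databases; benign variants at common frequencies), population-database
allele-count records, and paired tumor observations with planted LOH/AST
events.  Truth tables are first-class outputs — downstream recovery tests
never re-derive the ground truth from the generated data.

Default conditions follow the study scale: 568 cases, negative-binomial
read depth with mean 120 (the reported median exome coverage is 123-fold),
heterozygous germline VAF centered on 0.5 with binomial read-sampling
noise, control allele frequencies and relative risks on the order of the
significantly enriched genes, tumor purity 0.7, and LOH/AST fractions of
8/22 and 4/22 of assayed carrier tumors.

All generators are pure functions of their configuration (which carries
the mandatory seed): the same config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    CohortCase,
    GermlineVariant,
    PopulationDBRecord,
    RelativeCancer,
    RelativeRecord,
    TumorObservation,
)

__all__ = ["SimulationConfig", "generate_cohort", "generate_population_db", "generate_tumor_data"]

_DEFAULT_AF = {"PALB2": 4e-4, "BARD1": 2e-4, "BLM": 1e-3, "ATM": 1.5e-3}
_DEFAULT_RR = {"PALB2": 10.7, "BARD1": 10.2, "BLM": 3.6, "ATM": 2.7}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort (defaults emulate the study design)."""

    n_cases: int = 568
    per_gene_control_af: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_AF))
    relative_risk: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RR))
    per_gene_carrier_rate: Optional[dict[str, float]] = None  # default: 2*af*RR
    benign_variants_per_case: float = 2.0  # Poisson mean of common, filterable variants
    depth_mean: float = 120.0
    depth_dispersion: float = 5.0  # negative-binomial size parameter
    germline_panel_depth: float = 366.0  # germline targeted-panel coverage
    tumor_depth_mean: float = 790.0  # tumor panel coverage
    vaf_noise_concentration: float = 200.0  # Beta concentration around the expected VAF
    loh_fraction: float = 8 / 22
    ast_fraction: float = 4 / 22
    tumor_purity: float = 0.7
    cnv_carrier_fraction: float = 0.08  # 3/38 observations are exon-level deletions
    n_exons: int = 30
    affected_exon_span: int = 6
    level1_fraction: float = 0.5
    seed: int = 0

    def carrier_rates(self) -> dict[str, float]:
        if self.per_gene_carrier_rate is not None:
            rates = dict(self.per_gene_carrier_rate)
        else:
            rates = {
                g: 2.0 * self.per_gene_control_af[g] * self.relative_risk.get(g, 1.0)
                for g in self.per_gene_control_af
            }
        for gene, rate in rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"carrier rate out of [0,1] for {gene}: {rate}")
        return rates


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator
    ss = np.random.SeedSequence([config.seed % (2**31), abs(hash(stream)) % (2**31)])
    return np.random.default_rng(ss)


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=size), 1)


def _het_reads(rng: np.random.Generator, depth: int, conc: float) -> int:
    vaf = rng.beta(0.5 * conc, 0.5 * conc)
    return int(rng.binomial(depth, vaf))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[CohortCase], list[GermlineVariant], pd.DataFrame]:
    """Sample cases, their germline variant calls and the truth table.

    Planted pathogenic variants are truncations absent from every
    population database with heterozygous read support (expected VAF 0.5);
    planted benign variants are common (AF in [0.02, 0.2]) missense or
    synonymous changes that the frequency filter should remove.
    """
    rates = config.carrier_rates()
    rng = _rng(config, "cohort")
    cases: list[CohortCase] = []
    variants: list[GermlineVariant] = []
    truth_rows = []
    genes = sorted(rates)
    for i in range(config.n_cases):
        case_id = f"S{i:04d}"
        if rng.random() < config.level1_fraction:
            relatives = [
                RelativeRecord(1, [RelativeCancer("breast", int(rng.integers(35, 70)))]),
                RelativeRecord(1, [RelativeCancer("breast", int(rng.integers(35, 70)))]),
            ]
        else:
            relatives = [RelativeRecord(2, [RelativeCancer("ovary", int(rng.integers(40, 75)))])]
        cases.append(
            CohortCase(
                case_id=case_id,
                primary_site="breast" if rng.random() > 0.05 else "ovary",
                age_at_primary_dx=int(rng.integers(25, 70)),
                relatives=relatives,
            )
        )
        for gene in genes:
            if rng.random() >= rates[gene]:
                continue
            pos = int(rng.integers(1, 3000))
            is_cnv = rng.random() < config.cnv_carrier_fraction
            depth = int(_nb_depth(rng, config.depth_mean, config.depth_dispersion))
            alt = _het_reads(rng, depth, config.vaf_noise_concentration)
            if is_cnv:
                v = GermlineVariant(
                    case_id=case_id, gene=gene, hgvs_c=f"Exon {pos % 9 + 2}-{pos % 9 + 4} Deletion",
                    variant_class="cnv_deletion", exon_span=f"{pos % 9 + 2}-{pos % 9 + 4}",
                )
            else:
                v = GermlineVariant(
                    case_id=case_id, gene=gene,
                    hgvs_c=f"c.{pos * 3}del", hgvs_p=f"p.K{pos}fs",
                    variant_class="frameshift_indel",
                    chrom="17", pos=pos * 3, ref="AG", alt="A",
                    depth=depth, alt_reads=min(alt, depth),
                )
            variants.append(v)
            truth_rows.append(
                {"case_id": case_id, "gene": gene, "pathogenic": True,
                 "variant_class": v.variant_class, "hgvs_c": v.hgvs_c}
            )
        for _ in range(rng.poisson(config.benign_variants_per_case)):
            gene = genes[int(rng.integers(len(genes)))]
            pos = int(rng.integers(3000, 6000))
            af = float(rng.uniform(0.02, 0.2))
            depth = int(_nb_depth(rng, config.depth_mean, config.depth_dispersion))
            variants.append(
                GermlineVariant(
                    case_id=case_id, gene=gene,
                    hgvs_c=f"c.{pos}A>G", hgvs_p=f"p.T{pos // 3}A",
                    variant_class="missense",
                    chrom="17", pos=pos, ref="A", alt="G",
                    depth=depth, alt_reads=_het_reads(rng, depth, config.vaf_noise_concentration),
                    pop_af={db: af for db in ("HGVD", "TMM", "ExAC_EastAsian", "exac_global")},
                )
            )
    truth = pd.DataFrame(truth_rows, columns=["case_id", "gene", "pathogenic", "variant_class", "hgvs_c"])
    return cases, variants, truth


def generate_population_db(config: SimulationConfig) -> list[PopulationDBRecord]:
    """Control allele-count records: an east-Asian trio plus one female
    panel, with per-gene alt counts drawn binomially from the configured
    control allele frequencies."""
    rng = _rng(config, "popdb")
    panels = [
        ("HGVD", "Japanese", "combined", 1208),
        ("TMM", "Japanese", "combined", 3554),
        ("ExAC_EastAsian", "east-Asian", "combined", 3933),
        ("ExAC_Female", "combined", "female", 22937),
    ]
    records = []
    for db, eth, sex, n_subj in panels:
        totals = {g: 2 * n_subj for g in config.per_gene_control_af}
        alts = {
            g: int(rng.binomial(totals[g], af)) for g, af in config.per_gene_control_af.items()
        }
        records.append(
            PopulationDBRecord(
                db_name=db, ethnicity_label=eth, sex_label=sex, n_subjects=n_subj,
                alt_counts=alts, total_alleles=totals,
            )
        )
    return records


def _somatic_truncation(gene: str, pos: int) -> GermlineVariant:
    return GermlineVariant(
        case_id="tumor", gene=gene, hgvs_c=f"c.{pos}del", hgvs_p=f"p.E{pos // 3}fs",
        variant_class="frameshift_indel", chrom="17", pos=pos, ref="CT", alt="C",
    )


def generate_tumor_data(
    config: SimulationConfig, carrier_variants: list[GermlineVariant]
) -> tuple[list[TumorObservation], pd.DataFrame]:
    """Paired tumor observations for carrier tumors, with planted events.

    Each carrier tumor receives LOH (with probability ``loh_fraction``),
    AST (``ast_fraction``) or no event.  SNV carriers get germline/tumor
    VAF pairs (LOH shifts the tumor VAF to 1/(2-purity)); CNV carriers get
    per-exon Poisson read counts with the deleted span at half germline
    coverage and, under LOH, a further (1-purity)-fold tumor decrease.
    AST plants a second somatic truncation observed by at least two of the
    three simulated callers; caller-private artifacts are added so the
    consensus rule has something to reject.
    """
    rng = _rng(config, "tumor")
    p = config.tumor_purity
    obs_list: list[TumorObservation] = []
    truth_rows = []
    for v in carrier_variants:
        r = rng.random()
        event = "LOH" if r < config.loh_fraction else (
            "AST" if r < config.loh_fraction + config.ast_fraction else "none"
        )
        somatic_calls: dict[str, list] = {"varscan": [], "mutect": [], "karkinos": []}
        # caller-private artifact: must NOT survive the 2-of-3 consensus
        lone = _somatic_truncation(v.gene, int(rng.integers(6000, 9000)))
        somatic_calls[list(somatic_calls)[int(rng.integers(3))]].append(lone)
        if event == "AST":
            ast_pos = int(rng.integers(9000, 12000))
            second = _somatic_truncation(v.gene, ast_pos)
            callers = list(somatic_calls)
            n_detect = 2 + int(rng.random() < 0.6)
            for name in rng.choice(callers, size=n_detect, replace=False):
                somatic_calls[name].append(second)

        if v.variant_class == "cnv_deletion":
            n_exons = config.n_exons
            start = int(rng.integers(0, n_exons - config.affected_exon_span))
            affected = list(range(start, start + config.affected_exon_span))
            # germline panel and tumor panel run at different depths; the
            # LOWESS trend absorbs the resulting constant log-ratio offset
            g_mean = np.full(n_exons, config.germline_panel_depth)
            g_mean[affected] /= 2.0
            t_mean = np.full(n_exons, config.tumor_depth_mean)
            t_mean[affected] /= 2.0
            if event == "LOH":
                t_mean[affected] *= 1.0 - p
            obs = TumorObservation(
                case_id=v.case_id, tumor_id="T1", gene=v.gene,
                exon_counts_tumor=list(rng.poisson(t_mean).astype(float)),
                exon_counts_germline=list(rng.poisson(g_mean).astype(float)),
                affected_exons=affected,
                somatic_calls=somatic_calls,
            )
        else:
            g_depth = int(_nb_depth(rng, config.depth_mean, config.depth_dispersion))
            t_depth = int(_nb_depth(rng, config.tumor_depth_mean, config.depth_dispersion))
            g_vaf = _het_reads(rng, g_depth, config.vaf_noise_concentration) / g_depth
            expected_t = 1.0 / (2.0 - p) if event == "LOH" else 0.5
            t_vaf = rng.binomial(t_depth, expected_t) / t_depth
            obs = TumorObservation(
                case_id=v.case_id, tumor_id="T1", gene=v.gene,
                germline_vaf=float(np.clip(g_vaf, 0.0, 1.0)),
                tumor_vaf=float(np.clip(t_vaf, 0.0, 1.0)),
                somatic_calls=somatic_calls,
            )
        obs_list.append(obs)
        truth_rows.append(
            {"case_id": v.case_id, "tumor_id": "T1", "gene": v.gene, "event": event}
        )
    truth = pd.DataFrame(truth_rows, columns=["case_id", "tumor_id", "gene", "event"])
    return obs_list, truth


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a new seed (convenience for replicates)."""
    return replace(config, seed=seed)
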