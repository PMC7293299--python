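"""Stage-chaining pipeline with a run manifest, plus the packaged-cohort
summary used for reproducing the study counts.

``run_pipeline`` executes the stages named in a JSON config (any stage may
be omitted) and writes a report bundle plus a manifest recording package
versions, the config hash and the seeds, so a re-run of the same config is
identical except for timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__ as _pkg_version
from .acmg import EngineConfig, classify_variants
from .data_model import FilterThresholds, PopulationDBRecord, WildtypeLossCall
from .enrichment import aggregate_gene_allele_counts, build_case_control_tables, fisher_exact_2x2
from .filtering import classify_variant_type, filter_germline_variants
from .io import load_fixture, carrier_fixture_variants, read_variant_table, write_report, write_table
from .simulate import SimulationConfig, generate_cohort, generate_population_db, generate_tumor_data
from .tumor_loss import call_snv_loh, summarize_wildtype_loss

__all__ = ["analyze_fixtures", "run_pipeline", "read_controls", "PipelineInputError"]

log = logging.getLogger("hboc")


class PipelineInputError(FileNotFoundError):
    """A stage is enabled but its input is missing; names the stage."""


# ---------------------------------------------------------------------------
# packaged-cohort summary
# ---------------------------------------------------------------------------

def analyze_fixtures(engine_config: Optional[EngineConfig] = None) -> dict:
    """Recompute the study's headline counts from the packaged fixtures.

    Runs the variant-type classifier, the rule engine, the gene-level
    aggregation and the second-hit summary on the transcribed tables and
    returns the counts in one dict (the structure mirrors the published
    results narrative: cohort composition, carrier prevalence, variant-type
    breakdown, recurrence, per-gene allele counts, second-hit totals).
    """
    comp = load_fixture("cohort_composition")
    variants = carrier_fixture_variants()
    carriers_df = load_fixture("carriers_table1")
    patients = load_fixture("patients_table3")
    tumors = load_fixture("tumors_table4")

    n_wt = comp["n_wildtype_cases"]
    carrier_cases = sorted({v.case_id for v in variants})

    types = [classify_variant_type(v) for v in variants]
    breakdown = {t: types.count(t) for t in sorted(set(types))}

    # recurrence: same gene + nucleotide change in two or more cases
    key = carriers_df.assign(k=carriers_df["gene"] + ":" + carriers_df["hgvs_c"])
    rec = key.groupby("k")["case_id"].nunique()
    recurrent = rec[rec >= 2]
    recurrent_cnv = sum("Deletion" in k for k in recurrent.index)
    recurrent_snv_indel = len(recurrent) - recurrent_cnv

    results = classify_variants(variants, engine_config or EngineConfig())
    tier_counts = {t: sum(r.tier5 == t for r in results) for t in ("P", "LP", "VUS", "LB", "B")}
    allele_counts = aggregate_gene_allele_counts(results, include_cnv=False)

    site = patients.drop_duplicates("case_id").set_index("case_id")["primary_site"]
    calls = [
        WildtypeLossCall(r.case_id, r.tumor_id, r.gene, r.wildtype_loss)
        for r in tumors.itertuples()
    ]
    gene_alleles = carriers_df.groupby("gene")["case_id"].count().to_dict()
    second_hit = summarize_wildtype_loss(calls, allele_counts=gene_alleles)
    total_row = second_hit[second_hit["gene"] == "Total"].iloc[0]

    return {
        "cohort": dict(comp),
        "n_carriers": len(carrier_cases),
        "carrier_prevalence_pct": round(100.0 * len(carrier_cases) / n_wt, 1),
        "n_variant_observations": len(variants),
        "n_mutated_genes": carriers_df["gene"].nunique(),
        "variant_type_breakdown": breakdown,
        "recurrent_snv_indel": int(recurrent_snv_indel),
        "recurrent_cnv": int(recurrent_cnv),
        "tier_counts": tier_counts,
        "gene_allele_counts": dict(sorted(allele_counts.items())),
        "carrier_site_split": {
            "breast": int((site == "Breast").sum()),
            "ovary": int((site == "Ovary").sum()),
        },
        "group2_brca2_rate_pct": round(
            100.0 * comp["group2_brca2_positive"] / comp["group2_untested"], 1
        ),
        "second_hit_summary": second_hit,
        "second_hit_totals": {
            "analyzed": int(total_row["analyzed"]),
            "LOH": int(total_row["LOH"]),
            "AST": int(total_row["AST"]),
            "ND": int(total_row["ND"]),
            "ratio_pct": round(100.0 * total_row["ratio"], 1),
        },
    }


# ---------------------------------------------------------------------------
# file-driven stages
# ---------------------------------------------------------------------------

def read_controls(path) -> list[PopulationDBRecord]:
    """Read a long-format control allele-count TSV
    (``db_name sex_label n_subjects gene alt_count total_alleles``)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for (db, sex), grp in df.groupby(["db_name", "sex_label"]):
        records.append(
            PopulationDBRecord(
                db_name=str(db),
                sex_label=str(sex),
                n_subjects=int(grp["n_subjects"].iloc[0]),
                alt_counts=dict(zip(grp["gene"], grp["alt_count"].astype(int))),
                total_alleles=dict(zip(grp["gene"], grp["total_alleles"].astype(int))),
            )
        )
    return records


def classification_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": r.variant.case_id,
            "gene": r.variant.gene,
            "hgvs_c": r.variant.hgvs_c,
            "hgvs_p": r.variant.hgvs_p,
            "variant_class": classify_variant_type(r.variant),
            "fired_codes": ",".join(sorted(r.fired_codes)),
            "tier5": r.tier5,
            "tier3": r.tier3,
            "raw_tier5": r.raw_tier5 or r.tier5,
            "manual_review": r.manual_review,
            "review_reasons": ",".join(r.review_reasons),
        }
        for r in results
    )


def enrichment_table(tables: dict) -> pd.DataFrame:
    rows = []
    for gene, tab in sorted(tables.items()):
        res = fisher_exact_2x2(tab)
        rows.append(
            {
                "gene": gene,
                "mutant_alleles": tab.a,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config_path, out_dir: Optional[str] = None) -> dict:
    """Execute the stages named in a JSON config; returns the report dict.

    Fails fast with :class:`PipelineInputError` naming the stage whose
    input is missing.  Deterministic given inputs and seeds.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise PipelineInputError(f"pipeline config not found: {config_path}")
    raw = config_path.read_text()
    cfg = json.loads(raw)
    out = Path(out_dir or cfg.get("out_dir", config_path.parent / "hboc_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", {})
    seed = int(cfg.get("seed", 0))
    report: dict = {}
    timers: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)

            def __exit__(self, *exc):
                timers[name] = round(time.perf_counter() - self.t0, 3)
                log.info("stage %s finished in %.2fs", name, timers[name])

        return _T()

    kept = None

    if stages.get("fixtures"):
        with timed("fixtures"):
            fx = analyze_fixtures()
            second_hit = fx.pop("second_hit_summary")
            report["cohort_summary"] = fx
            report["second_hit_summary"] = second_hit

    if "simulate" in stages:
        with timed("simulate"):
            params = dict(stages["simulate"])
            params.setdefault("seed", seed)
            sim = SimulationConfig(**params)
            cases, variants, truth = generate_cohort(sim)
            controls = generate_population_db(sim)
            from .io import write_variant_table

            write_variant_table(variants, out / "simulated_variants.tsv")
            write_table(truth, out / "simulated_truth.tsv")
            ctrl_rows = [
                {
                    "db_name": r.db_name, "sex_label": r.sex_label, "n_subjects": r.n_subjects,
                    "gene": g, "alt_count": r.alt_counts[g], "total_alleles": r.total_alleles[g],
                }
                for r in controls
                for g in sorted(r.alt_counts)
            ]
            write_table(pd.DataFrame(ctrl_rows), out / "simulated_controls.tsv")
            report["simulate"] = {
                "n_cases": sim.n_cases, "n_variants": len(variants),
                "n_planted_pathogenic": int(len(truth)),
            }

    if "filter" in stages:
        spec = stages["filter"]
        path = spec.get("variants")
        if not path or not Path(path).exists():
            raise PipelineInputError(f"stage 'filter': variant table not found: {path}")
        with timed("filter"):
            variants = read_variant_table(path, spec.get("format", "tsv"))
            thresholds = FilterThresholds(**spec.get("thresholds", {}))
            kept, rejected = filter_germline_variants(variants, thresholds)
            from .io import write_variant_table

            write_variant_table(kept, out / "filtered_variants.tsv")
            rej = pd.DataFrame(
                {"case_id": v.case_id, "gene": v.gene, "hgvs_c": v.hgvs_c, "reject_reason": r}
                for v, r in rejected
            )
            write_table(rej if not rej.empty else pd.DataFrame(columns=["case_id", "gene", "hgvs_c", "reject_reason"]),
                        out / "rejected_variants.tsv")
            report["filter"] = {"n_input": len(variants), "n_kept": len(kept), "n_rejected": len(rejected)}

    results = None
    if "classify" in stages:
        spec = stages["classify"]
        with timed("classify"):
            if kept is None:
                path = spec.get("variants")
                if not path or not Path(path).exists():
                    raise PipelineInputError(f"stage 'classify': variant table not found: {path}")
                kept = read_variant_table(path, spec.get("format", "tsv"))
            engine = EngineConfig(**spec.get("engine", {})) if spec.get("engine") else EngineConfig()
            results = classify_variants(kept, engine)
            table = classification_table(results)
            write_table(table, out / "classification.tsv")
            report["classification"] = table

    if "enrich" in stages:
        spec = stages["enrich"]
        controls_path = spec.get("controls")
        if not controls_path or not Path(controls_path).exists():
            raise PipelineInputError(f"stage 'enrich': controls table not found: {controls_path}")
        if results is None:
            raise PipelineInputError("stage 'enrich': no classification results (enable 'classify')")
        with timed("enrich"):
            controls = read_controls(controls_path)
            counts = aggregate_gene_allele_counts(results, include_cnv=spec.get("include_cnv", False))
            for g in spec.get("report_genes", []):
                counts.setdefault(g, 0)
            tables = build_case_control_tables(counts, int(spec["n_cases"]), controls)
            table = enrichment_table(tables)
            write_table(table, out / "enrichment.tsv")
            report["enrichment"] = table

    if "second_hit" in stages:
        spec = stages["second_hit"]
        path = spec.get("observations")
        if not path or not Path(path).exists():
            raise PipelineInputError(f"stage 'second_hit': observations table not found: {path}")
        with timed("second_hit"):
            obs = pd.read_csv(path, sep="\t", na_values=["."])
            calls = []
            for r in obs.itertuples():
                if pd.isna(r.germline_vaf) or pd.isna(r.tumor_vaf):
                    verdict = "NA"
                else:
                    v = call_snv_loh(float(r.germline_vaf), float(r.tumor_vaf))
                    verdict = "ND" if v == "not_evaluable" else v
                calls.append(WildtypeLossCall(str(r.case_id), str(r.tumor_id), str(r.gene), verdict))
            summary = summarize_wildtype_loss(calls)
            write_table(summary, out / "second_hit_summary.tsv")
            report["second_hit_summary"] = summary

    manifest = {
        "package_version": _pkg_version,
        "python": sys.version.split()[0],
        "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
        "seed": seed,
        "stage_seconds": timers,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    write_report(report, out / "report.json", format="json")
    return report
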