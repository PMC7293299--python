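"""Readers, writers and packaged-fixture loaders.

Variant tables travel either as VCF 4.x (annotations in INFO keys, read
support in the per-sample DP/AD fields) or as a documented TSV dialect:
UTF-8, tab-separated, ``.`` for missing values.  Recognized TSV columns:

``case_id gene hgvs_c hgvs_p variant_class chrom pos ref alt exon_span
depth alt_reads called_by clinvar hgmd in_functional_domain
in_repeat_region insilico_deleterious_fraction functional_assay``

plus any number of ``af_<db>`` (allele frequency) and ``ac_<db>``
(``alt/total`` allele counts) columns.  A missing ``af_``/``ac_`` entry
means the variant is absent from that database — it is *not* zero-filled.

The packaged fixtures transcribe the published study tables verbatim:
``carriers_table1`` (38 pathogenic/likely-pathogenic variant observations
in 37 carriers), ``patients_table3`` (carrier clinical records),
``tumors_table4`` (48 breast tumors in 35 carriers, with the wildtype-
allele-loss verdicts) and ``cohort_composition`` (enrollment group sizes
and BRCA1/2 test outcomes).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .data_model import GermlineVariant, ValidationError

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "load_fixture",
    "carrier_fixture_variants",
    "write_table",
    "read_table",
    "write_report",
    "read_report",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = (
    "carriers_table1",
    "patients_table3",
    "tumors_table4",
    "cohort_composition",
)

#: east-Asian population-database panel printed in the carrier fixture
EAST_ASIAN_DBS = ("HGVD", "TMM", "ExAC_EastAsian")
ALL_FIXTURE_DBS = EAST_ASIAN_DBS + ("ExAC_Other",)

_SCALAR_COLS = {
    "case_id": str,
    "gene": str,
    "hgvs_c": str,
    "hgvs_p": str,
    "variant_class": str,
    "chrom": str,
    "ref": str,
    "alt": str,
    "exon_span": str,
    "functional_assay": str,
    "clinvar": str,
}


class ParseError(ValueError):
    """Raised for malformed input records; names the offending line."""


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value in (".", "")


def _row_to_variant(row: dict, line_no: int) -> GermlineVariant:
    def get(col, cast=None):
        v = row.get(col)
        if _missing(v):
            return None
        return cast(v) if cast else v

    pop_af: dict[str, float] = {}
    pop_ac: dict[str, tuple[int, int]] = {}
    for col, v in row.items():
        if _missing(v):
            continue
        if col.startswith("af_"):
            pop_af[col[3:]] = float(v)
        elif col.startswith("ac_"):
            try:
                ac, an = str(v).split("/")
                pop_ac[col[3:]] = (int(ac), int(an))
            except Exception as exc:  # noqa: BLE001
                raise ParseError(f"line {line_no}: bad allele-count field {col}={v!r}") from exc

    called_by = get("called_by")
    clinvar = get("clinvar") or "absent"
    clinvar = {
        "present": "pathogenic",  # registration columns record presence of a P/LP assertion
        "nr": "absent",
    }.get(str(clinvar).lower(), str(clinvar).lower())

    try:
        return GermlineVariant(
            case_id=str(row["case_id"]),
            gene=str(row["gene"]),
            hgvs_c=get("hgvs_c") or "",
            hgvs_p=get("hgvs_p") or "",
            variant_class=get("variant_class"),
            chrom=get("chrom", str),
            pos=get("pos", lambda v: int(float(v))),
            ref=get("ref", str),
            alt=get("alt", str),
            exon_span=get("exon_span", str),
            depth=get("depth", lambda v: int(float(v))),
            alt_reads=get("alt_reads", lambda v: int(float(v))),
            called_by=frozenset(str(called_by).split(",")) if called_by else frozenset(),
            pop_af=pop_af,
            pop_ac=pop_ac,
            clinvar_assertion=clinvar,
            hgmd_present=str(get("hgmd") or "").lower() in ("1", "true", "present"),
            in_functional_domain=_opt_bool(get("in_functional_domain")),
            in_repeat_region=_opt_bool(get("in_repeat_region")),
            insilico_deleterious_fraction=get("insilico_deleterious_fraction", float),
            functional_assay=get("functional_assay") or "none",
        )
    except ValidationError as exc:
        raise ValidationError(f"line {line_no}: {exc}") from exc
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"line {line_no}: malformed record ({exc})") from exc


def _opt_bool(v):
    if v is None:
        return None
    return str(v).lower() in ("1", "true", "yes")


def read_variant_table(path: Union[str, Path], format: str = "tsv") -> list[GermlineVariant]:
    """Read germline variants from a TSV or single-sample VCF file.

    Missing annotations are left absent, never zero-filled.  Malformed
    records raise :class:`ParseError` naming the line; invariant
    violations (e.g. ``alt_reads > depth``) raise ``ValidationError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=["."])
        if df.empty:
            return []
        return [
            _row_to_variant(row._asdict() if hasattr(row, "_asdict") else dict(row), i + 2)
            for i, (_, row) in enumerate(df.iterrows())
        ]
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown variant-table format {format!r}")


def _read_vcf(path: Path) -> list[GermlineVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[GermlineVariant] = []
    for i, rec in enumerate(vcf):
        info = dict(rec.INFO)
        pop_af = {k[3:]: float(v) for k, v in info.items() if k.startswith("AF_")}
        pop_ac = {}
        for k, v in info.items():
            if k.startswith("AC_"):
                ac, an = (int(x) for x in str(v).split(","))
                pop_ac[k[3:]] = (ac, an)
        depth = alt_reads = None
        case_id = samples[0] if samples else str(info.get("CASE", "unknown"))
        if samples:
            try:
                depth = int(rec.format("DP")[0][0])
                ad = rec.format("AD")[0]
                alt_reads = int(ad[1])
            except (TypeError, IndexError):
                pass
        try:
            out.append(
                GermlineVariant(
                    case_id=case_id,
                    gene=str(info.get("GENE", "")),
                    hgvs_c=str(info.get("HGVSC", "")),
                    hgvs_p=str(info.get("HGVSP", "")),
                    variant_class=info.get("VCLASS"),
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0] if rec.ALT else None,
                    exon_span=info.get("EXON_SPAN"),
                    depth=depth,
                    alt_reads=alt_reads,
                    pop_af=pop_af,
                    pop_ac=pop_ac,
                    clinvar_assertion=str(info.get("CLNSIG", "absent")).lower(),
                    hgmd_present="HGMD" in info,
                    in_functional_domain=("DOMAIN" in info) or None,
                    in_repeat_region=("REPEAT" in info) or None,
                    insilico_deleterious_fraction=(
                        float(info["INSILICO"]) if "INSILICO" in info else None
                    ),
                    functional_assay=str(info.get("ASSAY", "none")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"VCF record {i + 1} ({rec.CHROM}:{rec.POS}): {exc}") from exc
    return out


def write_variant_table(variants: Iterable[GermlineVariant], path: Union[str, Path]) -> None:
    """Write variants in the documented TSV dialect (inverse of the reader)."""
    rows = []
    for v in variants:
        row = {
            "case_id": v.case_id,
            "gene": v.gene,
            "hgvs_c": v.hgvs_c or None,
            "hgvs_p": v.hgvs_p or None,
            "variant_class": v.variant_class,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "exon_span": v.exon_span,
            "depth": v.depth,
            "alt_reads": v.alt_reads,
            "called_by": ",".join(sorted(v.called_by)) or None,
            "clinvar": None if v.clinvar_assertion == "absent" else v.clinvar_assertion,
            "hgmd": "1" if v.hgmd_present else None,
            "in_functional_domain": None if v.in_functional_domain is None else int(v.in_functional_domain),
            "in_repeat_region": None if v.in_repeat_region is None else int(v.in_repeat_region),
            "insilico_deleterious_fraction": v.insilico_deleterious_fraction,
            "functional_assay": None if v.functional_assay == "none" else v.functional_assay,
        }
        for db, af in v.pop_af.items():
            row[f"af_{db}"] = af
        for db, (ac, an) in v.pop_ac.items():
            row[f"ac_{db}"] = f"{ac}/{an}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``carriers_table1``, ``patients_table3`` and ``tumors_table4`` return
    DataFrames; ``cohort_composition`` returns a dict of enrollment counts.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    pkg = resources.files("hboc") / "fixtures"
    if name == "cohort_composition":
        return json.loads((pkg / "cohort_composition.json").read_text())
    with resources.as_file(pkg / f"{name}.tsv") as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False, na_values=["."])
    for col in ("age_at_primary_dx", "age_at_surgery", "history_level", "nuclear_grade"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def carrier_fixture_variants() -> list[GermlineVariant]:
    """The carrier fixture as annotated :class:`GermlineVariant` records.

    Database registration columns map onto annotations: a ``Present``
    ClinVar/HGMD entry becomes a pathogenic assertion flag, allele-count
    fractions become ``pop_ac`` entries, and ``NR``/``NA`` leave the
    database absent from the maps.
    """
    df = load_fixture("carriers_table1")
    col_to_db = {
        "hgvd": "HGVD",
        "tmm": "TMM",
        "exac_east_asian": "ExAC_EastAsian",
        "exac_other": "ExAC_Other",
    }
    variants = []
    for _, row in df.iterrows():
        pop_ac: dict[str, tuple[int, int]] = {}
        for col, db in col_to_db.items():
            raw = row[col]
            if isinstance(raw, str) and "/" in raw:
                ac, an = raw.split("/")
                pop_ac[db] = (int(ac), int(an))
        hgvs_c = row["hgvs_c"]
        exon_span = None
        if "Deletion" in hgvs_c:
            exon_span = hgvs_c.replace("Exon", "").replace("Deletion", "").strip()
            hgvs_c = row["hgvs_c"]
        variants.append(
            GermlineVariant(
                case_id=row["case_id"],
                gene=row["gene"],
                hgvs_c=hgvs_c,
                hgvs_p="" if pd.isna(row["hgvs_p"]) else row["hgvs_p"],
                exon_span=exon_span,
                pop_ac=pop_ac,
                clinvar_assertion="pathogenic" if row["clinvar"] == "Present" else "absent",
                hgmd_present=row["hgmd"] == "Present",
            )
        )
    return variants


# ---------------------------------------------------------------------------
# generic typed-table and report round trips
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a typed table as TSV ('.' for missing)."""
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, restoring dtypes
    with pandas' nullable conversions."""
    df = pd.read_csv(Path(path), sep="\t", keep_default_na=False, na_values=["."])
    return df.convert_dtypes()


def write_report(results: dict, path: Union[str, Path], format: str = "json") -> None:
    """Serialize a report bundle (mapping of section name -> table/dict).

    JSON reports keep every section in a single document; TSV reports
    write one ``<section>.tsv`` per table into the directory ``path``.
    """
    path = Path(path)
    if format == "json":
        doc = {}
        for key, value in results.items():
            if isinstance(value, pd.DataFrame):
                doc[key] = {
                    "type": "table",
                    "rows": json.loads(value.to_json(orient="records")),
                }
            else:
                doc[key] = {"type": "object", "value": value}
        path.write_text(json.dumps(doc, indent=2, default=str))
    elif format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        for key, value in results.items():
            if isinstance(value, pd.DataFrame):
                write_table(value, path / f"{key}.tsv")
            else:
                (path / f"{key}.json").write_text(json.dumps(value, indent=2, default=str))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: Union[str, Path]) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    doc = json.loads(Path(path).read_text())
    out = {}
    for key, block in doc.items():
        if block["type"] == "table":
            out[key] = pd.DataFrame(block["rows"])
        else:
            out[key] = block["value"]
    return out
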