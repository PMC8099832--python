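"""Tabular and VCF input/output.

All interchange is TSV with header rows; genotype dosages can also be
written/read as minimal VCF 4.2 (GT and DS fields).  Empty strings and
"NA" are missing tokens; dates are ISO-8601; variant coordinates are
1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_table", "write_table", "write_vcf", "read_vcf_dosages", "TableSchema"]

MISSING_TOKENS = ["", "NA"]


class TableSchema:
    """Required columns and their dtypes for a TSV table.

    ``columns`` maps column name -> numpy/pandas dtype string (or None
    to leave the column as read).  Extra columns in the file are kept
    and logged.
    """

    def __init__(self, name: str, columns: dict[str, str | None]):
        self.name = name
        self.columns = columns


PHENOTYPE_SCHEMA = TableSchema("phenotypes", {"sample_id": None})
INTENSITY_SCHEMA = TableSchema(
    "intensity", {"sample_id": None, "probe_id": None, "panel": None}
)
COVERAGE_SCHEMA = TableSchema(
    "coverage", {"sample_id": None, "normalized_mt_coverage": "float64"}
)
EVENTS_SCHEMA = TableSchema("events", {"sample_id": None, "code": None, "event_date": None})
PHECODE_MAP_SCHEMA = TableSchema(
    "phecode_map",
    {"code": None, "phecode": "float64", "excl_low": "float64", "excl_high": "float64"},
)


def read_table(path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a TSV with header into a typed DataFrame.

    Missing required columns raise an error naming them; cells that
    refuse the schema dtype raise an error with the 1-based data row
    number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", na_values=MISSING_TOKENS, keep_default_na=True, dtype=str)
    logger.info("read %s: %d rows from %s", schema.name if schema else "table", len(df), path)
    if schema is None:
        return df
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for {schema.name}")
    extra = [c for c in df.columns if c not in schema.columns]
    if extra:
        logger.info("%s: tolerating extra columns %s", path, extra)
    for col, dtype in schema.columns.items():
        if dtype is None:
            continue
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(np.flatnonzero(bad)[0]) + 1 if bad.any() else "?"
            raise ValueError(
                f"{path}: column {col!r} has an unparseable cell at data row {row}"
            ) from None
    # convert the remaining columns to numeric where that parses cleanly
    for col in df.columns:
        if schema.columns.get(col, "") is None and col in schema.columns:
            continue
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.notna().equals(df[col].notna()):
                df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def write_vcf(dosages: pd.DataFrame, variants: pd.DataFrame, path) -> Path:
    """Write hard-call dosages as a minimal uncompressed VCF 4.2.

    One sample column per row of ``dosages``; GT from rounded dosage,
    DS the dosage itself, ``./.`` for missing.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(dosages.index)
    meta = variants.set_index("variant_id").reindex(dosages.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in pd.unique(meta["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for vid in dosages.columns:
            row = meta.loc[vid]
            calls = []
            for v in dosages[vid].to_numpy(dtype=float):
                if np.isnan(v):
                    calls.append("./.:.")
                else:
                    calls.append(f"{gt_map[int(round(v))]}:{v:g}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\tA\tG\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(calls)
                + "\n"
            )
    return path


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read dosages (DS field) and variant metadata back from a VCF.

    Uses cyvcf2 when available, else a plain-text fallback sufficient
    for the minimal VCFs written by :func:`write_vcf`.
    """
    path = Path(path)
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    rows, meta = [], []
    if VCF is not None:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        for rec in vcf:
            ds = np.array(rec.format("DS"), dtype=float).ravel()
            rows.append(ds)
            meta.append((rec.ID, rec.CHROM, rec.POS))
    else:  # pragma: no cover - exercised only without cyvcf2
        samples = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    samples = fields[9:]
                    continue
                fmt = fields[8].split(":")
                ds_i = fmt.index("DS")
                ds = [
                    float(c.split(":")[ds_i]) if c.split(":")[ds_i] != "." else np.nan
                    for c in fields[9:]
                ]
                rows.append(np.array(ds))
                meta.append((fields[2], fields[0], int(fields[1])))
    variants = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos"])
    dosages = pd.DataFrame(
        np.array(rows).T, index=pd.Index(samples, name="sample_id"), columns=variants["variant_id"]
    )
    dosages.columns.name = None
    return dosages, variants
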