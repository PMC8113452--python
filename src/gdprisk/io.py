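"""Readers and writers: VCF dosages, covariate tables, catalogs, result tables.

VCF input goes through cyvcf2.  Dosages come from a per-genotype tag
(default ``DS``, the common imputation-server dialect) with a fallback to
hard genotypes (``GT`` coded 0/1/2); per-variant imputation quality is read
from an INFO tag (default ``R2``) when present.  Multiallelic records are
skipped with a logged warning — the downstream analysis is defined on
biallelic dosages only.

Result tables are tab-separated with a header row and full-precision floats
(``repr`` round-trip), written and read through a small schema registry so
every writer has a paired lossless reader.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .datatypes import (
    ANCESTRY_COMPONENTS,
    CatalogEntry,
    DosageDataset,
    KnownVariantCatalog,
    SampleRecord,
    VariantRecord,
)
from .errors import FormatError, InputError, JoinError, SchemaError, UsageError, ValidationError

logger = logging.getLogger(__name__)

_STATUS_VOCAB = {"case": "case", "control": "control", "1": "case", "0": "control"}
_SEX_VOCAB = {"female": "female", "male": "male", "f": "female", "m": "male"}
_SMOKING_VOCAB = {
    "smoker": "smoker",
    "non-smoker": "non-smoker",
    "non smoker": "non-smoker",
    "nonsmoker": "non-smoker",
    "never": "non-smoker",
}

COVARIATE_COLUMNS = ("sid", "status", "sex", "age", "bmi", "smoking") + ANCESTRY_COMPONENTS


def read_vcf_dosages(
    path: str,
    dosage_field: str = "DS",
    impq_info_tag: str = "R2",
) -> tuple[list[VariantRecord], np.ndarray, list[str]]:
    """Read per-sample alternate-allele dosages from a VCF.

    Returns ``(variants, dosage_columns, sample_order)`` where
    ``dosage_columns`` has shape (n_samples, n_variants) in file order.
    Records without the dosage tag fall back to GT allele counts; missing
    genotypes become NaN.  Multiallelic records are skipped with a warning.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise InputError("cyvcf2 is required for VCF input") from exc

    if not os.path.exists(path):
        raise InputError(f"VCF not found: {path}")
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:
        raise InputError(f"unreadable VCF {path}: {exc}") from exc

    sample_order = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%d (%d ALT alleles)",
                rec.CHROM,
                rec.POS,
                len(rec.ALT),
            )
            continue
        dose = None
        try:
            ds = rec.format(dosage_field)
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
            dose = np.where(np.isfinite(dose) & (dose >= 0), dose, np.nan)
        else:
            gts = rec.gt_types  # gts012: 0/1/2, 3 = unknown
            if gts is None or len(gts) == 0:
                raise FormatError(
                    f"record {rec.CHROM}:{rec.POS} has neither {dosage_field} nor GT"
                )
            dose = np.asarray(gts, dtype=float)
            dose[dose == 3] = np.nan
        impq = rec.INFO.get(impq_info_tag)
        impq = float(impq) if impq is not None else None
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variants.append(
            VariantRecord(
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                vid=vid,
                ref=rec.REF,
                alt=rec.ALT[0],
                impq=impq,
                is_imputed=impq is not None,
            )
        )
        columns.append(dose)

    if columns:
        matrix = np.column_stack(columns)
    else:
        matrix = np.empty((len(sample_order), 0))
    return variants, matrix, sample_order


def read_covariates(path: str) -> list[SampleRecord]:
    """Read the sample covariate table (TSV/CSV with a header).

    Required columns: sid, status, sex, age, bmi, smoking, eas, sas, eur,
    afr.  Categorical fields are parsed case-insensitively.  Ancestry rows
    must sum to 1 within 1e-3; all offending sample ids are reported at once.
    """
    if not os.path.exists(path):
        raise InputError(f"covariate file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype={"sid": str})
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"covariate file {path} missing required columns: {missing}")

    bad_sums: list[str] = []
    records: list[SampleRecord] = []
    for row in df.itertuples(index=False):
        anc = tuple(float(getattr(row, c)) for c in ANCESTRY_COMPONENTS)
        if abs(sum(anc) - 1.0) > 1e-3:
            bad_sums.append(str(row.sid))
            continue
        for vocab, value, label in (
            (_STATUS_VOCAB, str(row.status).strip().lower(), "status"),
            (_SEX_VOCAB, str(row.sex).strip().lower(), "sex"),
            (_SMOKING_VOCAB, str(row.smoking).strip().lower(), "smoking"),
        ):
            if value not in vocab:
                raise ValidationError(f"sample {row.sid}: unrecognized {label} {value!r}")
        records.append(
            SampleRecord(
                sid=str(row.sid),
                status=_STATUS_VOCAB[str(row.status).strip().lower()],
                sex=_SEX_VOCAB[str(row.sex).strip().lower()],
                age=float(row.age),
                bmi=float(row.bmi),
                smoking=_SMOKING_VOCAB[str(row.smoking).strip().lower()],
                ancestry=anc,
            )
        )
    if bad_sums:
        raise ValidationError(
            f"ancestry proportions do not sum to 1 (tolerance 1e-3) for samples: {bad_sums}"
        )
    return records


def read_catalog(path: str) -> KnownVariantCatalog:
    """Read a known-variant catalog (columns vid, chrom, pos, risk_allele[, source])."""
    if not os.path.exists(path):
        raise InputError(f"catalog file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype={"vid": str, "chrom": str})
    required = ["vid", "chrom", "pos", "risk_allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"catalog file {path} missing required columns: {missing}")
    entries = [
        CatalogEntry(
            vid=str(r.vid),
            chrom=str(r.chrom),
            pos=int(r.pos),
            risk_allele=str(r.risk_allele),
            source=str(getattr(r, "source", "")) if "source" in df.columns else "",
        )
        for r in df.itertuples(index=False)
    ]
    return KnownVariantCatalog(entries=entries)


def join_dataset(
    variants: list[VariantRecord],
    dosage_columns: np.ndarray,
    samples: list[SampleRecord],
    sample_order: list[str],
) -> DosageDataset:
    """Join VCF dosages with covariate records on sample id.

    The joined dataset is restricted to the intersection of the two sample
    sets, preserving VCF sample order; dropped counts are logged.
    """
    by_sid = {s.sid: s for s in samples}
    keep_idx = [i for i, sid in enumerate(sample_order) if sid in by_sid]
    if not keep_idx:
        raise JoinError("no overlap between VCF samples and covariate samples")
    n_drop_vcf = len(sample_order) - len(keep_idx)
    n_drop_cov = len(samples) - len(keep_idx)
    if n_drop_vcf:
        logger.info("dropping %d VCF samples without covariates", n_drop_vcf)
    if n_drop_cov:
        logger.info("dropping %d covariate samples absent from VCF", n_drop_cov)
    joined_samples = [by_sid[sample_order[i]] for i in keep_idx]
    matrix = np.asarray(dosage_columns, dtype=float)[keep_idx, :]
    return DosageDataset(samples=joined_samples, variants=list(variants), dosages=matrix)


# ---------------------------------------------------------------------------
# result-table schema registry

TABLE_SCHEMAS: dict[str, list[str]] = {
    "assoc": [
        "vid", "chrom", "pos", "ref", "alt", "maf",
        "beta", "se", "z", "p", "or_", "n", "converged",
    ],
    "screen": ["vid", "log10_bf", "rank", "selected"],
    "model": ["term", "vid", "chrom", "pos", "gene", "ref", "maf", "estimate"],
    "cohort": ["label", "case_summary", "control_summary", "test", "p"],
    "replication": [
        "vid", "chrom", "pos", "risk_allele", "found", "reason",
        "beta_risk", "p", "flagged", "orientation",
    ],
    "region": ["vid", "chrom", "pos", "ref", "alt", "maf", "beta", "se", "z", "p"],
    "truth": ["vid", "true_beta", "allele_freq"],
}

_INT_COLS = {"pos", "rank", "n"}
_BOOL_COLS = {"converged", "selected", "flagged", "found"}


def _format_value(col: str, v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "NA"
    if col in _BOOL_COLS:
        return "1" if v else "0"
    if col in _INT_COLS:
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_table(rows, path: str, schema: str) -> None:
    """Write result rows as TSV under a registered schema.

    ``rows`` is an iterable of dicts (or objects with matching attributes).
    Floats are written at full precision so the paired reader round-trips.
    """
    if schema not in TABLE_SCHEMAS:
        raise UsageError(f"unknown table schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    cols = TABLE_SCHEMAS[schema]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            get = row.get if isinstance(row, dict) else lambda c, r=row: getattr(r, c)
            fh.write("\t".join(_format_value(c, get(c)) for c in cols) + "\n")


def read_table(path: str, schema: str) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` back into a DataFrame."""
    if schema not in TABLE_SCHEMAS:
        raise UsageError(f"unknown table schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"vid": str, "chrom": str})
    expected = TABLE_SCHEMAS[schema]
    if list(df.columns) != expected:
        raise SchemaError(f"{path} does not match schema {schema!r}: {list(df.columns)}")
    for col in _BOOL_COLS & set(df.columns):
        df[col] = df[col].astype("boolean").astype(object).map(
            lambda x: bool(x) if x is not pd.NA else None
        )
    return df
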