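"""Variant-level quality-control filters.

Two sequential filters, both strict (``<``) so boundary values are
retained: imputed variants with imputation quality below ``impq_min``
(default 0.3) are removed first, then variants with minor allele frequency
below ``maf_min`` (default 0.01).  Directly genotyped variants (no
imputation-quality score) pass the first filter unconditionally.  MAF is
computed on the pooled analysis sample (cases + controls).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from .datatypes import DosageDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcReport:
    """Per-filter removal counts; filters are sequential, so a variant is
    counted at its first removal and n_input = removed + retained."""

    n_input: int
    n_removed_impq: int
    n_removed_maf: int
    n_retained: int
    impq_min: float
    maf_min: float

    def as_dict(self) -> dict:
        return asdict(self)


def minor_allele_frequency(dosage_column: np.ndarray) -> float:
    """Folded allele frequency min(f, 1-f) with f = mean(dosage)/2.

    Missing (NaN) dosages are ignored; an all-missing column is an error.
    """
    col = np.asarray(dosage_column, dtype=float)
    finite = col[np.isfinite(col)]
    if finite.size == 0:
        raise ValidationError("MAF undefined: all dosages missing")
    f = float(finite.mean()) / 2.0
    return min(f, 1.0 - f)


def apply_qc(
    dataset: DosageDataset, impq_min: float = 0.3, maf_min: float = 0.01
) -> tuple[DosageDataset, QcReport]:
    """Apply the imputation-quality filter then the MAF filter.

    Returns the filtered dataset (variant order preserved) and a report.
    Idempotent: re-applying to the output removes nothing further.
    """
    m = dataset.n_variants
    fail_impq = np.zeros(m, dtype=bool)
    for j, v in enumerate(dataset.variants):
        if v.impq is not None and v.impq < impq_min:
            fail_impq[j] = True

    fail_maf = np.zeros(m, dtype=bool)
    for j in range(m):
        if fail_impq[j]:
            continue
        if minor_allele_frequency(dataset.dosages[:, j]) < maf_min:
            fail_maf[j] = True

    keep = np.flatnonzero(~fail_impq & ~fail_maf)
    report = QcReport(
        n_input=m,
        n_removed_impq=int(fail_impq.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.size),
        impq_min=impq_min,
        maf_min=maf_min,
    )
    if keep.size == 0:
        logger.warning("QC removed every variant (impq_min=%g, maf_min=%g)", impq_min, maf_min)
    return dataset.subset_variants(keep), report
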