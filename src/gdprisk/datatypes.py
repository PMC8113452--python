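"""Core data containers for the case-control dosage analysis.

The central object is :class:`DosageDataset`: an ordered sample list, an
ordered variant list, and a samples x variants matrix of alternate-allele
dosages in [0, 2] (NaN marks a missing genotype).  Every pipeline stage
consumes and/or returns one of the types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

ANCESTRY_COMPONENTS = ("eas", "sas", "eur", "afr")

#: tolerance for ancestry proportions summing to one (per-record constructor check)
ANCESTRY_SUM_TOL = 1e-3


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant.

    ``impq`` is the per-variant imputation quality (r-squared) in [0, 1];
    it is ``None`` for directly genotyped variants, which then pass the
    imputation-quality filter unconditionally.
    """

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str
    impq: float | None = None
    is_imputed: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.vid}: pos must be >= 1, got {self.pos}")
        if self.impq is not None and not (0.0 <= self.impq <= 1.0):
            raise ValidationError(
                f"variant {self.vid}: imputation quality {self.impq} outside [0, 1]"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One study participant with case/control status and covariates.

    ``ancestry`` holds estimated global ancestry proportions for the
    EAS/SAS/EUR/AFR components, each in [0, 1] and summing to one.
    """

    sid: str
    status: str  # "case" | "control"
    sex: str  # "female" | "male"
    age: float
    bmi: float
    smoking: str  # "smoker" | "non-smoker"
    ancestry: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(f"sample {self.sid}: bad status {self.status!r}")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sample {self.sid}: bad sex {self.sex!r}")
        if self.smoking not in ("smoker", "non-smoker"):
            raise ValidationError(f"sample {self.sid}: bad smoking {self.smoking!r}")
        if self.age < 0:
            raise ValidationError(f"sample {self.sid}: negative age")
        if self.bmi <= 0:
            raise ValidationError(f"sample {self.sid}: non-positive BMI")
        a = np.asarray(self.ancestry, dtype=float)
        if a.shape != (4,) or (a < -1e-12).any() or (a > 1 + 1e-12).any():
            raise ValidationError(f"sample {self.sid}: ancestry proportions outside [0, 1]")
        if abs(a.sum() - 1.0) > ANCESTRY_SUM_TOL:
            raise ValidationError(
                f"sample {self.sid}: ancestry proportions sum to {a.sum():.6f}, not 1"
            )

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class DosageDataset:
    """Joined sample x variant dosage matrix with annotations.

    ``dosages`` has shape ``(len(samples), len(variants))``; entries are
    alternate-allele dosages in [0, 2] with NaN for missing.
    """

    samples: list[SampleRecord]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and ((finite < 0).any() or (finite > 2).any()):
            raise ValidationError("dosages must lie in [0, 2] (or be NaN for missing)")
        vids = [v.vid for v in self.variants]
        if len(set(vids)) != len(vids):
            raise ValidationError("variant identifiers are not unique")
        sids = [s.sid for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValidationError("sample identifiers are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def status_vector(self) -> np.ndarray:
        """Binary outcome: 1 for cases, 0 for controls."""
        return np.array([1.0 if s.is_case else 0.0 for s in self.samples])

    def covariate_frame(self):
        """Covariates as a pandas DataFrame indexed by sample id.

        ``sex`` is coded 1 = male, ``smoking`` 1 = smoker; ancestry
        proportions appear as columns eas/sas/eur/afr.
        """
        import pandas as pd

        rows = {
            "sid": [s.sid for s in self.samples],
            "status": [1 if s.is_case else 0 for s in self.samples],
            "sex": [1.0 if s.sex == "male" else 0.0 for s in self.samples],
            "age": [s.age for s in self.samples],
            "bmi": [s.bmi for s in self.samples],
            "smoking": [1.0 if s.smoking == "smoker" else 0.0 for s in self.samples],
        }
        anc = np.array([s.ancestry for s in self.samples], dtype=float)
        for k, name in enumerate(ANCESTRY_COMPONENTS):
            rows[name] = anc[:, k]
        return pd.DataFrame(rows).set_index("sid")

    def variant_index(self) -> dict[str, int]:
        return {v.vid: j for j, v in enumerate(self.variants)}

    def subset_variants(self, keep: np.ndarray) -> "DosageDataset":
        """New dataset restricted to variant indices ``keep`` (order preserved)."""
        keep = np.asarray(keep, dtype=int)
        return DosageDataset(
            samples=self.samples,
            variants=[self.variants[j] for j in keep],
            dosages=self.dosages[:, keep],
        )


@dataclass(frozen=True)
class CatalogEntry:
    """One previously reported risk variant."""

    vid: str
    chrom: str
    pos: int
    risk_allele: str
    source: str = ""


@dataclass
class KnownVariantCatalog:
    """Catalog of previously reported disease-associated variants."""

    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        vids = [e.vid for e in self.entries]
        if len(set(vids)) != len(vids):
            raise ValidationError("catalog variant identifiers are not unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)
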