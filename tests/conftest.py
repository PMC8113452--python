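import numpy as np
import pytest

from gdprisk.datatypes import DosageDataset, SampleRecord, VariantRecord
from gdprisk.simulate import SimConfig, simulate_cohort


def make_samples(n_case: int, n_control: int, rng: np.random.Generator) -> list[SampleRecord]:
    """Hand-rolled sample records with plausible covariates."""
    samples = []
    for i in range(n_case + n_control):
        anc = rng.dirichlet((92.0, 7.0, 1.0, 0.1))
        samples.append(
            SampleRecord(
                sid=f"S{i:03d}",
                status="case" if i < n_case else "control",
                sex="male" if rng.random() < 0.55 else "female",
                age=float(rng.normal(52, 10)),
                bmi=float(rng.normal(23, 3)),
                smoking="smoker" if rng.random() < 0.3 else "non-smoker",
                ancestry=tuple(float(a) for a in anc),
            )
        )
    return samples


def make_variants(m: int, chrom: str = "1", spacing: int = 1000) -> list[VariantRecord]:
    return [
        VariantRecord(chrom=chrom, pos=1 + j * spacing, vid=f"v{j}", ref="A", alt="G",
                      impq=1.0, is_imputed=True)
        for j in range(m)
    ]


@pytest.fixture
def tiny_dataset() -> DosageDataset:
    """40 samples x 6 variants with random integer dosages."""
    rng = np.random.default_rng(7)
    samples = make_samples(20, 20, rng)
    variants = make_variants(6)
    dosages = rng.binomial(2, 0.3, size=(40, 6)).astype(float)
    return DosageDataset(samples=samples, variants=variants, dosages=dosages)


@pytest.fixture(scope="session")
def small_cohort():
    """Session-wide synthetic cohort with two causal variants."""
    cfg = SimConfig(
        n_case=60,
        n_control=60,
        m_variants=40,
        causal_ids=(3, 25),
        causal_betas=(0.9, -0.9),
        impq_range=(0.5, 1.0),
        seed=11,
    )
    dataset, truth = simulate_cohort(cfg)
    return cfg, dataset, truth
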