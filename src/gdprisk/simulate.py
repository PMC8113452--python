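"""Synthetic case-control dosage cohorts with known ground truth.

Genotypes follow a Gaussian-copula threshold model: within each LD block a
latent standard-normal vector with AR(1) correlation ``rho^|i-j|`` is
thresholded at each variant's allele-frequency quantile to give one
haplotype's allele indicators; a genotype dosage is the sum of two
independent haplotypes (Hardy-Weinberg by construction).  Blocks are
independent, so LD is local and tunable through a single parameter.

Disease status is drawn from a logistic model on raw dosages plus
covariates (continuous covariates standardized by their generating
moments), and the population is sampled retrospectively until the
requested case and control counts accrue — mirroring a frequency-matched
case-control design, under which the logistic slopes remain estimable while
the intercept does not reflect prevalence.

Default parameters emulate a small admixed Southeast-Asian colorectal
cancer study: 84 cases and 89 controls, majority-male, East-Asian-dominant
ancestry proportions, smoking strongly enriched in cases and BMI lower in
cases, and a handful of causal variants with odds ratios around 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import DosageDataset, SampleRecord, VariantRecord
from .errors import AccrualError, UsageError

# moments of the generating covariate distributions, used to standardize
# continuous covariates inside the risk model so stated effects are per SD
_AGE_MEAN, _AGE_SD = 52.0, 14.0
_BMI_MEAN, _BMI_SD = 23.0, 3.5


# log odds per dosage unit; magnitudes around the OR ~ 1.8-2.2 range
# seen for replicated colorectal-cancer loci
_DEFAULT_CAUSAL_BETAS = (
    math.log(2.2),
    -math.log(2.0),
    math.log(2.0),
    -math.log(1.8),
    math.log(1.8),
)


@dataclass
class SimConfig:
    """Configuration for one synthetic cohort.

    ``covariate_effects`` are log-odds for sex (male vs female), age (per
    SD), bmi (per SD) and smoking (smoker vs non-smoker); causal_betas are
    log-odds per alternate-allele dosage unit.
    """

    n_case: int = 84
    n_control: int = 89
    m_variants: int = 500
    block_size: int = 10
    rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_ids: tuple[int, ...] | None = None  # None: 5 variants spread evenly
    causal_betas: tuple[float, ...] | None = None
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.0, "age": 0.25, "bmi": -0.8, "smoking": 1.3}
    )
    intercept: float = -1.5
    male_rate: float = 0.57
    smoking_rate: float = 0.25
    ancestry_conc: tuple[float, float, float, float] = (92.0, 7.0, 1.0, 0.1)
    impq_range: tuple[float, float] = (0.2, 1.0)
    chrom: str = "1"
    pos_spacing: int = 5000
    max_draw_factor: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise UsageError(f"rho must be in [0, 1), got {self.rho}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise UsageError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.causal_ids is None:
            # a handful of causal variants spread across distinct LD blocks
            k = min(5, self.m_variants)
            ids = np.unique(np.linspace(0, self.m_variants - 1, k).round().astype(int))
            self.causal_ids = tuple(int(j) for j in ids)
        if self.causal_betas is None:
            self.causal_betas = tuple(
                _DEFAULT_CAUSAL_BETAS[j % len(_DEFAULT_CAUSAL_BETAS)]
                for j in range(len(self.causal_ids))
            )
        if len(self.causal_ids) != len(self.causal_betas):
            raise UsageError("causal_ids and causal_betas must have equal length")
        if any(not (0 <= j < self.m_variants) for j in self.causal_ids):
            raise UsageError("causal indices must lie in [0, m_variants)")
        qlo, qhi = self.impq_range
        if not (0.0 <= qlo <= qhi <= 1.0):
            raise UsageError(f"impq_range must lie within [0, 1], got {self.impq_range}")
        if self.n_case < 1 or self.n_control < 1 or self.m_variants < 1:
            raise UsageError("n_case, n_control and m_variants must be positive")


@dataclass
class TruthRecord:
    """Generator ground truth for parameter-recovery tests."""

    beta: np.ndarray  # per-variant true log-odds (0 for non-causal)
    covariate_effects: dict
    intercept: float
    prevalence: float  # realized case fraction among all population draws
    allele_freq: np.ndarray  # target alternate-allele frequencies


def _ar1_normals(rng: np.ndarray, n: int, m: int, block_size: int, rho: float) -> np.ndarray:
    """n x m latent normals, AR(1) within consecutive blocks, blocks independent."""
    z = rng.standard_normal((n, m))
    if rho == 0.0:
        return z
    x = np.empty_like(z)
    c = math.sqrt(1.0 - rho * rho)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        x[:, start] = z[:, start]
        for j in range(start + 1, stop):
            x[:, j] = rho * x[:, j - 1] + c * z[:, j]
    return x


def _draw_dosages(rng, n: int, freqs: np.ndarray, cfg: SimConfig) -> np.ndarray:
    thr = stats.norm.ppf(freqs)  # latent < threshold => alt allele
    m = freqs.size
    hap1 = _ar1_normals(rng, n, m, cfg.block_size, cfg.rho) < thr
    hap2 = _ar1_normals(rng, n, m, cfg.block_size, cfg.rho) < thr
    return (hap1.astype(float) + hap2.astype(float))


def simulate_genotypes(
    config: SimConfig, n: int | None = None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[VariantRecord], np.ndarray]:
    """Draw an n x m dosage matrix plus variant annotations.

    Returns ``(dosages, variants, allele_freqs)``; fully reproducible from
    ``config.seed`` when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n is None:
        n = config.n_case + config.n_control
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.m_variants)
    impq = rng.uniform(config.impq_range[0], config.impq_range[1], size=config.m_variants)
    dosages = _draw_dosages(rng, n, freqs, config)
    variants = [
        VariantRecord(
            chrom=config.chrom,
            pos=1 + j * config.pos_spacing,
            vid=f"sim{j}",
            ref="A",
            alt="G",
            impq=round(float(impq[j]), 6),
            is_imputed=True,
        )
        for j in range(config.m_variants)
    ]
    return dosages, variants, freqs


def _draw_covariates(rng, n: int, cfg: SimConfig) -> dict[str, np.ndarray]:
    sex = (rng.random(n) < cfg.male_rate).astype(float)  # 1 = male
    age = rng.normal(_AGE_MEAN, _AGE_SD, size=n)
    while True:  # truncate age >= 18
        bad = age < 18
        if not bad.any():
            break
        age[bad] = rng.normal(_AGE_MEAN, _AGE_SD, size=bad.sum())
    bmi = rng.normal(_BMI_MEAN, _BMI_SD, size=n)
    while True:  # truncate bmi > 10
        bad = bmi <= 10
        if not bad.any():
            break
        bmi[bad] = rng.normal(_BMI_MEAN, _BMI_SD, size=bad.sum())
    smoking = (rng.random(n) < cfg.smoking_rate).astype(float)
    ancestry = rng.dirichlet(np.asarray(cfg.ancestry_conc, dtype=float), size=n)
    return {"sex": sex, "age": age, "bmi": bmi, "smoking": smoking, "ancestry": ancestry}


def simulate_cohort(config: SimConfig) -> tuple[DosageDataset, TruthRecord]:
    """Retrospectively sample a case-control cohort from the logistic model.

    Population individuals are drawn in batches until ``n_case`` cases and
    ``n_control`` controls accrue; surplus draws of either class are
    discarded.  Raises :class:`AccrualError` if the draw budget
    (``max_draw_factor`` times the target cohort size) is exhausted —
    usually a sign of an extreme intercept.
    """
    rng = np.random.default_rng(config.seed)
    target = config.n_case + config.n_control
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.m_variants)
    impq = rng.uniform(config.impq_range[0], config.impq_range[1], size=config.m_variants)

    beta = np.zeros(config.m_variants)
    for j, b in zip(config.causal_ids, config.causal_betas):
        beta[j] = b
    eff = config.covariate_effects

    kept_dos: list[np.ndarray] = []
    kept_cov: list[dict] = []
    kept_status: list[np.ndarray] = []
    n_case_have = n_control_have = 0
    n_drawn = n_cases_drawn = 0
    budget = config.max_draw_factor * target
    batch = max(2 * target, 200)

    while n_case_have < config.n_case or n_control_have < config.n_control:
        if n_drawn >= budget:
            raise AccrualError(
                f"drew {n_drawn} individuals without accruing {config.n_case} cases "
                f"and {config.n_control} controls; consider moving the intercept "
                f"({config.intercept}) toward 0"
            )
        nb = min(batch, budget - n_drawn)
        dos = _draw_dosages(rng, nb, freqs, config)
        cov = _draw_covariates(rng, nb, config)
        logit = (
            config.intercept
            + dos @ beta
            + eff.get("sex", 0.0) * cov["sex"]
            + eff.get("age", 0.0) * (cov["age"] - _AGE_MEAN) / _AGE_SD
            + eff.get("bmi", 0.0) * (cov["bmi"] - _BMI_MEAN) / _BMI_SD
            + eff.get("smoking", 0.0) * cov["smoking"]
        )
        status = (rng.random(nb) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
        n_drawn += nb
        n_cases_drawn += int(status.sum())
        kept_dos.append(dos)
        kept_cov.append(cov)
        kept_status.append(status)
        n_case_have += int(status.sum())
        n_control_have += int((1 - status).sum())

    dos = np.vstack(kept_dos)
    status = np.concatenate(kept_status)
    cov = {
        k: (np.vstack if k == "ancestry" else np.concatenate)([c[k] for c in kept_cov])
        for k in kept_cov[0]
    }

    case_idx = np.flatnonzero(status == 1)[: config.n_case]
    ctrl_idx = np.flatnonzero(status == 0)[: config.n_control]
    order = np.sort(np.concatenate([case_idx, ctrl_idx]))

    samples = []
    for k, i in enumerate(order):
        anc = cov["ancestry"][i]
        anc = tuple(float(a) for a in anc / anc.sum())
        samples.append(
            SampleRecord(
                sid=f"S{k:04d}",
                status="case" if status[i] == 1 else "control",
                sex="male" if cov["sex"][i] == 1.0 else "female",
                age=float(cov["age"][i]),
                bmi=float(cov["bmi"][i]),
                smoking="smoker" if cov["smoking"][i] == 1.0 else "non-smoker",
                ancestry=anc,
            )
        )
    variants = [
        VariantRecord(
            chrom=config.chrom,
            pos=1 + j * config.pos_spacing,
            vid=f"sim{j}",
            ref="A",
            alt="G",
            impq=round(float(impq[j]), 6),
            is_imputed=True,
        )
        for j in range(config.m_variants)
    ]
    dataset = DosageDataset(samples=samples, variants=variants, dosages=dos[order, :])
    truth = TruthRecord(
        beta=beta,
        covariate_effects=dict(eff),
        intercept=config.intercept,
        prevalence=n_cases_drawn / n_drawn,
        allele_freq=freqs,
    )
    return dataset, truth


def write_synthetic_vcf(dataset: DosageDataset, path: str) -> None:
    """Write the dataset as a VCF (v4.2) with DS genotype and R2 INFO fields.

    The file round-trips exactly through :func:`gdprisk.io.read_vcf_dosages`.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        contigs = []
        for v in dataset.variants:
            if v.chrom not in contigs:
                contigs.append(v.chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [s.sid for s in dataset.samples]
        fh.write("\t".join(header) + "\n")
        for j, v in enumerate(dataset.variants):
            info = f"R2={v.impq:g}" if v.impq is not None else "."
            col = dataset.dosages[:, j]
            fields = [v.chrom, str(v.pos), v.vid, v.ref, v.alt, ".", "PASS", info, "DS"]
            fields += ["." if not np.isfinite(d) else f"{d:g}" for d in col]
            fh.write("\t".join(fields) + "\n")


def write_covariates_tsv(dataset: DosageDataset, path: str) -> None:
    """Write the sample covariates as the TSV dialect read_covariates expects."""
    with open(path, "w") as fh:
        fh.write("sid\tstatus\tsex\tage\tbmi\tsmoking\teas\tsas\teur\tafr\n")
        for s in dataset.samples:
            anc = "\t".join(repr(float(a)) for a in s.ancestry)
            fh.write(
                f"{s.sid}\t{s.status}\t{s.sex}\t{s.age!r}\t{s.bmi!r}\t{s.smoking}\t{anc}\n"
            )


def write_truth_tsv(truth: TruthRecord, variants: list[VariantRecord], path: str) -> None:
    from .io import write_table

    rows = [
        {"vid": v.vid, "true_beta": float(truth.beta[j]), "allele_freq": float(truth.allele_freq[j])}
        for j, v in enumerate(variants)
    ]
    write_table(rows, path, "truth")
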