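"""Case/control cohort comparisons (baseline-characteristics table).

Continuous characteristics are compared with Welch's unequal-variance
t-test (Satterthwaite degrees of freedom) — computable either from raw
per-sample values or from printed group summaries (mean, SD, n).
Categorical characteristics use the Pearson chi-square test, with the
Yates continuity correction by default for 2x2 tables; r x c tables with
small expected counts additionally get a seeded Monte-Carlo p-value under
fixed margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ANCESTRY_COMPONENTS, DosageDataset
from .errors import UsageError, ValidationError


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one group: mean, SD, and count (n >= 2)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise UsageError(f"group summary needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise UsageError(f"negative SD {self.sd}")


@dataclass
class CohortRow:
    label: str
    case_summary: str
    control_summary: str
    test: str
    p: float


def welch_t(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float, float]:
    """Welch's two-sample t-test from summaries: (t, df, two-sided p).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Satterthwaite df.
    """
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    if v1 + v2 == 0.0:
        if g1.mean == g2.mean:
            raise ValidationError("both SDs zero and means equal: t undefined")
        return math.inf, float(g1.n + g2.n - 2), 0.0
    t = (g1.mean - g2.mean) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, min(p, 1.0)


def welch_t_from_samples(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float, float]:
    s1 = GroupSummary(float(np.mean(x1)), float(np.std(x1, ddof=1)), len(x1))
    s2 = GroupSummary(float(np.mean(x2)), float(np.std(x2, ddof=1)), len(x2))
    return welch_t(s1, s2)


def chisq_2x2(a: int, b: int, c: int, d: int, continuity: bool = True) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], 1 df.

    Yates continuity correction applied when ``continuity`` (the default
    for 2x2 tables).  A zero margin is a degenerate table.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise UsageError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("degenerate 2x2 table: a margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)


def chisq_rxc(
    table: np.ndarray,
    mc_reps: int | None = None,
    seed: int = 0,
    force_mc: bool = False,
) -> dict:
    """Pearson chi-square on an r x c table, (r-1)(c-1) df.

    Returns {"chi2", "df", "p", "p_mc"}; ``p_mc`` is a Monte-Carlo
    permutation p-value under fixed margins, computed (with ``mc_reps``
    tables, default 1e5) whenever any expected count is below 5 or
    ``force_mc`` is set, else None.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise UsageError("table must be at least 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("degenerate table: a margin is zero")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    p_mc = None
    if force_mc or (expected < 5).any():
        reps = int(mc_reps) if mc_reps else 100_000
        rng = np.random.default_rng(seed)
        rt = stats.random_table(table.sum(axis=1).astype(int), table.sum(axis=0).astype(int))
        sims = rt.rvs(reps, random_state=rng)
        stat = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        p_mc = float((1 + np.count_nonzero(stat >= chi2 - 1e-12)) / (reps + 1))
    return {"chi2": float(chi2), "df": int(df), "p": float(p), "p_mc": p_mc}


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})"


def _fmt_count_pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f}%)"


def cohort_table(dataset: DosageDataset, mc_seed: int = 0) -> list[CohortRow]:
    """Baseline-characteristics comparison of cases vs controls.

    Rows: age and BMI (mean (SD), Welch t), gender and smoking status
    (count (%), Yates chi-square), and ancestry-component means
    (descriptive Welch t on per-sample proportions).
    """
    frame = dataset.covariate_frame()
    case = frame[frame["status"] == 1]
    ctrl = frame[frame["status"] == 0]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValidationError("need at least 2 cases and 2 controls")
    rows: list[CohortRow] = []

    for label, col in (("Age", "age"), ("BMI", "bmi")):
        _, _, p = welch_t_from_samples(case[col].to_numpy(), ctrl[col].to_numpy())
        rows.append(CohortRow(label, _fmt_mean_sd(case[col]), _fmt_mean_sd(ctrl[col]),
                              "welch-t", p))

    for label, col, level_one in (("Gender (male)", "sex", 1.0),
                                  ("Smoking (smoker)", "smoking", 1.0)):
        a = int((case[col] == level_one).sum())
        b = int((case[col] != level_one).sum())
        c = int((ctrl[col] == level_one).sum())
        d = int((ctrl[col] != level_one).sum())
        _, p = chisq_2x2(a, b, c, d, continuity=True)
        rows.append(CohortRow(label, _fmt_count_pct(a, len(case)),
                              _fmt_count_pct(c, len(ctrl)), "chisq-yates", p))

    for comp in ANCESTRY_COMPONENTS:
        _, _, p = welch_t_from_samples(case[comp].to_numpy(), ctrl[comp].to_numpy())
        rows.append(CohortRow(f"Ancestry {comp.upper()}",
                              f"{case[comp].mean():.2f}", f"{ctrl[comp].mean():.2f}",
                              "welch-t", p))
    return rows
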