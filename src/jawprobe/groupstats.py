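"""Group-comparison battery: normality gating, pooled t, Mann-Whitney U,
Cohen's d with confidence interval, and phoneme-accuracy percentages.

Each cohort variable (the five criterion totals, the mandibular percent
total, and PCC/PVC/PPC where available) is compared between the TD and SSD
groups.  Normality of each group is gated by the Shapiro-Wilk test
(p > 0.05) together with standardized skewness and kurtosis within +/-1.96;
both groups passing selects the pooled-variance t-test, otherwise the
Mann-Whitney U test with midrank ties and a continuity-corrected normal
approximation.  Cohen's d (pooled, (n-1)-weighted SD) is always reported,
with the normal-approximation 95% CI

    d +/- 1.96 * sqrt((n1 + n2) / (n1 n2) + d^2 / (2 (n1 + n2))).

Alpha is 0.05 with no multiplicity adjustment, matching a deliberately
type-II-protective preliminary design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CRITERIA, Participant


class GroupStatsError(ValueError):
    """Degenerate or insufficient samples."""


@dataclass(frozen=True)
class GroupSummary:
    """Sizes, means and sample SDs (n-1) of two groups."""

    n1: int
    n2: int
    m1: float
    m2: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise GroupStatsError("each group needs n >= 2")
        if self.s1 < 0 or self.s2 < 0:
            raise GroupStatsError("SDs must be >= 0")

    @classmethod
    def from_samples(cls, x1: Sequence[float], x2: Sequence[float]) -> "GroupSummary":
        x1 = np.asarray(x1, float)
        x2 = np.asarray(x2, float)
        return cls(
            n1=len(x1), n2=len(x2),
            m1=float(x1.mean()), m2=float(x2.mean()),
            s1=float(x1.std(ddof=1)), s2=float(x2.std(ddof=1)),
        )

    @property
    def pooled_sd(self) -> float:
        return float(
            np.sqrt(
                ((self.n1 - 1) * self.s1**2 + (self.n2 - 1) * self.s2**2)
                / (self.n1 + self.n2 - 2)
            )
        )


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PhonemeCounts:
    consonants_correct: int
    consonants_total: int
    vowels_correct: int
    vowels_total: int

    def __post_init__(self) -> None:
        if self.consonants_total <= 0 or self.vowels_total <= 0:
            raise GroupStatsError("phoneme totals must be positive")
        if not (0 <= self.consonants_correct <= self.consonants_total):
            raise GroupStatsError("consonants_correct outside [0, total]")
        if not (0 <= self.vowels_correct <= self.vowels_total):
            raise GroupStatsError("vowels_correct outside [0, total]")


def cohens_d(gs: GroupSummary) -> EffectSize:
    """Pooled-SD Cohen's d with a normal-approximation 95% CI."""
    sp = gs.pooled_sd
    if sp == 0.0:
        raise GroupStatsError("pooled SD is zero; d undefined")
    d = (gs.m1 - gs.m2) / sp
    n = gs.n1 + gs.n2
    se = np.sqrt(n / (gs.n1 * gs.n2) + d**2 / (2 * n))
    return EffectSize(d=float(d), ci_low=float(d - 1.96 * se), ci_high=float(d + 1.96 * se))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def pooled_t_test(gs: GroupSummary) -> TTestResult:
    """Independent-samples pooled-variance t-test from group summaries."""
    sp = gs.pooled_sd
    if sp == 0.0:
        raise GroupStatsError("pooled SD is zero; t undefined")
    t = (gs.m1 - gs.m2) / (sp * np.sqrt(1.0 / gs.n1 + 1.0 / gs.n2))
    df = gs.n1 + gs.n2 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=int(df), p=float(p))


def mann_whitney_u(x1: Sequence[float], x2: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (reported as min(U1, U2), midrank ties) with a
    continuity-corrected, tie-corrected normal-approximation p-value."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if len(x1) == 0 or len(x2) == 0:
        raise GroupStatsError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        x1, x2, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    u1 = float(res.statistic)
    u = min(u1, len(x1) * len(x2) - u1)
    return u, float(res.pvalue)


def normality_gate(sample: Sequence[float]) -> str:
    """"parametric" iff Shapiro-Wilk p > 0.05 and both standardized skewness
    and kurtosis lie within +/-1.96 (large-sample SE formulas)."""
    x = np.asarray(sample, float)
    n = len(x)
    if n < 3:
        raise GroupStatsError("normality gate needs n >= 3")
    if np.std(x) == 0:
        return "nonparametric"
    sw_p = float(stats.shapiro(x).pvalue)
    se_skew = np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    z_skew = stats.skew(x, bias=False) / se_skew
    if n > 3:
        se_kurt = 2.0 * se_skew * np.sqrt((n**2 - 1) / ((n - 3) * (n + 5)))
        z_kurt = stats.kurtosis(x, fisher=True, bias=False) / se_kurt
    else:
        z_kurt = np.inf
    if sw_p > 0.05 and abs(z_skew) <= 1.96 and abs(z_kurt) <= 1.96:
        return "parametric"
    return "nonparametric"


def phoneme_accuracy(pc: PhonemeCounts) -> tuple[float, float, float]:
    """(PCC, PVC, PPC) percentages from phoneme counts."""
    pcc = 100.0 * pc.consonants_correct / pc.consonants_total
    pvc = 100.0 * pc.vowels_correct / pc.vowels_total
    ppc = (
        100.0
        * (pc.consonants_correct + pc.vowels_correct)
        / (pc.consonants_total + pc.vowels_total)
    )
    return pcc, pvc, ppc


#: Comparable cohort variables.
VARIABLES: tuple[str, ...] = CRITERIA + ("percent_total", "pcc", "pvc", "ppc")


def _variable_values(participants: Sequence[Participant], variable: str) -> dict[str, np.ndarray]:
    out: dict[str, list[float]] = {"TD": [], "SSD": []}
    for p in participants:
        if variable in CRITERIA:
            value = float(p.score_sheet.criterion_totals[variable])
        elif variable == "percent_total":
            value = p.score_sheet.percent_total
        elif variable in ("pcc", "pvc", "ppc"):
            if p.phoneme_accuracy is None:
                continue
            value = float(p.phoneme_accuracy[variable])
        else:
            raise GroupStatsError(f"unknown variable {variable!r}")
        out[p.group].append(value)
    return {g: np.asarray(v, float) for g, v in out.items()}


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    test: str
    statistic: float
    df: int | None
    p: float
    d: float
    ci_low: float
    ci_high: float
    summary: GroupSummary

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def compare_groups(participants: Sequence[Participant], variable: str) -> ComparisonRow:
    """Compare TD vs SSD on one variable: normality-gated test choice plus
    Cohen's d with CI; alpha 0.05, no multiplicity adjustment."""
    values = _variable_values(participants, variable)
    td, ssd = values["TD"], values["SSD"]
    if len(td) < 3 or len(ssd) < 3:
        raise GroupStatsError(f"{variable}: both groups need n >= 3")
    if np.std(np.concatenate([td, ssd])) == 0:
        raise GroupStatsError(f"{variable}: zero variance overall")
    gs = GroupSummary.from_samples(td, ssd)
    effect = cohens_d(gs)
    parametric = (
        normality_gate(td) == "parametric" and normality_gate(ssd) == "parametric"
    )
    if parametric:
        tt = pooled_t_test(gs)
        test, statistic, df, p = "t", tt.t, tt.df, tt.p
    else:
        u, p = mann_whitney_u(td, ssd)
        test, statistic, df = "mann-whitney", u, None
    return ComparisonRow(
        variable=variable, test=test, statistic=statistic, df=df, p=p,
        d=effect.d, ci_low=effect.ci_low, ci_high=effect.ci_high, summary=gs,
    )


def group_comparison_table(participants: Sequence[Participant]) -> pd.DataFrame:
    """One comparison row per available cohort variable."""
    rows = []
    has_phoneme = any(p.phoneme_accuracy is not None for p in participants)
    for variable in VARIABLES:
        if variable in ("pcc", "pvc", "ppc") and not has_phoneme:
            continue
        row = compare_groups(participants, variable)
        rows.append(
            {
                "variable": row.variable,
                "td_mean": row.summary.m1,
                "td_sd": row.summary.s1,
                "ssd_mean": row.summary.m2,
                "ssd_sd": row.summary.s2,
                "test": row.test,
                "statistic": row.statistic,
                "df": row.df,
                "p": row.p,
                "d": row.d,
                "d_ci_low": row.ci_low,
                "d_ci_high": row.ci_high,
            }
        )
    return pd.DataFrame(rows)
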