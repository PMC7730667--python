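"""Per-stratum symptom frequencies and the two-proportion test.

The survey literature this package serves reports a "Z-test" for comparing
symptom prevalence between two strata but prints values on the chi-square
scale.  Reverse-engineering those printed values shows they are
continuity-corrected (Yates) 2x2 chi-squares: e.g. 129/288 vs 54/267
endorsements gives 37.83 uncorrected but 36.73 corrected, and 36.73 is what
is printed.  The default here is therefore ``correction="yates"``;
``correction="none"`` gives the uncorrected statistic, which equals the
square of the pooled two-proportion z statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import StratumSpec, SymptomDataset


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float

    @property
    def marker(self) -> str:
        """Footnote marker: ``**`` for p < 0.001, ``*`` for p < 0.05."""
        if self.p_value < 0.001:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def display_percent(count: int, n: int) -> int:
    """Integer percent with half-up rounding (44.79 -> 45, 22.5 -> 23)."""
    pct = Decimal(100 * count) / Decimal(n)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, correction: str = "yates"
) -> TestResult:
    """Chi-square test that two binomial proportions k1/n1 and k2/n2 differ.

    With ``correction="yates"`` the statistic is

        N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d))

    on the 2x2 table a=k1, b=n1-k1, c=k2, d=n2-k2, N=n1+n2, with the
    correction capped so the statistic is never negative.  With
    ``correction="none"`` it is the uncorrected chi-square, identically the
    square of the pooled-variance two-proportion z statistic.  p-values come
    from chi-square with 1 df.  A degenerate table (both proportions 0 or
    both 1) yields statistic 0, p 1, with a warning.
    """
    if correction not in ("yates", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("stratum sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    N = n1 + n2
    if a + c == 0 or b + d == 0:
        warnings.warn("degenerate 2x2 table (zero marginal); statistic set to 0")
        return TestResult(0.0, 1, 1.0)
    diff = abs(a * d - b * c)
    if correction == "yates":
        diff = max(diff - N / 2.0, 0.0)
    stat = N * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return TestResult(float(stat), 1, float(stats.chi2.sf(stat, df=1)))


@dataclass
class FrequencyTable:
    """Counts, percents and (for two strata) the prevalence comparison test.

    ``counts``/``percent`` are DataFrames indexed by symptom acronym with one
    column per stratum label; ``n`` maps stratum label to size.  When built
    from exactly two strata, ``tests`` holds one :class:`TestResult` per
    symptom.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    n: dict[str, int]
    tests: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long display frame: 'count (pct%)' per stratum plus the test."""
        out = pd.DataFrame(index=self.counts.index)
        for col in self.counts.columns:
            out[col] = [
                f"{int(k)} ({display_percent(int(k), self.n[col])}%)"
                for k in self.counts[col]
            ]
        if self.tests is not None:
            out["statistic"] = [f"{t.statistic:.2f}" for t in self.tests]
            out["p_value"] = [f"{t.p_value:.3g}" for t in self.tests]
            out["sig"] = [t.marker for t in self.tests]
        return out

    def to_csv(self, path: str | Path) -> None:
        df = self.counts.add_prefix("count_").join(
            self.percent.add_prefix("percent_")
        )
        if self.tests is not None:
            df["statistic"] = [t.statistic for t in self.tests]
            df["p_value"] = [t.p_value for t in self.tests]
            df["sig"] = [t.marker for t in self.tests]
        df.to_csv(path, index_label="symptom")

    def to_markdown(self) -> str:
        return self.to_frame().to_markdown()


def symptom_frequencies(
    ds: SymptomDataset,
    strata: list[tuple[StratumSpec, SymptomDataset]],
    correction: str = "yates",
) -> FrequencyTable:
    """Endorsement counts and percents per symptom per stratum.

    With exactly two strata, a two-proportion test (default Yates-corrected)
    compares each symptom's prevalence between them.
    """
    if not strata:
        raise ValueError("at least one stratum required")
    acronyms = list(ds.codebook.acronyms)
    counts, percent, sizes = {}, {}, {}
    for spec, sub in strata:
        if sub.n == 0:
            raise ValueError(f"empty stratum {spec.label}: percent undefined")
        k = sub.values.sum(axis=0)
        counts[spec.level] = k
        percent[spec.level] = 100.0 * k / sub.n
        sizes[spec.level] = sub.n
    counts = pd.DataFrame(counts, index=acronyms)
    percent = pd.DataFrame(percent, index=acronyms)
    tests = None
    if len(strata) == 2:
        (s1, _), (s2, _) = strata
        tests = pd.Series(
            [
                two_proportion_test(
                    int(counts.loc[a, s1.level]), sizes[s1.level],
                    int(counts.loc[a, s2.level]), sizes[s2.level],
                    correction=correction,
                )
                for a in acronyms
            ],
            index=acronyms,
        )
    return FrequencyTable(counts, percent, sizes, tests)
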