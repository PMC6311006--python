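"""Chi-square goodness of fit of offspring sex ratios against 1:1.

A cohort of sexed offspring is tested for departure from the 1:1
Mendelian expectation with the two-category Pearson statistic
``sum (O - E)^2 / E`` where ``E = (n_f + n_m) / 2``, on one degree of
freedom.  Ratios are reported as female/male rounded half-up to two
decimals, the usual table format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

from .errors import ValidationError


def _round_half_up_2dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SexRatioResult:
    n_female: int
    n_male: int
    ratio_2dp: float  # female/male, half-up 2 dp; inf when n_male == 0
    chi2_stat: float
    df: int
    p_value: float
    label: str | None = None


def chi_square_1to1(
    n_female: int,
    n_male: int,
    continuity_correction: bool = False,
    label: str | None = None,
) -> SexRatioResult:
    """Test observed female/male counts against the expected 1:1 split.

    ``continuity_correction`` applies Yates' correction
    ``sum (|O - E| - 0.5)^2 / E`` (off by default).
    """
    if n_female < 0 or n_male < 0:
        raise ValidationError("counts must be non-negative")
    n = n_female + n_male
    if n == 0:
        raise ValidationError("at least one offspring required")
    expected = n / 2.0
    dev = abs(n_female - expected)
    if continuity_correction:
        dev = max(dev - 0.5, 0.0)
    chi2 = 2.0 * dev * dev / expected
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    if n_male == 0:
        ratio = math.inf
    else:
        ratio = _round_half_up_2dp(n_female / n_male)
    return SexRatioResult(n_female, n_male, ratio, chi2, 1, p, label)


def ratio_table(
    stage_counts: list[tuple[str, int, int]],
    continuity_correction: bool = False,
) -> list[SexRatioResult]:
    """Per-stage ratio tests plus a pooled ``Total`` row."""
    if not stage_counts:
        raise ValidationError("at least one stage required")
    results = [
        chi_square_1to1(f, m, continuity_correction, label=lab)
        for lab, f, m in stage_counts
    ]
    total_f = sum(f for _, f, _ in stage_counts)
    total_m = sum(m for _, _, m in stage_counts)
    results.append(
        chi_square_1to1(total_f, total_m, continuity_correction, label="Total")
    )
    return results


class SexRatioGoodnessOfFit:
    """1:1 sex-ratio model over one or more offspring cohorts.

    ``fit()`` returns a results object whose ``summary()`` mirrors the
    usual stage table: offspring counts, female/male ratio, chi-square
    statistic and upper-tail p-value per stage plus a pooled total.
    """

    def __init__(
        self,
        stage_counts: list[tuple[str, int, int]],
        continuity_correction: bool = False,
    ) -> None:
        self.stage_counts = list(stage_counts)
        self.continuity_correction = continuity_correction

    def fit(self) -> "SexRatioResults":
        return SexRatioResults(
            self, ratio_table(self.stage_counts, self.continuity_correction)
        )


class SexRatioResults:
    def __init__(self, model: SexRatioGoodnessOfFit, rows: list[SexRatioResult]):
        self.model = model
        self.rows = rows

    @property
    def total(self) -> SexRatioResult:
        return self.rows[-1]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [r.label for r in self.rows],
                "n_offspring": [r.n_female + r.n_male for r in self.rows],
                "n_female": [r.n_female for r in self.rows],
                "n_male": [r.n_male for r in self.rows],
                "sex_ratio": [r.ratio_2dp for r in self.rows],
                "chi2": [r.chi2_stat for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
            }
        )
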