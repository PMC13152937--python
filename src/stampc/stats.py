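"""Supporting statistics: inter-rater agreement, proportion comparison,
Likert summaries.

Cohen's kappa is computed for pairs of binary abstraction vectors (the
three report reviewers yield three pairwise kappas).  The 2x2 chi-square
uses the closed-form statistic n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with an
optional Yates continuity correction; the p-value comes from the chi-square
survival function with 1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .simulate import SurveyDataset


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class KappaResult:
    observed_agreement: float
    expected_agreement: float
    kappa: float
    n_items: int


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: tuple[tuple[float, float], tuple[float, float]]
    corrected: bool


def cohens_kappa(ratings_a, ratings_b) -> KappaResult:
    """Chance-corrected agreement between two binary raters.

    kappa = (po - pe) / (1 - pe) with po the fraction of identical
    judgments and pe the expected agreement from the marginal products.
    The degenerate case po = pe = 1 (both raters constant and identical)
    is reported as kappa 1.
    """
    a = np.asarray(ratings_a).astype(int)
    b = np.asarray(ratings_b).astype(int)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("ratings must be equal-length 1-D vectors")
    if a.size == 0:
        raise StatsError("ratings must be non-empty")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise StatsError("ratings must be binary (0/1)")
    n = a.size
    po = float(np.mean(a == b))
    pa1, pb1 = a.mean(), b.mean()
    pe = float(pa1 * pb1 + (1 - pa1) * (1 - pb1))
    if pe >= 1.0:
        kappa = 1.0 if po == 1.0 else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return KappaResult(po, pe, float(kappa), n)


def pairwise_kappas(raters: dict[str, np.ndarray]) -> dict[tuple[str, str], KappaResult]:
    """All pairwise kappas among named raters (three reviewers -> three pairs)."""
    return {
        (r1, r2): cohens_kappa(raters[r1], raters[r2])
        for r1, r2 in combinations(sorted(raters), 2)
    }


def chi_square_2x2(table, correction: bool = False) -> ChiSquareResult:
    """Chi-square test of independence on a 2x2 count table.

    Uncorrected statistic is the closed form n(ad-bc)^2 over the product of
    the four margins; the Yates version subtracts n/2 from |ad-bc| first
    (floored at 0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError("table must be 2x2")
    if np.any(t < 0):
        raise StatsError("counts must be non-negative")
    (a, b), (c, d) = t
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise StatsError("all four margins must be positive")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    statistic = n * diff**2 / margins
    p = float(chi2_dist.sf(statistic, df=1))
    return ChiSquareResult(
        statistic=float(statistic),
        df=1,
        p_value=p,
        table=((a, b), (c, d)),
        corrected=correction,
    )


def likert_summary(survey: SurveyDataset) -> pd.DataFrame:
    """Per-parameter mean, sample SD (n-1), and n, sorted by mean descending.

    With a single rater the SD is undefined and reported as NaN, not 0.
    """
    ratings = survey.ratings
    if ratings.empty:
        raise StatsError("survey has no ratings")
    n = len(ratings)
    out = pd.DataFrame(
        {
            "mean": ratings.mean(axis=0),
            "sd": ratings.std(axis=0, ddof=1) if n > 1 else np.nan,
            "n": n,
        }
    )
    out.index.name = "parameter"
    return out.sort_values("mean", ascending=False, kind="stable")
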