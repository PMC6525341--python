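"""Resampling category enrichment, BH FDR, and proportion tests.

Given a background of N analyzed families of which K tested positive for
adaptive expansion in a focal regime, a candidate category of n families
with k observed positives is tested by drawing n families from the
background without replacement many times; the raw p-value is the
fraction of draws containing at least k positives.  This is an
unbiased Monte-Carlo estimate of the hypergeometric upper tail
P(X >= k | N, K, n), which :func:`hypergeometric_tail` provides as the
analytic cross-check.  Raw p-values across categories are adjusted with
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BackgroundResults",
    "EnrichmentTable",
    "permutation_enrichment",
    "hypergeometric_tail",
    "bh_adjust",
    "prop_test_2x2",
    "enrichment_table",
]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class BackgroundResults:
    total: int
    positives: int

    def __post_init__(self) -> None:
        if not (0 <= self.positives <= self.total):
            raise EnrichmentError("need 0 <= positives <= total")


@dataclass
class EnrichmentTable:
    frame: pd.DataFrame  # columns: category, n_category, k_observed, p_raw, fdr

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def permutation_enrichment(
    background: BackgroundResults,
    categories: list[tuple[int, int]],
    n_draws: int = 100_000,
    seed: int = 0,
) -> list[float]:
    """Resampling tail probability per category.

    ``categories`` is a list of (n, k_observed) pairs.  For each category,
    draw n families without replacement from the background n_draws times
    and count draws whose number of positives reaches k_observed or more;
    the p-value is that count divided by n_draws (no pseudo-count, so an
    exact zero is possible and is reported as 0).
    """
    if n_draws < 1:
        raise EnrichmentError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for n, k in categories:
        if n > background.total:
            raise EnrichmentError(
                f"category size {n} exceeds background total {background.total}"
            )
        if k > n:
            raise EnrichmentError(f"observed positives {k} exceed category size {n}")
        if k <= 0:
            out.append(1.0)
            continue
        # drawing n items without replacement and counting successes IS a
        # hypergeometric draw; sample the count directly
        draws = rng.hypergeometric(
            background.positives, background.total - background.positives, n, n_draws
        )
        out.append(float(np.count_nonzero(draws >= k)) / n_draws)
    return out


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise EnrichmentError("require 0 <= K <= N and 0 <= n <= N")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    m is the number of tests supplied (all categories tested, including
    those with zero observed positives).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prop_test_2x2(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> tuple[float, float]:
    """Chi-squared test of equal proportions k1/n1 vs k2/n2.

    Yates continuity correction is applied by default (the conventional
    default of the two-sample equality-of-proportions test).  Returns
    (chi2 statistic, two-sided p from chi-squared df=1).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise EnrichmentError("invalid 2x2 counts")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        raise EnrichmentError("degenerate margins in 2x2 table")
    if k1 / n1 == k2 / n2 and not continuity:
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def enrichment_table(
    background: BackgroundResults,
    categories: list[tuple[str, int, int]],
    n_draws: int = 100_000,
    seed: int = 0,
) -> EnrichmentTable:
    """Full per-category enrichment: raw resampling p plus BH FDR."""
    p_raw = permutation_enrichment(
        background, [(n, k) for _, n, k in categories], n_draws=n_draws, seed=seed
    )
    fdr = bh_adjust(p_raw)
    frame = pd.DataFrame(
        {
            "category": [c for c, _, _ in categories],
            "n_category": [n for _, n, _ in categories],
            "k_observed": [k for _, _, k in categories],
            "p_raw": p_raw,
            "fdr": fdr,
        }
    )
    return EnrichmentTable(frame)
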