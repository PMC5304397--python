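"""Contingency-table and rank statistics for duplicate-gene enrichment.

The 2×2 chi-square and Mann–Whitney U statistics are computed from their
definitions (p-values come from the reference χ² and normal distributions);
``de_enrichment`` wraps them into the standard harness asking whether a set
of differentially expressed (DE) genes over-represents a gene category
(multigene families, tandem arrays, lineage-expanded families, …) relative
to the rest of the genome.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "chi2_2x2",
    "mannwhitney_u",
    "de_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b | c, d): rows = group 1/2, columns = trait +/−."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for x in (self.a, self.b, self.c, self.d):
            if x < 0:
                raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> tuple[float, float, float, float]:
        r1, r2, c1, c2 = self.marginals
        n = self.total
        return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    df: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def chi2_2x2(table: ContingencyTable2x2, continuity: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2×2 table,
    N(ad − bc)²/[(a+b)(c+d)(a+c)(b+d)], df = 1.

    No continuity correction by default; ``continuity=True`` applies the
    Yates correction |ad − bc| → max(0, |ad − bc| − N/2).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.marginals
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a marginal total is zero")
    n = table.total
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(stat, 1))
    return TestResult(statistic=float(stat), p=p, df=1, method="pearson-chi2")


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Two-sided exact p by enumeration of group assignments of the pooled
    sample (valid with ties; feasible for small samples)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))
    ranks = stats.rankdata(pooled)
    total = 0
    extreme = 0
    mu = n1 * len(y) / 2.0
    for comb in itertools.combinations(idx, n1):
        r1 = ranks[list(comb)].sum()
        u_perm = r1 - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u_perm - mu) >= abs(u - mu) - 1e-12:
            extreme += 1
    return extreme / total


def mannwhitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 8,
) -> TestResult:
    """Two-tailed Mann–Whitney U test.

    Reports U for the first sample (rank-sum form).  Small samples
    (min(n) ≤ ``exact_max_n``, and few enough assignments to enumerate) use
    the exact permutation distribution; otherwise the normal approximation
    with tie correction and 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if min(n1, n2) <= exact_max_n and math.comb(n1 + n2, n1) <= 50_000:
        p = _exact_mwu_p(x, y, u1)
        return TestResult(statistic=float(u1), p=float(p), method="mwu-exact")
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return TestResult(statistic=float(u1), p=1.0, method="mwu-normal")
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * float(stats.norm.sf(z))
    return TestResult(statistic=float(u1), p=min(p, 1.0), method="mwu-normal")


def de_enrichment(
    de_genes: Iterable[str],
    category_members: Mapping[str, Iterable[str]],
    genome_genes: Iterable[str],
    overlapping: bool = False,
) -> list[tuple[str, ContingencyTable2x2, TestResult]]:
    """Chi-square enrichment of each gene category in the DE set.

    Default table convention compares the DE set against the *rest* of the
    genome: a = |DE ∩ cat|, b = |DE \\ cat|, c = |cat \\ DE|,
    d = |genome \\ (DE ∪ cat)|.  With ``overlapping=True`` the second row is
    the whole genome including the DE genes (sensitivity variant).
    """
    genome = set(genome_genes)
    de = set(de_genes) & genome
    if not de:
        raise ValueError("DE set is empty or disjoint from the genome set")
    results = []
    for name in sorted(category_members):
        cat = set(category_members[name]) & genome
        a = len(de & cat)
        b = len(de - cat)
        if overlapping:
            c = len(cat)
            d = len(genome) - len(cat)
        else:
            c = len(cat - de)
            d = len(genome - de - cat)
        table = ContingencyTable2x2(a=a, b=b, c=c, d=d)
        results.append((name, table, chi2_2x2(table)))
    return results
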