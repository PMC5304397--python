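"""Differential-expression filter chain and qPCR quantification.

The chain is: drop the lowest 40% of genes by mean normalised expression,
test each remaining gene for a condition difference, control the false
discovery rate at 10% with Benjamini–Hochberg, and require at least a
1.5-fold change.  The per-gene test supplied here is a deliberately simple
negative-binomial Wald test (method-of-moments dispersion, median-of-ratios
size factors); externally computed (p, log2FC) tables can be fed straight
into :func:`bh_fdr` / :func:`de_call` when a full NB-GLM fit is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DECall",
    "size_factors",
    "quantile_filter",
    "nb_mm_test",
    "bh_fdr",
    "de_call",
    "delta_ct",
]


@dataclass(frozen=True)
class DECall:
    gene: str
    log2_fc: float
    p: float
    q: float
    is_de: bool


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors per sample.

    The reference is the per-gene geometric mean across samples (genes with
    any zero count are excluded from the reference, as usual).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logmat = np.log(mat[positive])
    ref = logmat.mean(axis=1)
    sf = np.exp(np.median(logmat - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def quantile_filter(
    counts: pd.DataFrame,
    fraction: float = 0.40,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Drop the ``fraction`` of genes with the lowest mean normalised count
    across all samples (ties broken by gene id, so the cut is deterministic)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.div(factors, axis=1)
    means = norm.mean(axis=1)
    order = sorted(counts.index, key=lambda g: (means[g], g))
    n_drop = int(np.floor(fraction * len(order)))
    keep = set(order[n_drop:])
    return counts.loc[[g for g in counts.index if g in keep]]


def nb_mm_test(
    counts: pd.DataFrame,
    condition: Mapping[str, str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene two-condition test on negative-binomial counts.

    Normalised means are compared on the log scale with a Wald statistic.
    The NB dispersion is a *common-scale* method-of-moments estimate: each
    gene contributes (pooled within-condition variance − mean)/mean², and
    the common dispersion is the median of those per-gene moments (floored
    at zero, i.e. Poisson).  Sharing one dispersion across genes removes the
    crippling noise of 4-df per-gene variance estimates at typical
    replicate numbers; the statistic is referred to a t distribution with
    n₁+n₂−2 degrees of freedom, whose heavier tails absorb the residual
    small-sample skew of few-replicate NB means.

    Returns a DataFrame indexed by gene with columns log2_fc and p, where
    positive log2_fc means higher expression in the second condition
    (condition labels sorted lexicographically).
    """
    levels = sorted(set(condition.values()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    groups = {
        lvl: [s for s in counts.columns if condition[s] == lvl] for lvl in levels
    }
    for lvl, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"condition {lvl!r} needs ≥ 2 replicates")
    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    x = norm[groups[levels[0]]].to_numpy(dtype=float)
    y = norm[groups[levels[1]]].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    # common-scale method-of-moments dispersion (median over genes)
    pooled_mean = (n1 * m1 + n2 * m2) / (n1 + n2)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    expressed = pooled_mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        per_gene = (pooled_var - pooled_mean) / pooled_mean**2
    disp = float(np.clip(np.median(per_gene[expressed]), 0.0, None))
    mu1 = m1 + pseudocount
    mu2 = m2 + pseudocount
    log2_fc = np.log2(mu2) - np.log2(mu1)
    # delta-method variance of log mean under NB sampling of each replicate
    var_log1 = (mu1 + disp * mu1**2) / (n1 * mu1**2)
    var_log2 = (mu2 + disp * mu2**2) / (n2 * mu2**2)
    se = np.sqrt(var_log1 + var_log2)
    wald = np.log(mu2 / mu1) / se
    p = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"log2_fc": log2_fc, "p": p}, index=counts.index)


def bh_fdr(pvals: Sequence[float], q: float = 0.10) -> pd.DataFrame:
    """Benjamini–Hochberg step-up FDR control.

    Adjusted value for the i-th smallest p is min over j ≥ i of p_(j)·n/j;
    ``reject`` flags adjusted values ≤ ``q``.  Index order of the input is
    preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return pd.DataFrame({"p": p, "q": adj, "reject": adj <= q})


def de_call(
    results: pd.DataFrame,
    min_fc: float = 1.5,
    fdr: float = 0.10,
) -> list[DECall]:
    """Final DE calls: BH-adjusted q ≤ ``fdr`` AND linear fold change ≥
    ``min_fc`` in either direction (|log2FC| ≥ log2 min_fc)."""
    adj = bh_fdr(results["p"].to_numpy(), q=fdr)
    min_l2 = np.log2(min_fc)
    calls = []
    for gene, q, rej, l2 in zip(
        results.index, adj["q"], adj["reject"], results["log2_fc"]
    ):
        is_de = bool(rej) and abs(l2) >= min_l2
        calls.append(
            DECall(gene=gene, log2_fc=float(l2), p=float(results.loc[gene, "p"]),
                   q=float(q), is_de=is_de)
        )
    return calls


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Relative qPCR expression by the comparative 2^−ΔCt method, with the
    target normalised to a reference gene from the same sample."""
    return float(2.0 ** (-(ct_target - ct_reference)))
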