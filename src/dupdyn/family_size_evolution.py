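"""Birth–death modelling of gene-family size along a species timetree.

Each gene copy independently duplicates and is lost at the same per-copy
rate λ (per relative-time unit).  Under this linear birth–death process the
size transition probability along a branch of length t has the closed form
(with α = λt/(1 + λt)):

    P(c | s, t) = Σ_{j=0}^{min(s,c)} C(s, j) C(s+c−j−1, s−1)
                  α^{s+c−2j} (1−2α)^{j},        P(c | 0, t) = δ_{c0}.

Family likelihoods are computed by pruning over a truncated size-state
space, λ is fitted by maximum likelihood (per rate-class partitions of the
branches give nested models compared by likelihood-ratio tests), and
ancestral family sizes are reconstructed by a max-product dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "BirthDeathModel",
    "FitResult",
    "branch_id",
    "parsimony_root_presence",
    "filter_copy_range",
    "bd_transition_prob",
    "transition_matrix",
    "family_loglik",
    "fit_lambda",
    "lrt_nested",
    "ancestral_sizes",
    "binomial_expansion_test",
    "normalize_expansion",
    "percent_increase",
]

DEFAULT_CLASS = "global"


def branch_id(node: dendropy.Node) -> frozenset:
    """A branch is identified by the set of leaf labels below it."""
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


@dataclass
class BirthDeathModel:
    """Branch partition into rate classes plus one λ (= gain = loss rate,
    per gene per relative-time unit) per class."""

    partition: Mapping[frozenset, str] = field(default_factory=dict)
    lam: Mapping[str, float] = field(default_factory=lambda: {DEFAULT_CLASS: 0.01})

    def rate_class(self, node: dendropy.Node) -> str:
        return self.partition.get(branch_id(node), DEFAULT_CLASS)

    def rate(self, node: dendropy.Node) -> float:
        cls = self.rate_class(node)
        if cls not in self.lam:
            raise KeyError(f"no λ for rate class {cls!r}")
        lam = self.lam[cls]
        if lam < 0 or not np.isfinite(lam):
            raise ValueError(f"invalid λ {lam} for class {cls!r}")
        return lam

    @property
    def n_params(self) -> int:
        return len(self.lam)


@dataclass
class FitResult:
    model: BirthDeathModel
    loglik: float
    per_family_loglik: pd.Series
    converged: bool


# ---------------------------------------------------------------------------
# Pre-likelihood family filters

def parsimony_root_presence(matrix: pd.DataFrame, tree: dendropy.Tree) -> pd.DataFrame:
    """Retain families inferred present at the root by Fitch small parsimony
    on presence/absence (ties at the root resolve to present)."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    missing = set(labels) - set(matrix.columns)
    if missing:
        raise KeyError(f"tree leaves absent from matrix: {sorted(missing)}")
    presence = matrix[labels].to_numpy() > 0  # (n_fam, n_leaves)
    n_fam = presence.shape[0]
    # state sets encoded as 2-bit masks: bit0 = absent, bit1 = present
    states: dict[int, np.ndarray] = {}
    for i, lf in enumerate(leaves):
        states[id(lf)] = np.where(presence[:, i], 2, 1)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        masks = [states[id(ch)] for ch in node.child_nodes()]
        inter = masks[0].copy()
        union = masks[0].copy()
        for m in masks[1:]:
            inter &= m
            union |= m
        states[id(node)] = np.where(inter > 0, inter, union)
    root = states[id(tree.seed_node)]
    keep = (root & 2) > 0  # present in the root state set (ties -> present)
    return matrix.loc[keep]


def filter_copy_range(matrix: pd.DataFrame, max_range: int = 200) -> pd.DataFrame:
    """Drop families whose copy number varies across species by more than
    ``max_range`` genes (strict >)."""
    rng = matrix.max(axis=1) - matrix.min(axis=1)
    return matrix.loc[rng <= max_range]


# ---------------------------------------------------------------------------
# Transition probabilities

def transition_matrix(lam: float, t: float, s_max: int) -> np.ndarray:
    """(s_max+1)×(s_max+1) matrix of P(child = c | parent = s) over a branch
    of length ``t`` at rate ``lam``; rows index the parent state."""
    if lam < 0 or t < 0:
        raise ValueError("λ and t must be non-negative")
    n = s_max + 1
    if lam * t == 0:
        return np.eye(n)
    alpha = lam * t / (1.0 + lam * t)
    beta = 1.0 - 2.0 * alpha
    s = np.arange(n)[:, None]
    c = np.arange(n)[None, :]
    P = np.zeros((n, n))
    for j in range(n):
        with np.errstate(invalid="ignore"):
            term = (
                special.comb(s, j)
                * special.comb(s + c - j - 1, s - 1)
                * alpha ** (s + c - 2 * j)
                * beta ** j
            )
        valid = (j <= np.minimum(s, c)) & (s >= 1)
        P += np.where(valid, np.nan_to_num(term), 0.0)
    P[0, :] = 0.0
    P[0, 0] = 1.0  # extinction is absorbing
    np.clip(P, 0.0, 1.0, out=P)
    return P


def bd_transition_prob(n_parent: int, n_child: int, t: float, lam: float) -> float:
    """P(family size ``n_child`` | size ``n_parent``, branch length ``t``, rate λ)."""
    if n_parent < 0 or n_child < 0:
        raise ValueError("sizes must be non-negative")
    s_max = max(n_parent, n_child)
    return float(transition_matrix(lam, t, s_max)[n_parent, n_child])


# ---------------------------------------------------------------------------
# Pruning likelihood

def _branch_matrices(
    tree: dendropy.Tree, model: BirthDeathModel, s_max: int
) -> dict[int, np.ndarray]:
    mats = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        mats[id(node)] = transition_matrix(model.rate(node), t, s_max)
    return mats


def _partials(
    counts: np.ndarray,
    leaf_order: Sequence[dendropy.Node],
    tree: dendropy.Tree,
    mats: dict[int, np.ndarray],
    s_max: int,
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Scaled pruning pass.  Returns (root partials, per-family log scale,
    all node partials)."""
    n_fam = counts.shape[0]
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_fam)
    leaf_idx = {id(lf): i for i, lf in enumerate(leaf_order)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            L = np.zeros((n_fam, s_max + 1))
            obs = counts[:, leaf_idx[id(node)]]
            L[np.arange(n_fam), obs] = 1.0
        else:
            L = np.ones((n_fam, s_max + 1))
            for child in node.child_nodes():
                L *= partial[id(child)] @ mats[id(child)].T
            mx = L.max(axis=1)
            mx[mx == 0.0] = 1.0
            L /= mx[:, None]
            logscale += np.log(mx)
        partial[id(node)] = L
    return partial[id(tree.seed_node)], logscale, partial


def family_loglik(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    model: BirthDeathModel,
    root_max: int | None = None,
    s_buffer: int = 10,
) -> pd.Series:
    """Per-family log-likelihood by pruning over size states 0..S_max.

    The root prior is uniform on sizes 1..``root_max`` (conditioning on
    presence at the root, matching the root-presence parsimony filter);
    S_max = max observed count + ``s_buffer``.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    counts = matrix[labels].to_numpy(dtype=int)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("family with all-zero counts; run the root filter first")
    obs_max = int(counts.max())
    s_max = obs_max + s_buffer
    if root_max is None:
        root_max = max(obs_max, 1)
    mats = _branch_matrices(tree, model, s_max)
    root_partial, logscale, _ = _partials(counts, leaves, tree, mats, s_max)
    prior = np.zeros(s_max + 1)
    prior[1 : root_max + 1] = 1.0 / root_max
    lik = root_partial @ prior
    with np.errstate(divide="ignore"):
        ll = np.log(lik) + logscale
    return pd.Series(ll, index=matrix.index, name="loglik")


# ---------------------------------------------------------------------------
# Maximum-likelihood rate fitting

LAM_BOUNDS = (1e-6, 10.0)


def fit_lambda(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    partition: Mapping[frozenset, str] | None = None,
    seed: int = 0,
    n_random_starts: int = 2,
    root_max: int | None = None,
    s_buffer: int = 10,
) -> FitResult:
    """Fit one λ per rate class by bounded maximum likelihood.

    Optimises log λ with L-BFGS-B from a fixed ladder of deterministic
    starting points plus ``n_random_starts`` seeded random ones; the best
    optimum wins, so the fit is reproducible for a given seed.
    """
    partition = dict(partition or {})
    # classes not covering any branch would be unidentifiable; keep only used ones
    used = set(partition.values())
    has_default = any(
        branch_id(nd) not in partition
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node
    )
    classes = sorted(used | ({DEFAULT_CLASS} if has_default else set()))

    def neg_loglik(log_lams: np.ndarray) -> float:
        lam = {cls: float(np.exp(v)) for cls, v in zip(classes, log_lams)}
        model = BirthDeathModel(partition=partition, lam=lam)
        ll = family_loglik(matrix, tree, model, root_max=root_max, s_buffer=s_buffer)
        total = ll.sum()
        if not np.isfinite(total):
            return 1e12
        return -float(total)

    rng = np.random.default_rng(seed)
    starts = [np.full(len(classes), np.log(v)) for v in (0.001, 0.01, 0.1)]
    for _ in range(n_random_starts):
        starts.append(rng.uniform(np.log(1e-4), np.log(1.0), size=len(classes)))
    bounds = [(np.log(LAM_BOUNDS[0]), np.log(LAM_BOUNDS[1]))] * len(classes)
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    lam = {cls: float(np.exp(v)) for cls, v in zip(classes, best.x)}
    model = BirthDeathModel(partition=partition, lam=lam)
    per_family = family_loglik(matrix, tree, model, root_max=root_max, s_buffer=s_buffer)
    return FitResult(
        model=model,
        loglik=float(per_family.sum()),
        per_family_loglik=per_family,
        converged=bool(best.success),
    )


def lrt_nested(fit_simple: FitResult, fit_complex: FitResult) -> dict:
    """Likelihood-ratio test between nested birth–death models:
    statistic 2ΔlogL, df = Δ(number of λ parameters), χ² p-value."""
    df = fit_complex.model.n_params - fit_simple.model.n_params
    if df <= 0:
        raise ValueError("complex model must have more rate classes")
    stat = max(0.0, 2.0 * (fit_complex.loglik - fit_simple.loglik))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return {"statistic": stat, "df": df, "p": p}


# ---------------------------------------------------------------------------
# Ancestral reconstruction

def ancestral_sizes(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    model: BirthDeathModel,
    root_max: int | None = None,
    s_buffer: int = 10,
) -> dict:
    """ML ancestral family sizes by a max-product (Viterbi-style) dynamic
    program over size states; per-branch change = child − parent.

    Returns {"sizes": DataFrame families × node ids, "changes": DataFrame
    families × branch ids, "expansions"/"contractions": per-branch counts}.
    Internal nodes are labelled by their branch id (sorted leaf labels joined
    with ``|``).
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    counts = matrix[labels].to_numpy(dtype=int)
    n_fam = counts.shape[0]
    obs_max = int(counts.max())
    s_max = obs_max + s_buffer
    if root_max is None:
        root_max = max(obs_max, 1)
    mats = _branch_matrices(tree, model, s_max)
    with np.errstate(divide="ignore"):
        logmats = {k: np.log(v) for k, v in mats.items()}

    leaf_idx = {id(lf): i for i, lf in enumerate(leaves)}
    up: dict[int, np.ndarray] = {}
    back: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            U = np.full((n_fam, s_max + 1), -np.inf)
            U[np.arange(n_fam), counts[:, leaf_idx[id(node)]]] = 0.0
        else:
            U = np.zeros((n_fam, s_max + 1))
            for child in node.child_nodes():
                logT = logmats[id(child)]
                W = up[id(child)]  # (n_fam, S+1)
                scores = np.full((n_fam, s_max + 1), -np.inf)
                argmax = np.zeros((n_fam, s_max + 1), dtype=int)
                for s in range(s_max + 1):
                    sc = logT[s][None, :] + W  # (n_fam, S+1)
                    argmax[:, s] = np.argmax(sc, axis=1)
                    scores[:, s] = sc[np.arange(n_fam), argmax[:, s]]
                back[id(child)] = argmax
                U = U + scores
        up[id(node)] = U

    root = tree.seed_node
    root_scores = up[id(root)].copy()
    root_scores[:, 0] = -np.inf
    root_scores[:, root_max + 1 :] = -np.inf  # uniform prior on 1..root_max
    assign: dict[int, np.ndarray] = {id(root): np.argmax(root_scores, axis=1)}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_states = assign[id(node.parent_node)]
        assign[id(node)] = back[id(node)][np.arange(n_fam), parent_states]

    def node_label(node):
        if node.is_leaf():
            return node.taxon.label
        return "|".join(sorted(branch_id(node)))

    sizes = pd.DataFrame(
        {node_label(nd): assign[id(nd)] for nd in tree.preorder_node_iter()},
        index=matrix.index,
    )
    changes = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        changes[node_label(node)] = assign[id(node)] - assign[id(node.parent_node)]
    changes = pd.DataFrame(changes, index=matrix.index)
    return {
        "sizes": sizes,
        "changes": changes,
        "expansions": (changes > 0).sum(axis=0),
        "contractions": (changes < 0).sum(axis=0),
    }


# ---------------------------------------------------------------------------
# Expansion comparisons and normalisation

def binomial_expansion_test(n_a: int, n_b: int) -> float:
    """Two-sided exact binomial test of ``n_a`` successes in ``n_a + n_b``
    trials at p = 0.5 (family expanded in lineage a vs lineage b)."""
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    n = n_a + n_b
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_a, n, 0.5).pvalue)


def normalize_expansion(
    per_taxon_counts: Mapping[str, float], tree: dendropy.Tree
) -> dict[str, float]:
    """Divide each taxon's expansion count by its terminal branch length
    (relative divergence time from its first ancestor), making counts
    comparable across unequally diverged taxa."""
    out = {}
    for taxon, count in per_taxon_counts.items():
        leaf = tree.find_node_with_taxon_label(taxon)
        if leaf is None:
            raise KeyError(f"taxon {taxon!r} not in tree")
        t = leaf.edge.length
        if not t or t <= 0:
            raise ValueError(f"taxon {taxon!r} has zero-length terminal branch")
        out[taxon] = count / t
    return out


def percent_increase(value: float, baseline: float) -> float:
    """Percentage increase of ``value`` over ``baseline`` (e.g. mean family
    size in one lineage relative to its sister)."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (value - baseline) / baseline
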