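"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analyses assume:

* gene-family sizes evolve by an exact Gillespie simulation of the linear
  birth–death process (λ = μ) along a species timetree;
* coding sequences evolve by single-nucleotide substitution proposals at a
  tunable per-site intensity, with nonsynonymous proposals accepted with
  probability ω and stop codons rejected, so realised dS grows with
  divergence time and realised dN/dS tracks ω;
* gene genealogies within families record every duplication and speciation
  split explicitly, making "duplicated before/after speciation" exact truth;
* similarity hits are computed from the simulated proteins with the
  package's own global aligner (an edit-distance prescreen skips clearly
  unrelated pairs) and carry a documented E-value surrogate;
* expression count matrices are negative-binomial with per-sample size
  factors, a planted DE set with controlled fold change, and DE membership
  enriched in designated gene categories.

All randomness flows from one ``numpy.random.Generator``; the same seed
reproduces every output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .codon_evolution import align_protein_pair, alignment_score
from .family_size_evolution import BirthDeathModel
from .io_formats import (
    CODON_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    CodingRecord,
    GeneFamily,
    GenePosition,
    ProteinRecord,
    SimilarityHit,
    translate_cds,
)

__all__ = [
    "simulate_family_sizes",
    "simulate_codon_pair",
    "evolve_cds",
    "random_cds",
    "TwoSpeciesConfig",
    "TwoSpeciesWorld",
    "simulate_two_species_world",
    "simulate_hits",
    "simulate_positions",
    "simulate_counts",
]

NUCLEOTIDES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Family sizes: exact Gillespie birth–death

def _gillespie_branch(n0: int, t: float, lam: float, rng: np.random.Generator) -> int:
    """Evolve a copy number for time ``t`` under birth rate λn and death
    rate λn (equal gain and loss per copy)."""
    n = n0
    clock = 0.0
    while n > 0:
        total = 2.0 * lam * n
        if total <= 0:
            break
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            break
        n += 1 if rng.random() < 0.5 else -1
    return n


def simulate_family_sizes(
    tree,
    n_families: int,
    model: BirthDeathModel,
    seed: int,
    root_size_mean: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate family sizes down a species tree.

    Root sizes are 1 + Poisson(root_size_mean − 1) (conditioned ≥ 1, as the
    root-presence filter assumes).  Returns (tip-count matrix, truth matrix
    of sizes at every node; internal nodes labelled by sorted leaf sets).
    """
    rng = np.random.default_rng(seed)
    nodes = list(tree.preorder_node_iter())

    def label(node):
        if node.is_leaf():
            return node.taxon.label
        return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))

    sizes: dict[int, np.ndarray] = {}
    root = tree.seed_node
    sizes[id(root)] = 1 + rng.poisson(max(root_size_mean - 1.0, 0.0), size=n_families)
    for node in nodes:
        if node is root:
            continue
        lam = model.rate(node)
        t = node.edge.length or 0.0
        parent = sizes[id(node.parent_node)]
        sizes[id(node)] = np.array(
            [_gillespie_branch(int(n0), t, lam, rng) for n0 in parent]
        )
    index = [f"F{i + 1:06d}" for i in range(n_families)]
    truth = pd.DataFrame({label(nd): sizes[id(nd)] for nd in nodes}, index=index)
    tips = truth[[lf.taxon.label for lf in tree.leaf_node_iter()]]
    return tips.copy(), truth


# ---------------------------------------------------------------------------
# Sequence evolution

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random coding sequence of sense codons (no stop)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def evolve_cds(
    cds: str,
    t: float,
    subst_rate: float,
    omega: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a CDS for time ``t``: substitution proposals arrive at
    ``subst_rate`` per nucleotide site per time unit; synonymous proposals
    always fix, nonsynonymous fix with probability ω, stops never."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n_sites = 3 * len(codons)
    n_prop = rng.poisson(subst_rate * n_sites * t)
    for _ in range(n_prop):
        site = int(rng.integers(0, n_sites))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        cur = codon[pos]
        alt = NUCLEOTIDES[NUCLEOTIDES != cur][int(rng.integers(0, 3))]
        new = codon[:pos] + alt + codon[pos + 1 :]
        if new in STOP_CODONS:
            continue
        if CODON_TABLE[new] != CODON_TABLE[codon] and rng.random() >= omega:
            continue
        codons[ci] = new
    return "".join(codons)


def simulate_codon_pair(
    n_codons: int,
    t: float,
    subst_rate: float,
    omega: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Two coding sequences that diverged ``t`` time units ago (each lineage
    evolves independently for t/2)."""
    root = random_cds(n_codons, rng)
    a = evolve_cds(root, t / 2.0, subst_rate, omega, rng)
    b = evolve_cds(root, t / 2.0, subst_rate, omega, rng)
    return a, b


# ---------------------------------------------------------------------------
# Two-species worlds with explicit gene genealogies

@dataclass(frozen=True)
class TwoSpeciesConfig:
    """Study conditions for a simulated pair of sister genomes.

    Times are relative units with the speciation ``t_speciation`` ago; the
    shared ancestral (stem) lineage extends ``t_stem`` further back.
    Duplication and loss rates are per gene per time unit; the loss-rate
    asymmetry between the two descendant lineages is the planted signal the
    streamlining analysis must recover.
    """

    species_a: str = "SPA"
    species_b: str = "SPB"
    n_families: int = 200
    t_stem: float = 1.0
    t_speciation: float = 1.0
    dup_rate_stem: float = 0.8
    dup_rate_tip: float = 0.15
    loss_rate_a: float = 0.9
    loss_rate_b: float = 0.45
    n_codons: int = 180
    subst_rate: float = 0.12
    omega: float = 0.2


@dataclass
class TwoSpeciesWorld:
    config: TwoSpeciesConfig
    proteins: list[ProteinRecord]
    coding: dict[str, CodingRecord]
    true_families: list[GeneFamily]
    pair_truth: pd.DataFrame  # gene_a, gene_b, species_a, species_b, divergence, pre_speciation


@dataclass
class _Gene:
    node: int
    cds: str
    t_last: float = 0.0  # absolute time the sequence was last brought up to


def _evolve_gene_set(
    genes: list[_Gene],
    t: float,
    dup_rate: float,
    loss_rate: float,
    cfg: TwoSpeciesConfig,
    rng: np.random.Generator,
    genealogy: dict[int, tuple[int | None, float]],
    next_node: list[int],
    t_abs: float,
) -> list[_Gene]:
    """Gillespie duplication/loss on a set of gene lineages over a branch.

    Sequence evolution is applied lazily (each lineage carries the absolute
    time its sequence was last advanced to), which is statistically
    identical because substitutions accrue independently per lineage.
    ``genealogy`` maps gene-tree node -> (parent node, absolute split time).
    """
    clock = 0.0
    genes = list(genes)
    while genes:
        total = (dup_rate + loss_rate) * len(genes)
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        if clock + dt >= t:
            break
        clock += dt
        k = int(rng.integers(0, len(genes)))
        if rng.random() < dup_rate / (dup_rate + loss_rate):
            parent = genes[k]
            now = t_abs + clock
            cds = evolve_cds(
                parent.cds, now - parent.t_last, cfg.subst_rate, cfg.omega, rng
            )
            children = []
            for _ in range(2):
                node = next_node[0]
                next_node[0] += 1
                genealogy[node] = (parent.node, now)
                children.append(_Gene(node=node, cds=cds, t_last=now))
            genes[k : k + 1] = children
        else:
            del genes[k]
    end = t_abs + t
    for g in genes:
        g.cds = evolve_cds(g.cds, end - g.t_last, cfg.subst_rate, cfg.omega, rng)
        g.t_last = end
    return genes


def _split_time(node_a: int, node_b: int, genealogy) -> float:
    """Absolute time at which two extant gene lineages diverged.

    Every split event (duplication or speciation) replaces a parent node by
    two children created at the event time, so the divergence time of two
    genes is the creation time of the LCA's child on either path.
    """
    ancestors_a = set()
    n = node_a
    while n is not None:
        ancestors_a.add(n)
        n = genealogy[n][0]
    n = node_b
    child_time = None
    while n is not None:
        if n in ancestors_a:
            if child_time is None:
                raise ValueError("one gene is an ancestor of the other")
            return child_time
        child_time = genealogy[n][1]
        n = genealogy[n][0]
    raise ValueError("gene lineages share no ancestor")


def simulate_two_species_world(config: TwoSpeciesConfig, seed: int) -> TwoSpeciesWorld:
    """Simulate families, genealogies and coding sequences for two sister
    genomes; returns sequences plus exact pair-level truth."""
    cfg = config
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    coding: dict[str, CodingRecord] = {}
    families: list[GeneFamily] = []
    truth_rows = []
    for fam_i in range(cfg.n_families):
        genealogy: dict[int, tuple[int | None, float]] = {0: (None, 0.0)}
        next_node = [1]
        root_gene = _Gene(node=0, cds=random_cds(cfg.n_codons, rng))
        # ancestral (stem) lineage: duplications here predate speciation
        stem = _evolve_gene_set(
            [root_gene], cfg.t_stem, cfg.dup_rate_stem, 0.0,
            cfg, rng, genealogy, next_node, t_abs=0.0,
        )
        if not stem:
            continue
        t_spec = cfg.t_stem
        tips: dict[str, list[_Gene]] = {}
        for species, loss in (
            (cfg.species_a, cfg.loss_rate_a),
            (cfg.species_b, cfg.loss_rate_b),
        ):
            branch_genes = []
            for g in stem:
                node = next_node[0]
                next_node[0] += 1
                genealogy[node] = (g.node, t_spec)
                branch_genes.append(_Gene(node=node, cds=g.cds, t_last=t_spec))
            tips[species] = _evolve_gene_set(
                branch_genes, cfg.t_speciation, cfg.dup_rate_tip, loss,
                cfg, rng, genealogy, next_node, t_abs=t_spec,
            )
        members = []
        extant = []
        for species in (cfg.species_a, cfg.species_b):
            for i, g in enumerate(tips[species]):
                gid = f"{species}|fam{fam_i:03d}_g{i:02d}"
                cds = g.cds
                coding[gid] = CodingRecord(gene_id=gid, cds=cds)
                proteins.append(
                    ProteinRecord(
                        gene_id=gid, species=species, sequence=translate_cds(cds)
                    )
                )
                members.append((species, gid))
                extant.append((species, gid, g.node))
        if members:
            families.append(
                GeneFamily(family_id=f"T{fam_i:04d}", members=frozenset(members))
            )
        t_now = cfg.t_stem + cfg.t_speciation
        for i in range(len(extant)):
            for j in range(i + 1, len(extant)):
                sp_i, gid_i, node_i = extant[i]
                sp_j, gid_j, node_j = extant[j]
                t_split = _split_time(node_i, node_j, genealogy)
                truth_rows.append(
                    {
                        "gene_a": min(gid_i, gid_j),
                        "gene_b": max(gid_i, gid_j),
                        "species_a": sp_i if gid_i < gid_j else sp_j,
                        "species_b": sp_j if gid_i < gid_j else sp_i,
                        "divergence": t_now - t_split,
                        "pre_speciation": t_split < t_spec,
                    }
                )
    pair_truth = pd.DataFrame(
        truth_rows,
        columns=["gene_a", "gene_b", "species_a", "species_b",
                 "divergence", "pre_speciation"],
    )
    return TwoSpeciesWorld(
        config=cfg,
        proteins=proteins,
        coding=coding,
        true_families=families,
        pair_truth=pair_truth,
    )


# ---------------------------------------------------------------------------
# Similarity hits

# affine parameters mirror the aligner defaults in codon_evolution
_BIT_SLOPE = 0.385   # bits per raw BLOSUM62 score unit
_BIT_OFFSET = 4.6


def _surrogate_evalue(score: float, len_a: int, len_b: int) -> tuple[float, float]:
    bits = max(_BIT_SLOPE * score + _BIT_OFFSET, 0.0)
    evalue = len_a * len_b * 2.0 ** (-bits)
    return bits, evalue


def simulate_hits(
    proteins: Sequence[ProteinRecord],
    prescreen_identity: float = 0.25,
    max_report_evalue: float = 1e-3,
) -> list[SimilarityHit]:
    """All-against-all similarity hits from simulated proteins.

    Pairs are prescreened with an edit-distance bound (pairs below
    ``prescreen_identity`` approximate identity are skipped — unrelated
    random proteins never reach reportable E-values); surviving pairs are
    globally aligned and reported in both directions with a Karlin–Altschul
    style E-value surrogate E = m·n·2^(−bits), bits = 0.385·score + 4.6.
    Deterministic for a fixed protein list.
    """
    hits: list[SimilarityHit] = []
    recs = list(proteins)
    for rec in recs:
        bits, evalue = _surrogate_evalue(
            alignment_score(rec.sequence, rec.sequence), len(rec), len(rec)
        )
        hits.append(
            SimilarityHit(
                query=rec.gene_id, subject=rec.gene_id, pct_identity=100.0,
                aln_length=len(rec), mismatch=0, gapopen=0,
                qstart=1, qend=len(rec), sstart=1, send=len(rec),
                evalue=evalue, bitscore=bits,
            )
        )
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            d = edlib.align(a.sequence, b.sequence, task="distance")["editDistance"]
            longest = max(len(a), len(b))
            if 1.0 - d / longest < prescreen_identity:
                continue
            aln = align_protein_pair(a.gene_id, a.sequence, b.gene_id, b.sequence)
            bits, evalue = _surrogate_evalue(aln.score, len(a), len(b))
            if evalue > max_report_evalue:
                continue
            cols = aln.aligned_columns
            ident = aln.identity
            mismatch = round(cols * (1.0 - ident / 100.0))
            gapopen = sum(
                1
                for k in range(len(aln.aligned_a))
                if (aln.aligned_a[k] == "-" and (k == 0 or aln.aligned_a[k - 1] != "-"))
                or (aln.aligned_b[k] == "-" and (k == 0 or aln.aligned_b[k - 1] != "-"))
            )
            for q, s in ((a, b), (b, a)):
                hits.append(
                    SimilarityHit(
                        query=q.gene_id, subject=s.gene_id,
                        pct_identity=round(ident, 2),
                        aln_length=len(aln.aligned_a), mismatch=mismatch,
                        gapopen=gapopen, qstart=1, qend=len(q),
                        sstart=1, send=len(s), evalue=evalue, bitscore=bits,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Gene positions with planted tandem arrays

def simulate_positions(
    families: Sequence[GeneFamily],
    species: str,
    seed: int,
    p_tandem: float = 0.5,
    gene_span: int = 2000,
    gap: int = 500,
) -> tuple[list[GenePosition], list[tuple[str, tuple[str, ...]]]]:
    """Lay out one species' genes on scaffolds, planting a tandem array for
    a ``p_tandem`` fraction of its multi-copy families.

    Families chosen for tandem placement get all their copies consecutively
    on one scaffold; every other gene goes to its own scaffold, so the
    planted arrays are exactly the true arrays.  Returns (positions,
    [(family_id, ordered member tuple), ...]).
    """
    rng = np.random.default_rng(seed)
    positions: list[GenePosition] = []
    true_arrays: list[tuple[str, tuple[str, ...]]] = []
    scaffold_n = 0
    for fam in sorted(families, key=lambda f: f.family_id):
        members = sorted(g for sp, g in fam.members if sp == species)
        if not members:
            continue
        if len(members) >= 2 and rng.random() < p_tandem:
            scaffold_n += 1
            scaffold = f"scaffold_{scaffold_n:04d}"
            pos = 1
            for g in members:
                positions.append(
                    GenePosition(
                        gene_id=g, scaffold=scaffold, start=pos,
                        end=pos + gene_span - 1,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
                pos += gene_span + gap
            true_arrays.append((fam.family_id, tuple(members)))
        else:
            for g in members:
                scaffold_n += 1
                positions.append(
                    GenePosition(
                        gene_id=g, scaffold=f"scaffold_{scaffold_n:04d}",
                        start=1, end=gene_span,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
    return positions, true_arrays


# ---------------------------------------------------------------------------
# Expression counts with planted DE enrichment

def simulate_counts(
    n_genes: int,
    seed: int,
    n_reps: int = 3,
    de_fraction: float = 0.05,
    log2_fc: float = 2.0,
    dispersion: float = 0.05,
    mean_log_mu: float = 5.0,
    sd_log_mu: float = 1.5,
    categories: Mapping[str, Sequence[str]] | None = None,
    enrichment_odds: float = 1.0,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
) -> tuple[pd.DataFrame, dict[str, str], set[str]]:
    """Negative-binomial count matrix for a two-condition design.

    DE genes get a ±``log2_fc`` shift split between the conditions; genes in
    any of ``categories`` are ``enrichment_odds`` times more likely (on the
    odds scale) to be DE.  Returns (counts, sample→condition, true DE set).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    in_cat = np.zeros(n_genes, dtype=bool)
    if categories:
        members = set()
        for m in categories.values():
            members.update(m)
        in_cat = np.array([g in members for g in genes])
    base_odds = de_fraction / (1.0 - de_fraction)
    odds = np.where(in_cat, base_odds * enrichment_odds, base_odds)
    p_de = odds / (1.0 + odds)
    is_de = rng.random(n_genes) < p_de
    direction = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    mu = np.exp(rng.normal(mean_log_mu, sd_log_mu, size=n_genes))
    shift = np.where(is_de, direction * log2_fc / 2.0, 0.0)
    mu_c1 = mu * 2.0 ** (-shift)
    mu_c2 = mu * 2.0 ** (shift)
    samples = [f"c1_r{i + 1}" for i in range(n_reps)] + [
        f"c2_r{i + 1}" for i in range(n_reps)
    ]
    condition = {s: ("c1" if s.startswith("c1") else "c2") for s in samples}
    sf = rng.uniform(*size_factor_range, size=2 * n_reps)
    data = {}
    r = 1.0 / dispersion
    for k, s in enumerate(samples):
        m = (mu_c1 if condition[s] == "c1" else mu_c2) * sf[k]
        data[s] = rng.negative_binomial(r, r / (r + m))
    counts = pd.DataFrame(data, index=genes)
    true_de = {g for g, flag in zip(genes, is_de) if flag}
    return counts, condition, true_de
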