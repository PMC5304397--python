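"""Duplicate-gene inference: nearest paralogs, filters, ortholog-anchored
speciation threshold, dS age distributions and ancestral-duplicate loss rates.

The chain mirrors the standard comparative protocol: each gene is paired
with its nearest paralog (highest-scoring within-genome hit), the
non-redundant pair set is filtered for alignability and saturation, the mean
dS of 1:1 cross-species orthologs marks the speciation time on the dS axis,
and families whose within-genome pairs pre-date speciation are scored for
loss of one or both copies in the sister genome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codon_evolution import (
    DnDsEstimate,
    align_protein_pair,
    classify_pair_age,
    ng86_dnds,
    thread_codons,
)
from .io_formats import CodingRecord, GeneFamily, ProteinRecord, SimilarityHit

__all__ = [
    "ParalogPair",
    "OrthologPair",
    "AgeDistribution",
    "nearest_paralogs",
    "filter_saturation",
    "filter_for_omega",
    "extract_one_to_one",
    "speciation_threshold",
    "age_distribution",
    "ancestral_loss_rates",
    "loss_rate_percent",
    "estimate_pair_dnds",
    "duplicate_history_analysis",
]


@dataclass(frozen=True)
class ParalogPair:
    """A gene and its nearest within-genome paralog (unordered, gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    species: str
    estimate: DnDsEstimate | None = None
    age_class: str = "unset"

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise ValueError("pair must be lexicographically ordered and distinct")

    def with_estimate(self, estimate: DnDsEstimate) -> "ParalogPair":
        return replace(self, estimate=estimate)

    def with_age(self, threshold: float) -> "ParalogPair":
        if self.estimate is None:
            raise ValueError("cannot classify age without a dN/dS estimate")
        return replace(self, age_class=classify_pair_age(self.estimate.dS, threshold))


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    family_id: str
    estimate: DnDsEstimate | None = None


@dataclass(frozen=True)
class AgeDistribution:
    """Histogram of paralog-pair dS values in half-open bins [lo, hi)."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    label: str = ""

    @property
    def n_pairs(self) -> int:
        return int(sum(self.counts))


def nearest_paralogs(
    hits: Iterable[SimilarityHit],
    species_of: Mapping[str, str],
    min_aln: int = 150,
    min_identity: float = 30.0,
) -> list[ParalogPair]:
    """Per gene, the highest-bitscore non-self within-species hit that aligns
    over ≥ ``min_aln`` residues at ≥ ``min_identity`` % identity; the union of
    these best hits is deduplicated on unordered pairs.

    Bitscore ties break towards the lexicographically smaller subject id so
    the pair set is a pure function of the hit set.
    """
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.is_self:
            continue
        sp_q = species_of.get(h.query)
        sp_s = species_of.get(h.subject)
        if sp_q is None or sp_s is None or sp_q != sp_s:
            continue
        if h.aln_length < min_aln or h.pct_identity < min_identity:
            continue
        cur = best.get(h.query)
        if (
            cur is None
            or h.bitscore > cur.bitscore
            or (h.bitscore == cur.bitscore and h.subject < cur.subject)
        ):
            best[h.query] = h
    pairs: dict[tuple[str, str], str] = {}
    for h in best.values():
        a, b = sorted((h.query, h.subject))
        pairs[(a, b)] = species_of[h.query]
    return [
        ParalogPair(gene_a=a, gene_b=b, species=sp)
        for (a, b), sp in sorted(pairs.items())
    ]


def filter_saturation(
    pairs: Sequence[ParalogPair | OrthologPair], max_ds: float = 2.0
) -> list:
    """Drop pairs with dS strictly above ``max_ds`` (likely saturated),
    including pairs flagged saturated by the estimator."""
    out = []
    for p in pairs:
        if p.estimate is None:
            raise ValueError("pair lacks a dN/dS estimate")
        if p.estimate.saturated or p.estimate.dS > max_ds:
            continue
        out.append(p)
    return out


def filter_for_omega(
    pairs: Sequence[ParalogPair],
    min_d: float = 0.01,
    min_s_sites: float = 50.0,
    conjunctive: bool = False,
) -> list[ParalogPair]:
    """Strict filter for trustworthy ω: remove pairs with dN or dS below
    ``min_d`` or fewer than ``min_s_sites`` synonymous sites.

    With ``conjunctive=True`` a pair is removed only when a small distance
    AND a small site count co-occur (the alternative reading of the rule).
    """
    out = []
    for p in pairs:
        e = p.estimate
        if e is None:
            raise ValueError("pair lacks a dN/dS estimate")
        small_d = e.dN < min_d or e.dS < min_d
        few_sites = e.S_sites < min_s_sites
        removed = (small_d and few_sites) if conjunctive else (small_d or few_sites)
        if not removed:
            out.append(p)
    return out


def extract_one_to_one(
    families: Sequence[GeneFamily], species_a: str, species_b: str
) -> list[OrthologPair]:
    """1:1 ortholog pairs: families with exactly one member in each species."""
    out = []
    for fam in families:
        a_members = sorted(g for sp, g in fam.members if sp == species_a)
        b_members = sorted(g for sp, g in fam.members if sp == species_b)
        if len(a_members) == 1 and len(b_members) == 1:
            out.append(
                OrthologPair(
                    gene_a=a_members[0], gene_b=b_members[0], family_id=fam.family_id
                )
            )
    return out


def speciation_threshold(
    orthologs: Sequence[OrthologPair], max_ds: float = 2.0
) -> float:
    """Mean dS over 1:1 ortholog pairs surviving the saturation filter; this
    marks the speciation time on the dS axis."""
    kept = filter_saturation(orthologs, max_ds=max_ds)
    if not kept:
        raise ValueError("no ortholog pairs survive the saturation filter")
    return float(np.mean([p.estimate.dS for p in kept]))


def age_distribution(
    pairs: Sequence[ParalogPair],
    bin_width: float = 0.05,
    max_ds: float = 2.0,
    label: str = "",
) -> AgeDistribution:
    """Histogram of pair dS values in [0, max_ds] with half-open bins."""
    n_bins = int(round(max_ds / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    values = []
    for p in pairs:
        if p.estimate is None:
            raise ValueError("pair lacks a dN/dS estimate")
        if not p.estimate.saturated and p.estimate.dS <= max_ds:
            values.append(p.estimate.dS)
    counts = np.zeros(n_bins, dtype=int)
    for v in values:
        idx = min(int(v / bin_width), n_bins - 1) if v < max_ds else n_bins - 1
        # half-open bins [lo, hi); the terminal edge value max_ds falls in the last bin
        counts[idx] += 1
    return AgeDistribution(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        label=label,
    )


def loss_rate_percent(n_lost: int, n_ancestral: int) -> float:
    """Percentage of ancestrally duplicated families that lost one or both
    copies in the sister lineage."""
    if n_ancestral <= 0:
        raise ValueError("no ancestral duplicates; loss rate undefined")
    return 100.0 * n_lost / n_ancestral


def ancestral_loss_rates(
    pairs_a: Sequence[ParalogPair],
    pairs_b: Sequence[ParalogPair],
    families: Sequence[GeneFamily],
    threshold: float,
    species_a: str,
    species_b: str,
    max_ds: float = 2.0,
) -> dict:
    """Ancestral-duplicate retention asymmetry between two sister genomes.

    A family counts as ancestrally duplicated in species X when it contains a
    within-X paralog pair with threshold < dS ≤ ``max_ds`` (duplicated before
    speciation, not saturated); it is scored as lost in the sister species Y
    when ≤ 1 of its members belong to Y.  Loss rates are n_lost/n_ancestral
    per direction, with the 2×2 table ready for a chi-square comparison.
    """
    gene_to_family: dict[str, str] = {}
    fam_by_id: dict[str, GeneFamily] = {}
    for fam in families:
        fam_by_id[fam.family_id] = fam
        for sp, g in fam.members:
            gene_to_family[g] = fam.family_id

    def ancestral_families(pairs, species):
        out = set()
        for p in pairs:
            if p.estimate is None:
                raise ValueError("pair lacks a dN/dS estimate")
            if p.species != species:
                continue
            if p.estimate.saturated or p.estimate.dS > max_ds:
                continue
            if p.estimate.dS <= threshold:
                continue
            fam = gene_to_family.get(p.gene_a)
            if fam is not None and fam == gene_to_family.get(p.gene_b):
                out.add(fam)
        return out

    def n_lost(ancestral, other_species):
        return sum(
            1 for fid in ancestral
            if fam_by_id[fid].species_count(other_species) <= 1
        )

    anc_a = ancestral_families(pairs_a, species_a)
    anc_b = ancestral_families(pairs_b, species_b)
    lost_in_b = n_lost(anc_a, species_b)
    lost_in_a = n_lost(anc_b, species_a)
    result = {
        "n_ancestral_a": len(anc_a),
        "n_lost_in_b": lost_in_b,
        "n_ancestral_b": len(anc_b),
        "n_lost_in_a": lost_in_a,
        "loss_rate_ab": None,
        "loss_rate_ba": None,
        "table": (
            lost_in_b, len(anc_a) - lost_in_b,
            lost_in_a, len(anc_b) - lost_in_a,
        ),
    }
    if anc_a:
        result["loss_rate_ab"] = lost_in_b / len(anc_a)
    if anc_b:
        result["loss_rate_ba"] = lost_in_a / len(anc_b)
    return result


# ---------------------------------------------------------------------------
# End-to-end orchestration

def estimate_pair_dnds(
    proteins: Mapping[str, str], coding: Mapping[str, CodingRecord],
    gene_a: str, gene_b: str,
) -> DnDsEstimate:
    """Align two proteins, thread their CDS and estimate dN/dS."""
    aln = align_protein_pair(gene_a, proteins[gene_a], gene_b, proteins[gene_b])
    caln = thread_codons(aln, coding[gene_a].cds, coding[gene_b].cds)
    return ng86_dnds(caln)


def duplicate_history_analysis(
    proteins: Sequence[ProteinRecord],
    coding: Mapping[str, CodingRecord],
    hits: Sequence[SimilarityHit],
    species_a: str,
    species_b: str,
    inflation: float = 2.1,
    max_evalue: float = 1e-5,
    min_coverage: float = 0.5,
    min_aln: int = 150,
    min_identity: float = 30.0,
    max_ds: float = 2.0,
) -> dict:
    """The full duplicate-gene chain for a pair of sister genomes.

    Clusters families (MCL over filtered hits), selects nearest paralogs,
    estimates pairwise dN/dS, anchors the speciation time at the mean dS of
    1:1 orthologs, and computes ancestral-duplicate loss rates in both
    directions.  Returns a dict with families, per-species paralog pairs
    (estimates attached), orthologs, the speciation threshold and the
    loss-rate summary.
    """
    from .family_clustering import build_graph, filter_hits, mcl_cluster

    prot_seq = {p.gene_id: p.sequence for p in proteins}
    species_of = {p.gene_id: p.species for p in proteins}
    lengths = {p.gene_id: len(p) for p in proteins}
    families = mcl_cluster(
        build_graph(
            filter_hits(hits, lengths, max_evalue=max_evalue, min_coverage=min_coverage)
        ),
        inflation=inflation,
    ).families
    pairs = [
        p.with_estimate(estimate_pair_dnds(prot_seq, coding, p.gene_a, p.gene_b))
        for p in nearest_paralogs(
            hits, species_of, min_aln=min_aln, min_identity=min_identity
        )
    ]
    orthologs = [
        replace(o, estimate=estimate_pair_dnds(prot_seq, coding, o.gene_a, o.gene_b))
        for o in extract_one_to_one(families, species_a, species_b)
    ]
    threshold = speciation_threshold(orthologs, max_ds=max_ds)
    pairs_a = [p for p in pairs if p.species == species_a]
    pairs_b = [p for p in pairs if p.species == species_b]
    loss = ancestral_loss_rates(
        pairs_a, pairs_b, families, threshold, species_a, species_b, max_ds=max_ds
    )
    return {
        "families": families,
        "pairs_a": pairs_a,
        "pairs_b": pairs_b,
        "orthologs": orthologs,
        "speciation_threshold": threshold,
        "loss": loss,
    }
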