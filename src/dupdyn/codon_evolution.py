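"""Pairwise protein alignment, codon-alignment threading and dN/dS.

The dN/dS estimator is the Nei–Gojobori (1986) codon-counting method:

* synonymous/nonsynonymous *site* counts per codon are the per-position
  fractions of single-nucleotide changes (changes to stop codons excluded)
  that preserve the encoded amino acid, so S + N = 3 × codons exactly;
* *substitution* counts for a codon pair are averaged over all orderings of
  the single-nucleotide steps between the two codons, skipping any pathway
  that passes through a stop codon;
* proportions p = D/sites are corrected for multiple hits with the
  Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 marks saturation.

dS between two coding sequences grows with the time since their divergence
and is the molecular clock used to date duplicates; ω = dN/dS measures the
strength of selection on the protein.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import CODON_TABLE, STOP_CODONS

__all__ = [
    "PairwiseAlignment",
    "CodonAlignment",
    "DnDsEstimate",
    "align_protein_pair",
    "thread_codons",
    "ng86_dnds",
    "classify_pair_age",
    "codon_sites",
    "pathway_counts",
]

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float = 0.0

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("column gapped in both rows")

    @property
    def aligned_columns(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        )

    @property
    def identity(self) -> float:
        """Percent identical residues over non-gap–non-gap columns."""
        cols = self.aligned_columns
        if cols == 0:
            return 0.0
        same = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )
        return 100.0 * same / cols


@dataclass(frozen=True)
class CodonAlignment:
    """Codon triplets threaded through a protein alignment; gap columns hold
    ``---``.  Only ``comparable`` columns (two sense codons, no N) enter the
    substitution counting."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    @property
    def comparable(self) -> list[tuple[str, str]]:
        out = []
        for ca, cb in zip(self.codons_a, self.codons_b):
            if ca in CODON_TABLE and cb in CODON_TABLE:
                out.append((ca, cb))
        return out

    @property
    def n_codons(self) -> int:
        return len(self.comparable)


@dataclass(frozen=True)
class DnDsEstimate:
    dN: float
    dS: float
    S_sites: float
    N_sites: float
    n_codons: int
    saturated: bool

    @property
    def omega(self) -> float | None:
        if self.dS is None or self.dS <= 0 or not math.isfinite(self.dS):
            return None
        return self.dN / self.dS


# ---------------------------------------------------------------------------
# Protein alignment

def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # opening a gap of length k costs gap_open + (k−1)·gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_protein_pair(
    id_a: str,
    seq_a: str,
    id_b: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch) alignment of two protein sequences
    under an affine gap penalty.  Among co-optimal alignments the first in
    the aligner's deterministic traceback order is returned."""
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = aln[0], aln[1]
    return PairwiseAlignment(
        id_a=id_a, id_b=id_b, aligned_a=a_row, aligned_b=b_row,
        score=float(aln.score),
    )


def alignment_score(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal global alignment score (for cross-checks and hit simulation)."""
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return float(aligner.score(seq_a, seq_b))


# ---------------------------------------------------------------------------
# Codon threading

def thread_codons(aln: PairwiseAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Thread coding sequences through a protein alignment.

    Each amino-acid column becomes the corresponding codon column; a gap in a
    protein row becomes a ``---`` codon gap.  Raises ValueError when a CDS
    does not translate to its aligned protein row.
    """
    out = {"a": [], "b": []}
    for label, row, cds in (("a", aln.aligned_a, cds_a), ("b", aln.aligned_b, cds_b)):
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        protein = row.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"CDS length {len(cds)} does not match {len(protein)} aligned "
                f"residues for sequence {label}"
            )
        pos = 0
        for i, ch in enumerate(row):
            if ch == "-":
                out[label].append("---")
                continue
            codon = cds[3 * pos : 3 * pos + 3]
            aa = CODON_TABLE.get(codon, "X")
            if codon in STOP_CODONS or (aa != ch and not (aa == "X" or ch == "X")):
                raise ValueError(
                    f"sequence {label}: codon {codon} at residue {pos + 1} "
                    f"translates to {aa!r}, alignment has {ch!r}"
                )
            out[label].append(codon)
            pos += 1
    return CodonAlignment(codons_a=tuple(out["a"]), codons_b=tuple(out["b"]))


# ---------------------------------------------------------------------------
# NG86 tables

@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position: the fraction of single-nucleotide changes to other sense
    codons that are synonymous; changes to stop codons are excluded from the
    denominator, so the two counts always sum to 3.
    """
    aa = CODON_TABLE[codon]
    syn_total = 0.0
    for i in range(3):
        syn = nonsyn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if alt in STOP_CODONS:
                continue
            if CODON_TABLE[alt] == aa:
                syn += 1
            else:
                nonsyn += 1
        if syn + nonsyn:
            syn_total += syn / (syn + nonsyn)
    return syn_total, 3.0 - syn_total


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts for one codon pair,
    averaged over all orderings of the single-nucleotide steps; pathways
    through stop codons are skipped.  If every pathway is blocked the raw
    differences are split evenly between the two classes (rare; logged)."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    syn_paths = []
    for order in itertools.permutations(diffs):
        cur = codon_a
        syn = nonsyn = 0
        ok = True
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_paths.append((syn, nonsyn))
    if not syn_paths:
        logger.warning(
            "all mutational pathways between %s and %s pass through stops; "
            "splitting %d differences evenly", codon_a, codon_b, len(diffs)
        )
        return len(diffs) / 2.0, len(diffs) / 2.0
    sd = sum(s for s, _ in syn_paths) / len(syn_paths)
    nd = sum(n for _, n in syn_paths) / len(syn_paths)
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 multiple-hit correction; returns (distance, saturated)."""
    if p <= 0.0:
        return 0.0, False
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0.0:
        return math.inf, True
    return -0.75 * math.log(x), False


def ng86_dnds(caln: CodonAlignment) -> DnDsEstimate:
    """Nei–Gojobori (1986) pairwise dN/dS from a codon alignment."""
    pairs = caln.comparable
    if not pairs:
        raise ValueError("no comparable codon columns")
    S = N = 0.0
    Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, sat_s = _jukes_cantor(pS)
    dN, sat_n = _jukes_cantor(pN)
    return DnDsEstimate(
        dN=dN,
        dS=dS,
        S_sites=S,
        N_sites=N,
        n_codons=len(pairs),
        saturated=sat_s or sat_n,
    )


def classify_pair_age(dS: float, speciation_threshold: float) -> str:
    """'old' (duplicated before speciation) iff dS exceeds the mean dS of 1:1
    orthologs between the two species; ties classify as 'young'."""
    return "old" if dS > speciation_threshold else "young"
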