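"""Readers and writers for the external formats the pipeline consumes.

All coordinates are 1-based inclusive (the BLAST/GFF convention).  Readers
validate rather than coerce: malformed records raise :class:`FormatError`
with enough context to locate the offending line.

Species assignment follows the ``SPECIES|gene`` id convention by default; a
merged multi-species FASTA can instead supply an explicit ``species_map``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "FormatError",
    "ProteinRecord",
    "CodingRecord",
    "SimilarityHit",
    "GenePosition",
    "GeneFamily",
    "read_fasta",
    "read_cds_fasta",
    "read_hits",
    "write_hits",
    "read_newick",
    "read_positions",
    "read_family_dump",
    "write_family_dump",
    "split_species",
    "translate_cds",
    "longest_cds_per_gene",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTN")

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TABLE = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TABLE))


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def split_species(gene_id: str, delimiter: str = "|") -> tuple[str, str]:
    """Split ``SPECIES|gene`` into ``(species, gene)``.

    Returns ``("", gene_id)`` when the id carries no species prefix.
    """
    if delimiter in gene_id:
        species, _, rest = gene_id.partition(delimiter)
        return species, rest
    return "", gene_id


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    species: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"{self.gene_id}: empty protein sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"{self.gene_id}: invalid amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingRecord:
    gene_id: str
    cds: str

    def __post_init__(self):
        if not self.cds:
            raise FormatError(f"{self.gene_id}: empty CDS")
        if len(self.cds) % 3:
            raise FormatError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        bad = set(self.cds) - NT_ALPHABET
        if bad:
            raise FormatError(
                f"{self.gene_id}: invalid nucleotide characters {sorted(bad)}"
            )
        codons = [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]
        for i, codon in enumerate(codons[:-1]):
            if codon in STOP_CODONS:
                raise FormatError(
                    f"{self.gene_id}: internal stop codon {codon} at codon {i + 1}"
                )

    @property
    def coding_part(self) -> str:
        """CDS with a terminal stop codon, if present, trimmed."""
        if self.cds[-3:] in STOP_CODONS:
            return self.cds[:-3]
        return self.cds


def translate_cds(cds: str) -> str:
    """Translate a CDS (terminal stop trimmed) under the standard code.

    Codons containing N translate to X.
    """
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise local-alignment record (12-column tabular dialect)."""

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not (0.0 <= self.pct_identity <= 100.0):
            raise FormatError(
                f"{self.query}->{self.subject}: identity {self.pct_identity} "
                "outside [0, 100]"
            )
        if self.qstart > self.qend or self.sstart > self.send:
            raise FormatError(
                f"{self.query}->{self.subject}: reversed alignment coordinates"
            )
        if self.evalue < 0 or not math.isfinite(self.evalue):
            raise FormatError(
                f"{self.query}->{self.subject}: invalid E-value {self.evalue}"
            )

    @property
    def is_self(self) -> bool:
        return self.query == self.subject


@dataclass(frozen=True)
class GenePosition:
    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class GeneFamily:
    """An MCL cluster: a set of (species, gene_id) members."""

    family_id: str
    members: frozenset[tuple[str, str]]

    def species_count(self, species: str) -> int:
        return sum(1 for sp, _ in self.members if sp == species)

    def species_set(self) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.members)

    def gene_ids(self) -> frozenset[str]:
        return frozenset(g for _, g in self.members)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# FASTA

def _iter_fasta(path):
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def read_fasta(
    path,
    species_map: Mapping[str, str] | None = None,
    delimiter: str = "|",
) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Species come from ``species_map`` when given, else from the
    ``SPECIES|gene`` prefix of each header.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for gene_id, seq in _iter_fasta(path):
        if gene_id in seen:
            raise FormatError(f"{path}: duplicate sequence id {gene_id!r}")
        seen.add(gene_id)
        if species_map is not None:
            species = species_map.get(gene_id, "")
        else:
            species, _ = split_species(gene_id, delimiter)
        records.append(ProteinRecord(gene_id=gene_id, species=species, sequence=seq))
    return records


def read_cds_fasta(path) -> list[CodingRecord]:
    """Read a CDS FASTA into :class:`CodingRecord` objects."""
    records: list[CodingRecord] = []
    seen: set[str] = set()
    for gene_id, seq in _iter_fasta(path):
        if gene_id in seen:
            raise FormatError(f"{path}: duplicate sequence id {gene_id!r}")
        seen.add(gene_id)
        records.append(CodingRecord(gene_id=gene_id, cds=seq))
    return records


def longest_cds_per_gene(
    coding: Iterable[CodingRecord], gene_of_transcript: Mapping[str, str]
) -> dict[str, CodingRecord]:
    """Collapse isoforms to one record per gene, keeping the longest CDS.

    ``gene_of_transcript`` maps transcript id -> gene id; transcripts absent
    from the mapping are treated as their own gene.  Ties break towards the
    lexicographically smaller transcript id, for determinism.
    """
    best: dict[str, CodingRecord] = {}
    for rec in sorted(coding, key=lambda r: r.gene_id):
        gene = gene_of_transcript.get(rec.gene_id, rec.gene_id)
        cur = best.get(gene)
        if cur is None or len(rec.cds) > len(cur.cds):
            best[gene] = rec
    return best


# ---------------------------------------------------------------------------
# Tabular hits

_HIT_COLUMNS = 12


def read_hits(path) -> list[SimilarityHit]:
    """Read 12-column tabular similarity hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Self-hits are retained; downstream filters remove them.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = SimilarityHit(
                    query=fields[0],
                    subject=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query, h.subject, h.pct_identity, h.aln_length,
                        h.mismatch, h.gapopen, h.qstart, h.qend, h.sstart,
                        h.send, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick species tree

def read_newick(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick timetree; branch lengths are relative times.

    Rejects negative branch lengths and trees whose root polytomy marks them
    as unrooted.
    """
    src = str(path_or_string)
    kwargs = {"schema": "newick", "rooting": "default-rooted"}
    if src.strip().startswith("(") or src.strip().endswith(";"):
        tree = dendropy.Tree.get(data=src, **kwargs)
    else:
        tree = dendropy.Tree.get(path=src, **kwargs)
    if not tree.is_rooted:
        raise FormatError("species tree must be rooted")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise FormatError("species tree needs at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise FormatError("duplicate leaf labels in species tree")
    root_children = len(tree.seed_node.child_nodes())
    if root_children > 2:
        raise FormatError(
            f"tree root has {root_children} children; expected a rooted "
            "(bifurcating-root) tree"
        )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Gene positions

def read_positions(path) -> list[GenePosition]:
    """Read a gene-position TSV: gene_id, scaffold, start, end, strand."""
    out: list[GenePosition] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                )
            try:
                pos = GenePosition(
                    gene_id=fields[0],
                    scaffold=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                    strand=fields[4],
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if pos.gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene {pos.gene_id}")
            seen.add(pos.gene_id)
            out.append(pos)
    return out


# ---------------------------------------------------------------------------
# Family dump (MCL convention: one family per line, tab-separated gene ids)

def read_family_dump(path, delimiter: str = "|") -> list[GeneFamily]:
    """Read a family dump; family ids are assigned by line order (F000001…)."""
    families: list[GeneFamily] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            members = []
            for token in line.split("\t"):
                if not token:
                    raise FormatError(f"{path}:{lineno}: empty member field")
                if token in seen:
                    raise FormatError(
                        f"{path}:{lineno}: gene {token!r} in more than one family"
                    )
                seen.add(token)
                members.append((split_species(token, delimiter)[0], token))
            families.append(
                GeneFamily(family_id=f"F{lineno:06d}", members=frozenset(members))
            )
    return families


def write_family_dump(families: Sequence[GeneFamily], path, delimiter: str = "|") -> None:
    """Write families one per line, members sorted, in input order.

    Gene ids are written as-is (they already carry any species prefix), so
    read ∘ write is the identity on membership.
    """
    with open(path, "w") as fh:
        for fam in families:
            fh.write("\t".join(sorted(gid for _, gid in fam.members)) + "\n")
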