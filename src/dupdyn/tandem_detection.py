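"""Tandem gene-array calling from gene order and family membership.

Two genes of the same family on the same scaffold belong to one tandem
array when at most ``max_intervening`` genes of other families sit between
them in scaffold order (transitively closed).  Strand is ignored: tandem
duplicates frequently invert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import GeneFamily, GenePosition

__all__ = ["TandemArray", "call_tandem_arrays"]


@dataclass(frozen=True)
class TandemArray:
    scaffold: str
    family_id: str
    members: tuple[str, ...]  # ordered by start coordinate

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a tandem array needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


def call_tandem_arrays(
    positions: Sequence[GenePosition],
    families: Sequence[GeneFamily],
    max_intervening: int = 1,
) -> list[TandemArray]:
    """Call tandem arrays; each gene belongs to at most one array.

    Genes are ordered along each scaffold by (start, gene_id); consecutive
    same-family genes are chained when separated by ≤ ``max_intervening``
    other genes.  Output is sorted by (scaffold, first member start).
    """
    family_of: dict[str, str] = {}
    for fam in families:
        for _, gene in fam.members:
            family_of[gene] = fam.family_id

    by_scaffold: dict[str, list[GenePosition]] = {}
    for pos in positions:
        by_scaffold.setdefault(pos.scaffold, []).append(pos)

    arrays: list[TandemArray] = []
    for scaffold in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold], key=lambda p: (p.start, p.gene_id))
        # indices per family along the scaffold
        fam_indices: dict[str, list[int]] = {}
        for i, pos in enumerate(ordered):
            fam = family_of.get(pos.gene_id)
            if fam is not None:
                fam_indices.setdefault(fam, []).append(i)
        for fam in sorted(fam_indices):
            idxs = fam_indices[fam]
            run = [idxs[0]]
            for i in idxs[1:]:
                if i - run[-1] - 1 <= max_intervening:
                    run.append(i)
                else:
                    if len(run) >= 2:
                        arrays.append(
                            TandemArray(
                                scaffold=scaffold,
                                family_id=fam,
                                members=tuple(ordered[j].gene_id for j in run),
                            )
                        )
                    run = [i]
            if len(run) >= 2:
                arrays.append(
                    TandemArray(
                        scaffold=scaffold,
                        family_id=fam,
                        members=tuple(ordered[j].gene_id for j in run),
                    )
                )
    arrays.sort(key=lambda a: (a.scaffold, a.members))
    return arrays
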