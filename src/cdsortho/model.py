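"""Core in-memory containers: genes as ordered CDS-region sequences.

A gene is represented by the ordered list of its coding (CDS) regions,
5'->3' in coding orientation: minus-strand regions have already been
reverse-complemented and re-ordered so that index 0 is the 5'-most coding
region. The number and nucleotide lengths of those regions are the primary
matching signal downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class CDSGene:
    """One gene: species tag, identifiers, and ordered CDS-region sequences."""

    species: str
    gene_id: str
    transcript_id: str
    cds_seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.cds_seqs) < 1:
            raise ValueError(f"gene {self.gene_id}: needs at least one CDS region")
        for seq in self.cds_seqs:
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(
                    f"gene {self.gene_id}: invalid characters {bad} in CDS sequence"
                )

    @property
    def cds_lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.cds_seqs)

    @property
    def n_cds(self) -> int:
        return len(self.cds_seqs)

    @property
    def coding_sequence(self) -> str:
        """Concatenation of all CDS regions in coding orientation."""
        return "".join(self.cds_seqs)


@dataclass(frozen=True)
class GeneSet:
    """All genes of one species, sorted by (number of CDS regions, gene_id).

    The sort order is load-bearing: the ortholog search walks subjects in
    ascending CDS-region count and stops once the count difference exceeds
    its budget, so candidate enumeration is a contiguous window.
    """

    species: str
    genes: tuple[CDSGene, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", _sorted_genes(self.genes))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in GeneSet")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[CDSGene]:
        return iter(self.genes)

    @property
    def cds_counts(self) -> tuple[int, ...]:
        """CDS-region count per gene, non-decreasing by construction."""
        return tuple(g.n_cds for g in self.genes)

    def subset(self, gene_ids: Iterable[str]) -> "GeneSet":
        wanted = set(gene_ids)
        return GeneSet(self.species, tuple(g for g in self.genes if g.gene_id in wanted))


def _sorted_genes(genes: Iterable[CDSGene]) -> tuple[CDSGene, ...]:
    return tuple(sorted(genes, key=lambda g: (g.n_cds, g.gene_id)))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
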