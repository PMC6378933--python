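"""GFF3 + genome FASTA -> per-gene ordered CDS sequences, and the CDS-FASTA
interchange format.

The pipeline here mirrors how annotated reference genomes are prepared for
structure-based ortholog search: parse the annotation, drop genes flagged with
known annotation problems (translational errors, suspected errors,
transcription discrepancies), keep the longest isoform of each gene, extract
the CDS regions in coding orientation, and write them to a sorted "CDS-FASTA"
file, one record per gene with regions delimited by ``*``.

All GFF3 coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import urllib.parse
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta

from .model import CDSGene, GeneSet, VALID_BASES, reverse_complement

#: Attribute-value substrings marking annotation error classes whose genes are
#: removed by default (case-insensitive substring match over all values).
DEFAULT_ERROR_FLAGS = (
    "translational error",
    "suspected error",
    "transcription discrepancy",
)


class GFF3ParseError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    """One GFF3 feature line."""

    seqid: str
    source: str
    feature_type: str
    start: int  # 1-based inclusive
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(hash=False)

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")


def _parse_attributes(col: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[urllib.parse.unquote(key)] = urllib.parse.unquote(value)
    return attrs


def parse_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Parse a GFF3 file into a flat list of records.

    Comment and directive lines are skipped; a ``##FASTA`` directive
    terminates parsing. Records with an unknown strand symbol are rejected
    with a warning; malformed lines raise :class:`GFF3ParseError` naming the
    line number.
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GFF3ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start > end:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: start {start} > end {end}"
                )
            if cols[6] not in ("+", "-"):
                warnings.warn(
                    f"{path}: line {lineno}: unknown strand {cols[6]!r}; record skipped"
                )
                continue
            records.append(
                AnnotationRecord(
                    seqid=cols[0],
                    source=cols[1],
                    feature_type=cols[2],
                    start=start,
                    end=end,
                    score=cols[5],
                    strand=cols[6],
                    phase=cols[7],
                    attributes=_parse_attributes(cols[8]),
                )
            )
    return records


def _gene_of(record: AnnotationRecord, by_id: dict[str, AnnotationRecord]) -> str | None:
    """Walk the Parent chain up to the enclosing gene's ID."""
    node: AnnotationRecord | None = record
    for _ in range(16):  # hierarchy depth guard
        if node is None:
            return None
        if node.feature_type == "gene":
            return node.id
        parent = node.parent
        if parent is None:
            return node.id
        node = by_id.get(parent)
    return None


def filter_flagged(
    records: list[AnnotationRecord],
    flags: tuple[str, ...] | set[str] = DEFAULT_ERROR_FLAGS,
) -> list[AnnotationRecord]:
    """Remove every record of any gene carrying a flagged attribute value.

    Matching is a case-insensitive substring search over all attribute values
    of all of the gene's records, so annotation-problem notes are caught
    whichever attribute key (exception, note, ...) carries them.
    """
    lowered = tuple(f.lower() for f in flags)
    if not lowered:
        return list(records)
    by_id = {r.id: r for r in records if r.id is not None}
    bad_genes: set[str] = set()
    for rec in records:
        values = " ; ".join(rec.attributes.values()).lower()
        if any(f in values for f in lowered):
            gene = _gene_of(rec, by_id)
            if gene is not None:
                bad_genes.add(gene)
    if not bad_genes:
        return list(records)
    kept = []
    for rec in records:
        if _gene_of(rec, by_id) in bad_genes:
            continue
        kept.append(rec)
    return kept


def _transcripts_and_cds(
    records: list[AnnotationRecord],
) -> tuple[dict[str, list[str]], dict[str, list[AnnotationRecord]]]:
    """Map gene_id -> transcript ids, and transcript id -> its CDS records."""
    by_id = {r.id: r for r in records if r.id is not None}
    cds_by_tx: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        if rec.feature_type == "CDS" and rec.parent is not None:
            cds_by_tx.setdefault(rec.parent, []).append(rec)
    tx_by_gene: dict[str, list[str]] = {}
    for tx_id in cds_by_tx:
        tx = by_id.get(tx_id)
        gene = _gene_of(tx, by_id) if tx is not None else None
        if gene is None:
            gene = tx_id  # orphan transcript: treat as its own gene
        tx_by_gene.setdefault(gene, []).append(tx_id)
    return tx_by_gene, cds_by_tx


def select_longest_isoform(records: list[AnnotationRecord]) -> dict[str, str]:
    """Pick one transcript per gene: the one maximizing summed CDS length.

    Ties break to the lexicographically smallest transcript_id. Genes without
    any CDS-bearing transcript are dropped with a warning.
    """
    by_id = {r.id: r for r in records if r.id is not None}
    tx_by_gene, cds_by_tx = _transcripts_and_cds(records)
    chosen: dict[str, str] = {}
    for gene_id, tx_ids in sorted(tx_by_gene.items()):
        best = min(
            tx_ids,
            key=lambda t: (-sum(c.end - c.start + 1 for c in cds_by_tx[t]), t),
        )
        chosen[gene_id] = best
    genes = {r.id for r in records if r.feature_type == "gene"}
    for gene_id in sorted(genes - set(chosen)):
        warnings.warn(f"gene {gene_id}: no CDS-bearing transcript; dropped")
    return chosen


def extract_cds(
    genome: str | Path | Fasta,
    records: list[AnnotationRecord],
    species: str,
) -> GeneSet:
    """Extract per-gene ordered CDS sequences for the longest isoforms.

    Minus-strand regions are reverse-complemented and their order reversed so
    index 0 is always the 5'-most coding region. Genes whose CDS coordinates
    run past the contig end, or whose sequence contains characters outside
    {A,C,G,T,N}, are dropped with a warning.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    chosen = select_longest_isoform(records)
    _, cds_by_tx = _transcripts_and_cds(records)

    missing = sorted(
        {c.seqid for tx in chosen.values() for c in cds_by_tx[tx]} - set(fasta.keys())
    )
    if missing:
        raise KeyError(f"seqids absent from genome FASTA: {', '.join(missing)}")

    genes: list[CDSGene] = []
    for gene_id, tx_id in sorted(chosen.items()):
        cds = sorted(cds_by_tx[tx_id], key=lambda r: r.start)
        contig_len = len(fasta[cds[0].seqid])
        if cds[-1].end > contig_len:
            warnings.warn(
                f"gene {gene_id}: CDS end {cds[-1].end} beyond contig "
                f"{cds[0].seqid} length {contig_len}; dropped"
            )
            continue
        strand = cds[0].strand
        seqs = [str(fasta[r.seqid][r.start - 1 : r.end]).upper() for r in cds]
        if strand == "-":
            seqs = [reverse_complement(s) for s in reversed(seqs)]
        if any(set(s) - VALID_BASES for s in seqs):
            warnings.warn(f"gene {gene_id}: non-ACGTN characters in CDS; dropped")
            continue
        genes.append(CDSGene(species, gene_id, tx_id, tuple(seqs)))
    return GeneSet(species, tuple(genes))


# ---------------------------------------------------------------------------
# CDS-FASTA: the sorted interchange format consumed by the search engine.
# One record per gene; header ``>species|gene_id|transcript_id|n_cds``;
# sequence is the CDS regions joined by a single "*".
# ---------------------------------------------------------------------------

def write_cds_fasta(genes: GeneSet, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.species}|{g.gene_id}|{g.transcript_id}|{g.n_cds}\n")
            joined = "*".join(g.cds_seqs)
            for i in range(0, len(joined), width):
                fh.write(joined[i : i + width] + "\n")


def read_cds_fasta(path: str | Path) -> GeneSet:
    species: str | None = None
    genes: list[CDSGene] = []
    header: tuple[str, str, str, int] | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        sp, gid, tid, n = header
        seqs = tuple("".join(chunks).split("*"))
        if len(seqs) != n:
            raise ValueError(
                f"{path}: gene {gid}: header declares {n} CDS regions, found {len(seqs)}"
            )
        genes.append(CDSGene(sp, gid, tid, seqs))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("|")
                if len(fields) != 4:
                    raise ValueError(f"{path}: malformed CDS-FASTA header {line!r}")
                header = (fields[0], fields[1], fields[2], int(fields[3]))
                if species is None:
                    species = fields[0]
                chunks = []
            else:
                chunks.append(line)
        flush()
    if species is None:
        raise ValueError(f"{path}: empty CDS-FASTA file")
    return GeneSet(species, tuple(genes))
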