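"""Synthetic annotated genome pairs with planted orthologs.

The generator produces exactly the kind of data the structure-based search
assumes: multi-exon genes whose orthologs preserve CDS-region lengths and
diverge by point substitution, plus optional single fusion/split events and
decoy genes with no ortholog. It can emit a full genome FASTA + GFF3 pair
(genes placed on contigs with intronic and intergenic spacers, random strand,
gene/mRNA/CDS hierarchy, optional extra isoforms and error-flagged genes) so
the annotation pipeline is exercised end to end, and it keeps a truth table
(ortholog map, per-gene event logs, planted names) against which every
downstream stage can be verified.

Substitutions are uniform over the three alternative bases (a Jukes-Cantor
style process): the search thresholds only care about the amount of
divergence, not its spectrum. Structural events are capped at one per gene by
default so the matcher's two-event budget is comfortably sufficient;
``structural_events_per_gene`` can be raised to stress-test rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import CDSGene, GeneSet, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic species pair.

    Defaults describe a plausible vertebrate-like gene complement at the
    divergence the ``close`` setting targets: 500 ortholog pairs, coding
    exons of 60-300 nt, 3-12 exons per gene with geometrically decaying
    weights, 1% per-site substitution, no structural events unless asked for.
    """

    seed: int
    n_genes: int = 500
    n_decoys: int = 50
    exon_count_range: tuple[int, int] = (3, 12)
    exon_count_decay: float = 0.8  # weight ratio between consecutive counts
    exon_len_range: tuple[int, int] = (60, 300)
    sub_rate: float = 0.01
    p_structural: float = 0.0
    structural_events_per_gene: int = 1
    intron_len_range: tuple[int, int] = (50, 400)
    intergenic_len_range: tuple[int, int] = (100, 500)
    gc: float = 0.5
    genes_per_contig: int = 25
    n_flagged: int = 0
    p_extra_isoform: float = 0.0
    decoy_exon_len_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.p_structural, self.gc, self.p_extra_isoform):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.n_genes, self.n_decoys, self.n_flagged) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class TruthTable:
    """Everything the generator planted, for downstream verification."""

    ortholog_map: dict[str, str] = field(default_factory=dict)  # gene_a -> gene_b
    event_logs: dict[str, dict] = field(default_factory=dict)  # gene_b -> events
    names: dict[str, str] = field(default_factory=dict)  # gene_id -> planted name
    decoys: dict[str, set[str]] = field(default_factory=dict)  # species -> gene_ids
    flagged: dict[str, set[str]] = field(default_factory=dict)  # species -> gene_ids
    placements: dict[str, dict] = field(default_factory=dict)  # gene_id -> contig/strand


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")


def _draw_exon_count(params: SimParams, rng: np.random.Generator) -> int:
    lo, hi = params.exon_count_range
    counts = np.arange(lo, hi + 1)
    weights = params.exon_count_decay ** np.arange(len(counts))
    return int(rng.choice(counts, p=weights / weights.sum()))


def simulate_gene(
    params: SimParams,
    rng: np.random.Generator,
    species: str,
    gene_index: int,
    exon_len_range: tuple[int, int] | None = None,
) -> CDSGene:
    """Draw exon count and lengths, fill regions with random nucleotides."""
    lo, hi = exon_len_range or params.exon_len_range
    n_exons = _draw_exon_count(params, rng)
    lengths = rng.integers(lo, hi + 1, size=n_exons)
    seqs = tuple(_random_seq(int(L), params.gc, rng) for L in lengths)
    gid = f"{species}_g{gene_index:05d}"
    return CDSGene(species, gid, f"{gid}.t1", seqs)


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape) < rate)[0]
    for pos in hits:
        alternatives = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(alternatives)
    return arr.tobytes().decode("ascii"), int(len(hits))


def evolve_ortholog(
    gene: CDSGene,
    params: SimParams,
    rng: np.random.Generator,
    species: str,
    gene_index: int,
) -> tuple[CDSGene, dict]:
    """Derive an ortholog: i.i.d. substitutions, optionally fusion/split events.

    Without structural events the CDS-region lengths are preserved exactly;
    a split adds one region conserving summed length, a fusion joins two
    adjacent regions.
    """
    seqs = list(gene.cds_seqs)
    n_subs = 0
    for k, s in enumerate(seqs):
        seqs[k], n = _substitute(s, params.sub_rate, rng)
        n_subs += n
    events: list[tuple] = []
    if params.p_structural > 0 and rng.random() < params.p_structural:
        for _ in range(params.structural_events_per_gene):
            splittable = [k for k, s in enumerate(seqs) if len(s) >= 4]
            can_fuse = len(seqs) >= 2
            if can_fuse and (not splittable or rng.random() < 0.5):
                k = int(rng.integers(0, len(seqs) - 1))
                seqs[k : k + 2] = [seqs[k] + seqs[k + 1]]
                events.append(("fusion", k))
            elif splittable:
                k = int(rng.choice(splittable))
                cut = int(rng.integers(2, len(seqs[k]) - 1))
                seqs[k : k + 1] = [seqs[k][:cut], seqs[k][cut:]]
                events.append(("split", k, cut))
    gid = f"{species}_g{gene_index:05d}"
    ortholog = CDSGene(species, gid, f"{gid}.t1", tuple(seqs))
    log = {"n_substitutions": n_subs, "structural": events}
    return ortholog, log


# ---------------------------------------------------------------------------
# Genome emission: FASTA + GFF3 with a correct gene/mRNA/CDS hierarchy.
# ---------------------------------------------------------------------------

def _gff_phase(prev_coding_len: int) -> int:
    return (3 - prev_coding_len % 3) % 3


def emit_genome(
    genes: list[CDSGene],
    params: SimParams,
    rng: np.random.Generator,
    fasta_path: str | Path,
    gff3_path: str | Path,
    *,
    flagged: set[str] | None = None,
    names: dict[str, str] | None = None,
    truth: TruthTable | None = None,
) -> None:
    """Write genes onto synthetic contigs as genome FASTA + GFF3.

    Genes are placed in order with random intergenic spacers; regions within
    a gene are separated by random introns; each gene lands on a random
    strand. Genes in ``flagged`` get an ``exception`` attribute carrying an
    annotation-error note; with ``p_extra_isoform`` a shorter second isoform
    (missing the last CDS region) is added so longest-isoform selection is
    exercised. Extracting CDS from the emitted files reproduces ``genes``.
    """
    flagged = flagged or set()
    names = names or {}
    flag_texts = (
        "annotated translational error",
        "suspected error in annotation",
        "unclassified transcription discrepancy",
    )
    gff_lines: list[str] = ["##gff-version 3"]
    contigs: list[tuple[str, str]] = []
    contig_parts: list[str] = []
    contig_id = ""
    pos = 0  # 0-based length of current contig so far
    n_flagged_so_far = 0

    def new_contig(k: int) -> None:
        nonlocal contig_id, contig_parts, pos
        contig_id = f"contig{k:03d}"
        contig_parts = []
        pos = 0

    def close_contig() -> None:
        if contig_parts:
            contigs.append((contig_id, "".join(contig_parts)))

    new_contig(0)
    for idx, gene in enumerate(genes):
        if idx and idx % params.genes_per_contig == 0:
            close_contig()
            new_contig(idx // params.genes_per_contig)
        spacer = int(rng.integers(*params.intergenic_len_range))
        contig_parts.append(_random_seq(spacer, params.gc, rng))
        pos += spacer

        introns = [
            _random_seq(int(rng.integers(*params.intron_len_range)), params.gc, rng)
            for _ in range(gene.n_cds - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        # build the gene's genomic segment in coding orientation first
        segment_parts: list[str] = []
        region_spans: list[tuple[int, int]] = []  # 1-based within segment
        cursor = 0
        for k, seq in enumerate(gene.cds_seqs):
            segment_parts.append(seq)
            region_spans.append((cursor + 1, cursor + len(seq)))
            cursor += len(seq)
            if k < len(introns):
                segment_parts.append(introns[k])
                cursor += len(introns[k])
        segment = "".join(segment_parts)
        if strand == "-":
            segment = reverse_complement(segment)
            L = len(segment)
            region_spans = [(L - e + 1, L - s + 1) for s, e in region_spans]

        g_start = pos + 1  # 1-based on contig
        contig_parts.append(segment)
        pos += len(segment)
        g_end = pos

        def abs_span(span: tuple[int, int]) -> tuple[int, int]:
            return g_start + span[0] - 1, g_start + span[1] - 1

        attrs_extra = ""
        if gene.gene_id in flagged:
            text = flag_texts[n_flagged_so_far % len(flag_texts)]
            attrs_extra = f";exception={text}"
            n_flagged_so_far += 1
        name_attr = f";Name={names[gene.gene_id]}" if gene.gene_id in names else ""
        gff_lines.append(
            f"{contig_id}\tsim\tgene\t{g_start}\t{g_end}\t.\t{strand}\t."
            f"\tID={gene.gene_id}{name_attr}"
        )
        gff_lines.append(
            f"{contig_id}\tsim\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t."
            f"\tID={gene.transcript_id};Parent={gene.gene_id}{attrs_extra}"
        )
        coding_so_far = 0
        lengths_coding_order = gene.cds_lengths
        for k, span in enumerate(region_spans):
            s, e = abs_span(span)
            phase = _gff_phase(coding_so_far)
            coding_so_far += lengths_coding_order[k]
            gff_lines.append(
                f"{contig_id}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}"
                f"\tID={gene.transcript_id}.cds{k};Parent={gene.transcript_id}"
            )
        # optional shorter extra isoform (drops the last coding region)
        if gene.n_cds >= 2 and rng.random() < params.p_extra_isoform:
            alt = f"{gene.gene_id}.t2"
            gff_lines.append(
                f"{contig_id}\tsim\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t."
                f"\tID={alt};Parent={gene.gene_id}"
            )
            coding_so_far = 0
            for k, span in enumerate(region_spans[:-1]):
                s, e = abs_span(span)
                phase = _gff_phase(coding_so_far)
                coding_so_far += lengths_coding_order[k]
                gff_lines.append(
                    f"{contig_id}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}"
                    f"\tID={alt}.cds{k};Parent={alt}"
                )
        if truth is not None:
            truth.placements[gene.gene_id] = {
                "contig": contig_id,
                "strand": strand,
                "start": g_start,
                "end": g_end,
            }
    close_contig()

    with open(fasta_path, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")


@dataclass
class PairFixture:
    """A simulated species pair plus its ground truth."""

    genes_a: GeneSet
    genes_b: GeneSet
    truth: TruthTable
    params: SimParams
    flagged_genes_a: tuple[CDSGene, ...] = ()
    flagged_genes_b: tuple[CDSGene, ...] = ()


def simulate_pair(
    params: SimParams, species_a: str = "speciesA", species_b: str = "speciesB"
) -> PairFixture:
    """Simulate two species: planted 1:1 orthologs, decoys, optional flags.

    Ortholog pairs share a planted gene name (``GENE%04d``); decoys get
    unique names so they are nameable but partnerless. Flagged genes are
    extra genes that only appear in emitted GFF3 (with an error note) and
    should vanish in annotation filtering.
    """
    rng = np.random.default_rng(params.seed)
    truth = TruthTable()
    genes_a: list[CDSGene] = []
    genes_b: list[CDSGene] = []
    for k in range(params.n_genes):
        g = simulate_gene(params, rng, species_a, k)
        o, log = evolve_ortholog(g, params, rng, species_b, k)
        name = f"GENE{k:04d}"
        truth.ortholog_map[g.gene_id] = o.gene_id
        truth.event_logs[o.gene_id] = log
        truth.names[g.gene_id] = name
        truth.names[o.gene_id] = name
        genes_a.append(g)
        genes_b.append(o)
    decoy_range = params.decoy_exon_len_range
    truth.decoys = {species_a: set(), species_b: set()}
    for k in range(params.n_decoys):
        d_a = simulate_gene(params, rng, species_a, params.n_genes + k, decoy_range)
        d_b = simulate_gene(params, rng, species_b, params.n_genes + k, decoy_range)
        truth.decoys[species_a].add(d_a.gene_id)
        truth.decoys[species_b].add(d_b.gene_id)
        truth.names[d_a.gene_id] = f"DECOYA{k:04d}"
        truth.names[d_b.gene_id] = f"DECOYB{k:04d}"
        genes_a.append(d_a)
        genes_b.append(d_b)
    flagged_a: list[CDSGene] = []
    flagged_b: list[CDSGene] = []
    truth.flagged = {species_a: set(), species_b: set()}
    base = params.n_genes + params.n_decoys
    for k in range(params.n_flagged):
        f_a = simulate_gene(params, rng, species_a, base + k)
        f_b = simulate_gene(params, rng, species_b, base + k)
        truth.flagged[species_a].add(f_a.gene_id)
        truth.flagged[species_b].add(f_b.gene_id)
        flagged_a.append(f_a)
        flagged_b.append(f_b)
    return PairFixture(
        GeneSet(species_a, tuple(genes_a)),
        GeneSet(species_b, tuple(genes_b)),
        truth,
        params,
        tuple(flagged_a),
        tuple(flagged_b),
    )


def emit_pair(
    fixture: PairFixture, out_dir: str | Path
) -> dict[str, Path]:
    """Emit both species' genome FASTA + GFF3 and the truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rng = np.random.default_rng(fixture.params.seed + 1)
    for tag, genes, flagged_extra in (
        ("a", fixture.genes_a, fixture.flagged_genes_a),
        ("b", fixture.genes_b, fixture.flagged_genes_b),
    ):
        species = genes.species
        all_genes = sorted(
            list(genes.genes) + list(flagged_extra), key=lambda g: g.gene_id
        )
        fasta = out / f"{species}.fa"
        gff = out / f"{species}.gff3"
        emit_genome(
            all_genes,
            fixture.params,
            rng,
            fasta,
            gff,
            flagged=fixture.truth.flagged.get(species, set()),
            names=fixture.truth.names,
            truth=fixture.truth,
        )
        paths[f"fasta_{tag}"] = fasta
        paths[f"gff_{tag}"] = gff
    truth_path = out / "truth_pairs.tsv"
    with open(truth_path, "w") as fh:
        fh.write("gene_a\tgene_b\tname\tn_substitutions\tstructural_events\n")
        for a, b in sorted(fixture.truth.ortholog_map.items()):
            log = fixture.truth.event_logs[b]
            ev = ";".join(
                ":".join(str(x) for x in e) for e in log["structural"]
            ) or "."
            fh.write(
                f"{a}\t{b}\t{fixture.truth.names[a]}\t{log['n_substitutions']}\t{ev}\n"
            )
    names_path = out / "names.tsv"
    with open(names_path, "w") as fh:
        fh.write("gene_id\tname\n")
        for gid, name in sorted(fixture.truth.names.items()):
            fh.write(f"{gid}\t{name}\n")
    paths["truth"] = truth_path
    paths["names"] = names_path
    return paths
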