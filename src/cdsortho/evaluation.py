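"""Benchmark construction and precision/recall scoring.

Ground truth for ortholog benchmarking comes from shared gene names
(case-insensitive): a gene in species A and a gene in species B carrying the
same name are a true ortholog pair. From such an annotated pair of gene sets
three kinds of test sets are built:

* ``original`` — every included gene has its true partner included, so all
  reportable pairs are true positives;
* ``mismatch`` — a per-chunk mixture of 50-90% true pairs, padded with
  partnerless genes, approximating an unfiltered research data set;
* ``error`` — only partnerless genes, so every reported pair is a false
  positive.

Each test set holds up to ``chunk_size`` (default 1000) genes per species;
when a set fills up, the next one starts where it left off.

Scoring follows the one-to-one protocol: reported items lacking a sequence
from each of the two species are excluded from evaluation; a true positive
requires exactly one gene per species with matching names (here: membership
in the truth pair set); precision = TP/(TP+FP), recall = TP/(TP+FN), with
0/0 reported as not-applicable rather than 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .core import OrthologPair
from .groups import Member, OrthologGroup
from .model import GeneSet

Kind = Literal["original", "mismatch", "error"]


@dataclass(frozen=True)
class TestSet:
    kind: Kind
    genes_a: GeneSet
    genes_b: GeneSet
    truth: frozenset[tuple[str, str]]  # (gene_id in A, gene_id in B)
    tp_fraction: float | None = None  # mismatch only


@dataclass(frozen=True)
class ScoreResult:
    tp: int
    fp: int
    fn: int
    n_excluded: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None


def _name_index(genes: GeneSet, names: Mapping[str, str]) -> dict[str, str]:
    """Case-folded name -> gene_id (smallest gene_id wins on duplicates)."""
    index: dict[str, str] = {}
    for g in genes:
        name = names.get(g.gene_id)
        if not name:
            continue
        key = name.casefold()
        if key in index:
            warnings.warn(f"duplicate name {name!r} in {genes.species}; keeping smallest gene_id")
            index[key] = min(index[key], g.gene_id)
        else:
            index[key] = g.gene_id
    return index


def build_test_sets(
    genes_a: GeneSet,
    genes_b: GeneSet,
    names: Mapping[str, str],
    kind: Kind,
    chunk_size: int = 1000,
    seed: int = 0,
) -> list[TestSet]:
    """Chunk annotated gene sets into test sets of the requested kind.

    ``names`` maps gene_id -> gene name; names shared (case-insensitively)
    between the two species define the true ortholog pairs. Chunks are formed
    over the name-sorted pair list (and gene_id-sorted partnerless pools), so
    the same inputs and seed always produce the same sets.
    """
    index_a, index_b = _name_index(genes_a, names), _name_index(genes_b, names)
    shared = sorted(set(index_a) & set(index_b))
    pairs = [(index_a[n], index_b[n]) for n in shared]
    paired_a = {index_a[n] for n in shared}
    paired_b = {index_b[n] for n in shared}
    partnerless_a = sorted(g.gene_id for g in genes_a if g.gene_id not in paired_a)
    partnerless_b = sorted(g.gene_id for g in genes_b if g.gene_id not in paired_b)

    rng = np.random.default_rng(seed)
    sets: list[TestSet] = []

    if kind == "original":
        if not pairs:
            warnings.warn("no true ortholog pairs available; no original sets built")
        for k in range(0, len(pairs), chunk_size):
            chunk = pairs[k : k + chunk_size]
            sets.append(
                TestSet(
                    "original",
                    genes_a.subset(a for a, _ in chunk),
                    genes_b.subset(b for _, b in chunk),
                    frozenset(chunk),
                )
            )
    elif kind == "error":
        if not partnerless_a or not partnerless_b:
            warnings.warn("no partnerless genes available; no error sets built")
        n_sets = max(
            -(-len(partnerless_a) // chunk_size), -(-len(partnerless_b) // chunk_size)
        ) if (partnerless_a and partnerless_b) else 0
        for k in range(n_sets):
            ids_a = partnerless_a[k * chunk_size : (k + 1) * chunk_size]
            ids_b = partnerless_b[k * chunk_size : (k + 1) * chunk_size]
            if not ids_a or not ids_b:
                break
            sets.append(
                TestSet("error", genes_a.subset(ids_a), genes_b.subset(ids_b), frozenset())
            )
    elif kind == "mismatch":
        pa, pb = list(partnerless_a), list(partnerless_b)
        k = 0
        while k < len(pairs):
            frac = float(rng.uniform(0.5, 0.9))
            n_tp = max(1, round(frac * chunk_size))
            chunk = pairs[k : k + n_tp]
            k += n_tp
            # pad so the realized TP fraction tracks the drawn one even when
            # the final chunk of pairs is short
            n_fill = min(chunk_size - len(chunk), round(len(chunk) * (1 / frac - 1)))
            fill_a, pa = pa[:n_fill], pa[n_fill:]
            fill_b, pb = pb[:n_fill], pb[n_fill:]
            if n_fill and not (fill_a or fill_b):
                warnings.warn("partnerless genes exhausted; mismatch set is all-TP")
            ids_a = [a for a, _ in chunk] + fill_a
            ids_b = [b for _, b in chunk] + fill_b
            actual = len(chunk) / max(len(ids_a), len(ids_b))
            sets.append(
                TestSet(
                    "mismatch",
                    genes_a.subset(ids_a),
                    genes_b.subset(ids_b),
                    frozenset(chunk),
                    tp_fraction=actual,
                )
            )
    else:
        raise ValueError(f"unknown test-set kind {kind!r}")
    return sets


def _as_group(item: OrthologPair | OrthologGroup | Iterable[Member]) -> frozenset[Member]:
    if isinstance(item, OrthologPair):
        return frozenset(
            {
                (item.query.species, item.query.gene_id),
                (item.subject.species, item.subject.gene_id),
            }
        )
    if isinstance(item, OrthologGroup):
        return item.members
    return frozenset(tuple(m) for m in item)


def score(
    reported: Sequence[OrthologPair | OrthologGroup | Iterable[Member]],
    truth: Iterable[tuple[str, str]],
    species_pair: tuple[str, str],
) -> ScoreResult:
    """Score reported pairs/groups against a truth pair set.

    Items that do not include a sequence from each of the two species are
    excluded from evaluation. A true positive has exactly one gene per
    species and its (species-A gene, species-B gene) pair in the truth set;
    any other evaluable item is a false positive. FN counts truth pairs never
    recovered.
    """
    sp_a, sp_b = species_pair
    truth_set = {tuple(t) for t in truth}
    tp = fp = excluded = 0
    hit: set[tuple[str, str]] = set()
    for item in reported:
        members = _as_group(item)
        species = {sp for sp, _ in members}
        if not {sp_a, sp_b} <= species:
            excluded += 1
            continue
        a_genes = sorted(gid for sp, gid in members if sp == sp_a)
        b_genes = sorted(gid for sp, gid in members if sp == sp_b)
        if len(a_genes) == 1 and len(b_genes) == 1 and (a_genes[0], b_genes[0]) in truth_set:
            tp += 1
            hit.add((a_genes[0], b_genes[0]))
        else:
            fp += 1
    fn = len(truth_set - hit)
    return ScoreResult(tp=tp, fp=fp, fn=fn, n_excluded=excluded)


# ---------------------------------------------------------------------------
# Serialization: truth TSV and score table.
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(truth):
            fh.write(f"{a}\t{b}\n")


def read_truth_tsv(path: str | Path) -> frozenset[tuple[str, str]]:
    pairs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("gene_a"):
                continue
            a, b = line.split("\t")[:2]
            pairs.add((a, b))
    return frozenset(pairs)


def write_scores_tsv(
    rows: Sequence[tuple[str, str, ScoreResult]], path: str | Path
) -> None:
    """Rows of (set_id, kind, result) -> TSV; undefined ratios printed as NA."""

    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6f}"

    with open(path, "w") as fh:
        fh.write("set_id\tkind\ttp\tfp\tfn\tprecision\trecall\n")
        for set_id, kind, r in rows:
            fh.write(
                f"{set_id}\t{kind}\t{r.tp}\t{r.fp}\t{r.fn}\t{fmt(r.precision)}\t{fmt(r.recall)}\n"
            )
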