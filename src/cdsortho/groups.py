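"""Combine pairwise ortholog outputs into multi-species ortholog groups.

Pairwise runs produce query->subject gene pairs; across many species
comparisons these pairs form a graph whose connected components are the
ortholog groups (if A pairs with B and B with C, the group is {A, B, C}).
A one-to-one filter then discards groups in which any species contributes
more than one gene, since such groups likely reflect paralogy or error
rather than simple orthology.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

Member = tuple[str, str]  # (species, gene_id)


@dataclass(frozen=True)
class OrthologEdge:
    gene_a: Member
    gene_b: Member

    def __post_init__(self) -> None:
        if self.gene_a[0] == self.gene_b[0]:
            raise ValueError(f"edge within one species: {self.gene_a} - {self.gene_b}")

    @property
    def key(self) -> frozenset[Member]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class OrthologGroup:
    members: frozenset[Member]
    provenance: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.members)

    @property
    def species_counts(self) -> Counter:
        return Counter(sp for sp, _ in self.members)

    @property
    def is_one_to_one(self) -> bool:
        return all(n == 1 for n in self.species_counts.values())


def load_pair_files(
    directory: str | Path,
    provenance: dict[frozenset[Member], set[str]] | None = None,
) -> list[OrthologEdge]:
    """Read every pair TSV in a directory into deduplicated edges.

    Species labels come from the ``# query_species=`` / ``# subject_species=``
    comment headers written by the search engine. Malformed rows are skipped
    with one summary warning. If a ``provenance`` dict is passed it is filled
    with edge -> contributing file names.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no pair TSV files found in {directory}")
    edges: list[OrthologEdge] = []
    seen: set[frozenset[Member]] = set()
    n_bad = 0
    for path in files:
        file_edges, bad = read_pair_file(path)
        n_bad += bad
        for edge in file_edges:
            if provenance is not None:
                provenance.setdefault(edge.key, set()).add(path.name)
            if edge.key in seen:
                continue
            seen.add(edge.key)
            edges.append(edge)
    if n_bad:
        warnings.warn(f"{n_bad} malformed pair row(s) skipped")
    return edges


def read_pair_file(path: str | Path) -> tuple[list[OrthologEdge], int]:
    """Read one pair TSV; returns (edges, number of malformed rows skipped)."""
    q_species = s_species = None
    edges: list[OrthologEdge] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# query_species="):
                q_species = line.split("=", 1)[1]
                continue
            if line.startswith("# subject_species="):
                s_species = line.split("=", 1)[1]
                continue
            if line.startswith("#") or not line:
                continue
            cols = line.split("\t")
            if cols[0] == "query_gene_id":  # column header
                continue
            if len(cols) < 2 or q_species is None or s_species is None:
                n_bad += 1
                continue
            try:
                edges.append(OrthologEdge((q_species, cols[0]), (s_species, cols[1])))
            except ValueError:
                n_bad += 1
    return edges, n_bad


def build_groups(
    edges: Iterable[OrthologEdge],
    provenance: Mapping[frozenset[Member], set[str]] | None = None,
) -> list[OrthologGroup]:
    """Connected components of the ortholog-pair graph, as groups.

    Output is sorted by descending size, then by the lexicographically
    smallest member; the result is independent of edge order.
    """
    provenance = provenance or {}
    graph = nx.Graph()
    edge_list = list(edges)
    for e in edge_list:
        graph.add_edge(e.gene_a, e.gene_b)
    groups = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        prov: set[str] = set()
        for e in edge_list:
            if e.gene_a in members and e.key in provenance:
                prov |= provenance[e.key]
        groups.append(OrthologGroup(members, frozenset(prov)))
    groups.sort(key=lambda g: (-len(g.members), min(g.members)))
    return groups


def enforce_one_to_one(
    groups: Iterable[OrthologGroup], *, prune: bool = False
) -> list[OrthologGroup]:
    """Enforce at most one gene per species within each group.

    Default: any group where some species contributes two or more genes is
    removed entirely. With ``prune=True``, the offending species' genes are
    dropped instead and the group is kept if it still spans two species.
    """
    out: list[OrthologGroup] = []
    for g in groups:
        if g.is_one_to_one:
            out.append(g)
            continue
        if not prune:
            continue
        dup_species = {sp for sp, n in g.species_counts.items() if n > 1}
        kept = frozenset(m for m in g.members if m[0] not in dup_species)
        if len(kept) >= 2:
            out.append(OrthologGroup(kept, g.provenance))
    return out


def group_summary(
    groups: Iterable[OrthologGroup], annotations: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group annotation agreement table.

    For each group: how many genes share the modal (case-insensitive) name,
    how many carry a different name, how many are unannotated, and the total.
    ``annotations`` maps gene_id -> name and may be partial.
    """
    rows = []
    for g in groups:
        names = [annotations.get(gid) for _, gid in g.members]
        known = [n.casefold() for n in names if n]
        n_unknown = len(names) - len(known)
        if known:
            modal, n_same = Counter(known).most_common(1)[0]
            n_other = len(known) - n_same
        else:
            n_same = n_other = 0
        rows.append(
            {
                "same_annotation": n_same,
                "other_annotation": n_other,
                "unannotated": n_unknown,
                "total": len(names),
            }
        )
    return pd.DataFrame(rows)


def write_groups_tsv(groups: Iterable[OrthologGroup], path: str | Path) -> None:
    """One group per line: tab-separated ``species:gene_id`` tokens."""
    with open(path, "w") as fh:
        for g in groups:
            tokens = sorted(f"{sp}:{gid}" for sp, gid in g.members)
            fh.write("\t".join(tokens) + "\n")


def read_groups_tsv(path: str | Path) -> list[OrthologGroup]:
    groups = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            members = frozenset(
                tuple(tok.split(":", 1)) for tok in line.split("\t")
            )
            groups.append(OrthologGroup(members))
    return groups
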