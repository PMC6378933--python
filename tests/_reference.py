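"""Independent reference implementations used as oracles.

Everything here is deliberately naive (dict counting, recursive enumeration,
O(n^2) loops) and shares no code with the package's engine, so agreement is
meaningful.
"""

from __future__ import annotations

from itertools import product

DINUCS = ["".join(p) for p in product("ACGT", repeat=2)]


def naive_profile(exon: str) -> list[float]:
    """Bigram proportions by substring counting, skipping N-containing pairs."""
    counts = {d: 0 for d in DINUCS}
    total = 0
    for i in range(len(exon) - 1):
        pair = exon[i : i + 2]
        if "N" in pair:
            continue
        counts[pair] += 1
        total += 1
    if total == 0:
        return [0.0] * 16
    return [counts[d] / total for d in DINUCS]


def naive_tv(p: list[float], q: list[float]) -> float:
    return sum(abs(a - b) for a, b in zip(p, q)) / 2


def exhaustive_match(
    ql: tuple[int, ...], sl: tuple[int, ...], max_events: int
) -> list[tuple[tuple[int, ...], tuple[int, ...]]] | None:
    """All-ways recursive in-order merge matching; returns a pairing or None."""

    def rec(i: int, j: int, budget: int):
        if i == len(ql) and j == len(sl):
            return []
        if i == len(ql) or j == len(sl):
            return None
        # 1:1
        if ql[i] == sl[j]:
            rest = rec(i + 1, j + 1, budget)
            if rest is not None:
                return [((i,), (j,))] + rest
        if budget > 0:
            # merge runs of query into subject[j]
            total = 0
            for end in range(i, len(ql)):
                total += ql[end]
                if total == sl[j] and end > i:
                    rest = rec(end + 1, j + 1, budget - 1)
                    if rest is not None:
                        return [(tuple(range(i, end + 1)), (j,))] + rest
                if total >= sl[j]:
                    break
            # merge runs of subject into query[i]
            total = 0
            for end in range(j, len(sl)):
                total += sl[end]
                if total == ql[i] and end > j:
                    rest = rec(i + 1, end + 1, budget - 1)
                    if rest is not None:
                        return [((i,), tuple(range(j, end + 1)))] + rest
                if total >= ql[i]:
                    break
        return None

    return rec(0, 0, max_events)


def naive_gene_distance(query, subject, units) -> float:
    """Mean naive-TV over pairing units, skipping zero-profile units."""
    dists = []
    for q_idx, s_idx in units:
        p = naive_profile("".join(query.cds_seqs[k] for k in q_idx))
        q = naive_profile("".join(subject.cds_seqs[k] for k in s_idx))
        if not any(p) or not any(q):
            continue
        dists.append(naive_tv(p, q))
    if not dists:
        return float("inf")
    return sum(dists) / len(dists)


def naive_find_orthologs(queries, subjects, setting: str, threshold: float,
                         max_events: int = 2):
    """Exhaustive all-pairs search under the same reporting rules.

    Returns (query_id, subject_id, distance, setting) tuples sorted by
    query_id: best subject per query (ties to smallest gene_id), reported if
    distance <= threshold.
    """
    out = []
    for q in queries.genes:
        best = None
        for s in subjects.genes:
            if abs(q.n_cds - s.n_cds) > max_events:
                continue
            if setting == "close":
                if q.cds_lengths != s.cds_lengths:
                    continue
                units = [((i,), (i,)) for i in range(q.n_cds)]
            else:
                units = exhaustive_match(q.cds_lengths, s.cds_lengths, max_events)
                if units is None:
                    continue
            d = naive_gene_distance(q, s, units)
            if best is None or (d, s.gene_id) < best[:2]:
                best = (d, s.gene_id, s)
        if best is not None and best[0] <= threshold:
            out.append((q.gene_id, best[1], best[0], setting))
    out.sort(key=lambda t: t[0])
    return out


def naive_combined(queries, subjects, close_threshold=0.05, distant_threshold=0.1):
    close = naive_find_orthologs(queries, subjects, "close", close_threshold)
    distant = naive_find_orthologs(queries, subjects, "distant", distant_threshold)
    have = {t[0] for t in close}
    merged = close + [t for t in distant if t[0] not in have]
    merged.sort(key=lambda t: t[0])
    return merged


def brute_transitive_closure(edges) -> set[frozenset]:
    """O(n^2) union of overlapping pair sets until a fixed point."""
    groups = [set(e) for e in edges]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            if not groups[i]:
                continue
            for j in range(i + 1, len(groups)):
                if groups[j] and groups[i] & groups[j]:
                    groups[i] |= groups[j]
                    groups[j] = set()
                    changed = True
    return {frozenset(g) for g in groups if g}
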