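"""Independent brute-force oracle for gap-constrained closed frequent
pattern mining.

Enumerates, per sequence, every gap-feasible embedded subsequence by
exhaustive DFS over index embeddings, counts document support, keeps the
frequent ones and removes any pattern with a same-support frequent
super-sequence. Entirely independent of the pattern-growth miner."""

from __future__ import annotations

from routinemine.gapbide import GapConstraint


def feasible_subsequences(seq, gap: GapConstraint) -> set[tuple[str, ...]]:
    """All label tuples embeddable in ``seq`` under the gap constraint."""
    out: set[tuple[str, ...]] = set()

    def dfs(last_idx: int, prefix: tuple[str, ...]) -> None:
        out.add(prefix)
        lo = last_idx + 1 + gap.gap_min
        hi = last_idx + 1 + gap.gap_max
        for j in range(lo, min(hi, len(seq) - 1) + 1):
            dfs(j, prefix + (seq[j],))

    for i, item in enumerate(seq):
        dfs(i, (item,))
    return out


def is_subsequence(short, long) -> bool:
    it = iter(long)
    return all(any(x == y for y in it) for x in short)


def brute_force_closed(sequences: dict, min_support: int, gap: GapConstraint):
    """{pattern: (support, supporting ids)} of the closed frequent set."""
    per_seq = {sid: feasible_subsequences(tuple(s), gap) for sid, s in sequences.items()}
    counts: dict[tuple[str, ...], set] = {}
    for sid, pats in per_seq.items():
        for p in pats:
            counts.setdefault(p, set()).add(sid)
    frequent = {p: ids for p, ids in counts.items() if len(ids) >= min_support}
    closed = {}
    for p, ids in frequent.items():
        absorbed = any(
            len(q) > len(p) and len(qids) == len(ids) and is_subsequence(p, q)
            for q, qids in frequent.items()
        )
        if not absorbed:
            closed[p] = (len(ids), frozenset(ids))
    return closed
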