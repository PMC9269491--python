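"""Gap-constrained closed frequent sequential pattern mining.

Mines the closed frequent activity sequences of a corpus of per-period
label sequences, in the Gap-BIDE family: between two consecutive pattern
elements at least ``gap_min`` and at most ``gap_max`` non-pattern items may
intervene. Support is *document-based* — the number of input sequences
containing at least one gap-feasible occurrence — which matches counting
the number of days on which a behavioural pattern repeats.

A frequent pattern is *closed* when no frequent super-sequence has the
same support; non-closed patterns carry no extra information (they are
absorbed by a longer pattern occurring on exactly the same days).

The miner grows patterns over projected occurrence lists (the classic
pattern-growth scheme: document support can only shrink when a pattern is
extended, so sub-threshold branches are pruned) and applies a closure
post-filter. Output order is canonical: by pattern length, then
lexicographically by labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

__all__ = ["GapConstraint", "Pattern", "occurs", "mine_patterns", "mine_per_period"]


@dataclass(frozen=True)
class GapConstraint:
    """Allowed number of interleaved items between consecutive pattern
    elements: at least ``gap_min`` and at most ``gap_max``."""

    gap_min: int = 0
    gap_max: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gap_min <= self.gap_max):
            raise ValueError(f"need 0 <= gap_min <= gap_max, got {self}")


@dataclass(frozen=True)
class Pattern:
    """A closed frequent sequence of activity labels."""

    labels: tuple[str, ...]
    support: int
    supporting_ids: frozenset = field(compare=False)

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("pattern labels must be non-empty")
        if self.support != len(self.supporting_ids):
            raise ValueError("support must equal the number of supporting ids")


def occurs(
    pattern_labels: Sequence[str], sequence: Sequence[str], gap: GapConstraint
) -> bool:
    """True iff the pattern embeds in the sequence under the gap constraint.

    An embedding is a strictly increasing index tuple matching the pattern
    label-for-label with ``gap_min <= i_{j+1} - i_j - 1 <= gap_max`` between
    consecutive matched positions.
    """
    if not pattern_labels:
        raise ValueError("pattern must be non-empty")
    ends = [i for i, item in enumerate(sequence) if item == pattern_labels[0]]
    for label in pattern_labels[1:]:
        if not ends:
            return False
        ends = _advance(ends, label, sequence, gap)
    return bool(ends)


def _advance(
    ends: list[int], label: str, sequence: Sequence[str], gap: GapConstraint
) -> list[int]:
    """End positions of embeddings extended by one more matched label."""
    out: list[int] = []
    for j, item in enumerate(sequence):
        if item != label:
            continue
        # feasible iff some current end i satisfies gap_min <= j-i-1 <= gap_max
        lo, hi = j - 1 - gap.gap_max, j - 1 - gap.gap_min
        if any(lo <= i <= hi for i in ends):
            out.append(j)
    return out


def mine_patterns(
    sequences: Mapping[Hashable, Sequence[str]],
    min_support: int,
    gap: GapConstraint = GapConstraint(0, 0),
    min_length: int = 1,
) -> list[Pattern]:
    """Mine all closed frequent patterns of a sequence corpus.

    Parameters
    ----------
    sequences
        Mapping from a sequence identifier (e.g. a day) to its label
        sequence.
    min_support
        Minimum number of sequences a pattern must occur in (>= 1).
    gap
        Gap constraint between consecutive pattern elements.
    min_length
        Minimum emitted pattern length (single frequent activities are
        patterns by default).

    Returns
    -------
    Canonically ordered list (length, then lexicographic) of the frequent
    patterns with no same-support frequent super-sequence.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    items = {seq[i] for seq in sequences.values() for i in range(len(seq))}
    frequent: list[tuple[tuple[str, ...], frozenset]] = []

    def grow(labels: tuple[str, ...], ends_by_seq: dict) -> None:
        frequent.append((labels, frozenset(ends_by_seq)))
        # candidate extensions: any item occurring in a feasible window
        candidates: dict[str, dict] = {}
        for sid, ends in ends_by_seq.items():
            seq = sequences[sid]
            for label in items:
                new_ends = _advance(ends, label, seq, gap)
                if new_ends:
                    candidates.setdefault(label, {})[sid] = new_ends
        for label in sorted(candidates):
            ext = candidates[label]
            if len(ext) >= min_support:
                grow(labels + (label,), ext)

    for label in sorted(items):
        starts = {
            sid: [i for i, it in enumerate(seq) if it == label]
            for sid, seq in sequences.items()
        }
        starts = {sid: pos for sid, pos in starts.items() if pos}
        if len(starts) >= min_support:
            grow((label,), starts)

    return _closed(frequent, min_length)


def _is_subsequence(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    it = iter(long)
    return all(any(x == y for y in it) for x in short)


def _closed(
    frequent: list[tuple[tuple[str, ...], frozenset]], min_length: int
) -> list[Pattern]:
    """Drop patterns absorbed by a same-support frequent super-sequence."""
    by_support: dict[int, list[tuple[tuple[str, ...], frozenset]]] = {}
    for labels, ids in frequent:
        by_support.setdefault(len(ids), []).append((labels, ids))
    out: list[Pattern] = []
    for support, group in by_support.items():
        for labels, ids in group:
            if len(labels) < min_length:
                continue
            absorbed = any(
                len(other) > len(labels) and _is_subsequence(labels, other)
                for other, _ in group
            )
            if not absorbed:
                out.append(Pattern(labels, support, ids))
    out.sort(key=lambda p: (len(p.labels), p.labels))
    return out


def mine_per_period(
    period_sequences: Mapping[str, Mapping[Hashable, Sequence[str]]],
    min_support: int,
    gap: GapConstraint = GapConstraint(0, 0),
    min_length: int = 1,
) -> dict[str, list[Pattern]]:
    """Mine each day-period's corpus independently.

    ``period_sequences`` maps a period tag to its ``{sequence id: labels}``
    corpus; empty corpora yield empty pattern lists.
    """
    return {
        period: (mine_patterns(seqs, min_support, gap, min_length) if seqs else [])
        for period, seqs in period_sequences.items()
    }


def patterns_to_json(patterns_by_period: Mapping[str, Sequence[Pattern]]) -> list[dict]:
    """JSON-serialisable pattern dump."""
    return [
        {
            "period": period,
            "labels": list(p.labels),
            "support": p.support,
            "days": sorted(str(d) for d in p.supporting_ids),
        }
        for period, pats in patterns_by_period.items()
        for p in pats
    ]
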