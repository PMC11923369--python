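"""Longest common contiguous segments across paralog sequences.

The reported conserved segments are contiguous runs shared verbatim by every
input sequence (exact matching, case-sensitive, no ambiguity-code expansion),
so the detector is a generalized longest-common-substring search: a suffix
automaton is built over the first sequence and every other sequence is swept
through it, keeping per-state the longest match it achieves; the per-state
minimum over sequences bounds the longest substring common to all.  A
brute-force enumeration oracle lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SegmentHit",
    "longest_common_segments",
    "percent_identity",
    "map_segment",
]


@dataclass(frozen=True)
class SegmentHit:
    """A common segment with its 1-based inclusive coordinates per sequence."""

    segment: str
    positions: tuple[tuple[int, int], ...]  # (start, end) in each input sequence
    sequence_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.segment)

    def to_dict(self) -> dict:
        row = {"segment": self.segment, "length": self.length}
        for sid, (start, end) in zip(self.sequence_ids, self.positions):
            row[f"{sid}_start"] = start
            row[f"{sid}_end"] = end
        return row


class _SuffixAutomaton:
    """Suffix automaton of one string (online construction)."""

    def __init__(self, s: str) -> None:
        self.link = [-1]
        self.length = [0]
        self.first_end = [0]      # end index (exclusive) of first occurrence
        self.next: list[dict[str, int]] = [{}]
        last = 0
        for i, ch in enumerate(s):
            cur = self._new_state(self.length[last] + 1, i + 1)
            p = last
            while p != -1 and ch not in self.next[p]:
                self.next[p][ch] = cur
                p = self.link[p]
            if p == -1:
                self.link[cur] = 0
            else:
                q = self.next[p][ch]
                if self.length[p] + 1 == self.length[q]:
                    self.link[cur] = q
                else:
                    clone = self._new_state(self.length[p] + 1, self.first_end[q])
                    self.next[clone] = dict(self.next[q])
                    self.link[clone] = self.link[q]
                    while p != -1 and self.next[p].get(ch) == q:
                        self.next[p][ch] = clone
                        p = self.link[p]
                    self.link[q] = clone
                    self.link[cur] = clone
            last = cur
        self.last = last

    def _new_state(self, length: int, first_end: int) -> int:
        self.link.append(-1)
        self.length.append(length)
        self.first_end.append(first_end)
        self.next.append({})
        return len(self.link) - 1

    def states_by_length(self) -> list[int]:
        return sorted(range(len(self.length)), key=self.length.__getitem__)

    def match_lengths(self, other: str) -> list[int]:
        """Per-state longest substring of the base string ending at that state
        that also occurs in ``other``."""
        best = [0] * len(self.length)
        state, length = 0, 0
        for ch in other:
            while state != 0 and ch not in self.next[state]:
                state = self.link[state]
                length = self.length[state]
            if ch in self.next[state]:
                state = self.next[state][ch]
                length += 1
            else:
                state, length = 0, 0
            if length > best[state]:
                best[state] = length
        # propagate down the suffix-link tree (shorter suffixes also match)
        for v in reversed(self.states_by_length()):
            p = self.link[v]
            if p >= 0 and best[v] > 0:
                best[p] = max(best[p], min(best[v], self.length[p]))
        return best


def longest_common_segments(sequences: Sequence[str] | Sequence[tuple[str, str]],
                            min_len: int = 1,
                            top_n: int = 1) -> list[SegmentHit]:
    """Longest contiguous segment(s) present verbatim in ALL input sequences.

    ``sequences`` is a list of strings or of ``(id, sequence)`` pairs.  All
    ties at the winning length are returned; ``top_n > 1`` additionally
    returns hits at the next distinct lengths.  Every hit is re-verified
    against every sequence before being returned.
    """
    if sequences and isinstance(sequences[0], (tuple, list)):
        ids = tuple(str(s[0]) for s in sequences)
        seqs = [str(s[1]) for s in sequences]
    else:
        seqs = [str(s) for s in sequences]
        ids = tuple(f"seq{i + 1}" for i in range(len(seqs)))
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for i, s in enumerate(seqs):
        if not s:
            raise ValueError(f"sequence {ids[i]} is empty")

    sam = _SuffixAutomaton(seqs[0])
    per_state = np.array([sam.match_lengths(s) for s in seqs[1:]])
    common = per_state.min(axis=0)  # per state: longest common run ending there

    candidates: dict[str, int] = {}
    for state in range(1, len(sam.length)):
        run = int(min(common[state], sam.length[state]))
        if run >= min_len:
            end = sam.first_end[state]
            seg = seqs[0][end - run:end]
            candidates[seg] = max(candidates.get(seg, 0), run)
    if not candidates:
        return []
    # drop candidates that are substrings of a longer candidate of the same run
    lengths = sorted({len(s) for s in candidates}, reverse=True)[:top_n]
    hits = []
    for seg in sorted(candidates, key=lambda s: (-len(s), s)):
        if len(seg) not in lengths:
            continue
        occurrences = [map_segment(seg, s) for s in seqs]
        if any(not occ for occ in occurrences):  # self-check pass
            continue
        hits.append(SegmentHit(
            segment=seg,
            positions=tuple(occ[0] for occ in occurrences),
            sequence_ids=ids))
    return hits


def map_segment(segment: str, sequence: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrences, 1-based inclusive coordinates."""
    if not segment:
        raise ValueError("segment must be non-empty")
    out = []
    start = sequence.find(segment)
    while start != -1:
        out.append((start + 1, start + len(segment)))
        start = sequence.find(segment, start + 1)
    return out


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # end gaps are free, the standard global-alignment default for comparing
    # full-length homologs of slightly different lengths
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def percent_identity(seq_a: str, seq_b: str,
                     alignment_mode: str = "ungapped") -> float:
    """Percent identity between two sequences.

    ``ungapped``: position-wise matches over the (equal) length.
    ``global``: matches over all aligned columns of a global alignment
    (BLOSUM62, gap open 10 / extend 0.5); gap columns count as mismatches.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if alignment_mode == "ungapped":
        if len(seq_a) != len(seq_b):
            raise ValueError("ungapped mode requires equal-length sequences")
        matches = sum(a == b for a, b in zip(seq_a, seq_b))
        return 100.0 * matches / len(seq_a)
    if alignment_mode != "global":
        raise ValueError("alignment_mode must be 'ungapped' or 'global'")
    alignment = _global_aligner().align(seq_a, seq_b)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    matches = sum(a == b and a != "-" for a, b in zip(a_row, b_row))
    return 100.0 * matches / len(a_row)
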