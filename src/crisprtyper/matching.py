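"""Approximate string matching helpers built on edlib.

edlib reports only the best-scoring locations of a pattern, so occurrences
of different quality are recovered iteratively: find the current best hit,
mask it out, repeat until nothing matches within the edit budget. Overlaps
are thereby resolved greedily by ascending edit distance, ties by leftmost
position — a deterministic rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_MASK_CHAR = "#"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Occurrence:
    """One approximate occurrence of a pattern in a text (end exclusive)."""

    start: int
    end: int
    dist: int


def best_occurrence(pattern: str, text: str, max_edits: int) -> Occurrence | None:
    """Leftmost best-scoring occurrence of ``pattern`` in ``text``, or None."""
    if not text:
        return None
    res = edlib.align(pattern, text, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1:
        return None
    locs = [(s if s is not None else 0, e) for s, e in res["locations"]]
    start, end = min(locs)
    return Occurrence(start=start, end=end + 1, dist=res["editDistance"])


def find_occurrences(pattern: str, text: str, max_edits: int) -> list[Occurrence]:
    """All non-overlapping occurrences, greedily by ascending edit distance.

    Returned sorted by start position.
    """
    masked = list(text)
    hits: list[Occurrence] = []
    while True:
        occ = best_occurrence(pattern, "".join(masked), max_edits)
        if occ is None:
            break
        hits.append(occ)
        for i in range(occ.start, occ.end):
            masked[i] = _MASK_CHAR
    return sorted(hits, key=lambda o: o.start)


def edit_distance(a: str, b: str) -> int:
    """Global (Needleman-Wunsch) Levenshtein distance."""
    return edlib.align(a, b, mode="NW")["editDistance"]


def identity(a: str, b: str) -> float:
    """1 - edits / length of the longer sequence."""
    return 1.0 - edit_distance(a, b) / max(len(a), len(b))
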