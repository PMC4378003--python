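"""Coordinate projection across sequence-editing stages.

Each refinement stage replaces intervals of its input sequences with new
content; a :class:`CoordinateMap` records those edits so positions in the
stage's input can be projected into its output (used when scoring recovery
against a ground-truth ledger whose loci are in draft coordinates).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Edit:
    seq_id: str
    start: int  # interval replaced, in input coordinates
    end: int
    new_len: int

    @property
    def delta(self) -> int:
        return self.new_len - (self.end - self.start)


@dataclass
class CoordinateMap:
    edits: list[Edit] = field(default_factory=list)

    def add(self, seq_id: str, start: int, end: int, new_len: int) -> None:
        self.edits.append(Edit(seq_id, start, end, new_len))

    def _per_seq(self, seq_id: str) -> tuple[list[int], list[int], list[Edit]]:
        es = sorted((e for e in self.edits if e.seq_id == seq_id), key=lambda e: e.start)
        starts = [e.start for e in es]
        cum = []
        total = 0
        for e in es:
            total += e.delta
            cum.append(total)
        return starts, cum, es

    def project(self, seq_id: str, pos: int) -> int | None:
        """Project an input position to the output; None inside a replaced interval."""
        starts, cum, es = self._per_seq(seq_id)
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return pos
        e = es[i]
        if pos < e.end:  # inside a replaced interval
            return None
        return pos + cum[i]

    def compose(self, later: "CoordinateMap") -> "_ComposedMap":
        return _ComposedMap([self, later])


class _ComposedMap:
    def __init__(self, maps):
        self.maps = list(maps)

    def project(self, seq_id: str, pos: int) -> int | None:
        for m in self.maps:
            pos = m.project(seq_id, pos)
            if pos is None:
                return None
        return pos

    def compose(self, later) -> "_ComposedMap":
        return _ComposedMap(self.maps + [later])
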