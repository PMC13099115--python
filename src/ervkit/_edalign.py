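"""Fast infix (query-in-target) alignment via edlib, with column bookkeeping.

edlib's bit-parallel edit-distance alignment is used wherever a query must be
located inside a (much longer) subject: homology-search windows, LTR and
gene/peptide annotation. The extended cigar is expanded into per-column
arrays so callers can trim terminal noise, map alignment columns back to
query/subject coordinates, and compute identity under their own rules.

Column op codes: 0 '=' match, 1 'X' mismatch, 2 'I' query-only (deletion in
the subject relative to the query), 3 'D' subject-only (insertion in the
subject).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_CIGAR = re.compile(r"(\d+)([=XID])")
MATCH, MISMATCH, QGAP, TGAP = 0, 1, 2, 3
_OPCODE = {"=": MATCH, "X": MISMATCH, "I": QGAP, "D": TGAP}


@dataclass
class EdAlignment:
    ops: np.ndarray        # per-column op codes
    q_off: np.ndarray      # query offset at the start of each column
    t_off: np.ndarray      # subject offset (absolute) at the start of each column
    qlen: int

    @property
    def match(self) -> np.ndarray:
        return self.ops == MATCH

    def counts(self, lo: int = 0, hi: int | None = None) -> tuple[int, int, int, int]:
        """(matches, mismatches, query-gap cols, subject-gap cols) in [lo,hi)."""
        sub = self.ops[lo: hi if hi is not None else self.ops.size]
        return (int((sub == MATCH).sum()), int((sub == MISMATCH).sum()),
                int((sub == QGAP).sum()), int((sub == TGAP).sum()))

    def q_range(self, lo: int, hi: int) -> tuple[int, int]:
        q1 = self.q_off[hi] if hi < self.ops.size else \
            int(self.q_off[-1] + (self.ops[-1] != TGAP))
        return int(self.q_off[lo]), int(q1)

    def t_range(self, lo: int, hi: int) -> tuple[int, int]:
        t1 = self.t_off[hi] if hi < self.ops.size else \
            int(self.t_off[-1] + (self.ops[-1] != QGAP))
        return int(self.t_off[lo]), int(t1)

    def score(self, lo: int, hi: int, match: int = 1, mismatch: int = -2,
              gap_open: int = -5, gap_extend: int = -2) -> float:
        sub = self.ops[lo:hi]
        s = match * int((sub == MATCH).sum()) + mismatch * int((sub == MISMATCH).sum())
        is_gap = (sub == QGAP) | (sub == TGAP)
        if is_gap.any():
            starts = int(is_gap[0]) + int((is_gap[1:] & ~is_gap[:-1]).sum())
            total = int(is_gap.sum())
            s += starts * gap_open + (total - starts) * gap_extend
        return float(s)

    def best_local_segment(self, match: int = 1, mismatch: int = -2,
                           gap_open: int = -5, gap_extend: int = -2
                           ) -> tuple[int, int]:
        """Maximal-scoring contiguous column interval [lo,hi).

        Scoring the expanded columns and taking the best subarray recovers
        local-alignment semantics from the semi-global placement: flanking
        noise (negative expected score) is trimmed, internal gaps are bridged
        only when both sides outweigh the gap cost."""
        ops = self.ops
        scores = np.where(ops == MATCH, float(match),
                          np.where(ops == MISMATCH, float(mismatch),
                                   float(gap_extend)))
        is_gap = (ops == QGAP) | (ops == TGAP)
        run_start = is_gap & ~np.concatenate([[False], is_gap[:-1]])
        scores[run_start] += gap_open - gap_extend
        S = np.concatenate([[0.0], np.cumsum(scores)])
        run_min = np.minimum.accumulate(S[:-1])
        gains = S[1:] - run_min
        hi = int(np.argmax(gains)) + 1
        if gains[hi - 1] <= 0:
            return 0, 0
        lo = int(np.argmin(S[:hi]))
        return lo, hi


def infix_align(query: str, target: str) -> EdAlignment | None:
    """Best semi-global placement of `query` inside `target` (None if degenerate)."""
    if not query or not target:
        return None
    r = edlib.align(query, target, mode="HW", task="path")
    if r["editDistance"] < 0 or not r.get("cigar"):
        return None
    t_start = r["locations"][0][0]
    if t_start is None:
        t_start = 0
    runs = [(int(n), _OPCODE[op]) for n, op in _CIGAR.findall(r["cigar"])]
    total = sum(n for n, _ in runs)
    ops = np.empty(total, dtype=np.uint8)
    i = 0
    for n, code in runs:
        ops[i: i + n] = code
        i += n
    dq = (ops != TGAP).astype(np.int64)
    dt = (ops != QGAP).astype(np.int64)
    q_off = np.concatenate([[0], np.cumsum(dq)[:-1]])
    t_off = np.concatenate([[0], np.cumsum(dt)[:-1]]) + t_start
    return EdAlignment(ops=ops, q_off=q_off, t_off=t_off, qlen=len(query))
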