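"""Inverted-repeat (candidate stem-loop) detection within single ESTs.

The detector plays the role einverted plays in EST surveys: a gapped local
alignment of the sequence against its own reverse complement, where an
alignment column pairs a left-arm base with a complementary right-arm base.
Scoring defaults (match +3, mismatch -4, gap -12 per position, report
threshold 50) follow einverted's defaults.

Overlapping hits are reduced to a non-overlapping set by iterated
best-hit extraction: the top-scoring eligible repeat is reported, its arm
positions are masked out, and the search repeats until nothing reaches the
score threshold.  All coordinates are 0-based half-open; serialized reports
are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import ESTRecord, revcomp

_NEG = -(10**9)  # masking sentinel score


@dataclass(frozen=True)
class IRParams:
    min_total_span: int = 30
    match_score: int = 3
    mismatch_score: int = -4
    gap_penalty: int = -12  # per gap position (linear)
    min_score: int = 50
    max_loop: int = 300

    def __post_init__(self) -> None:
        if self.min_total_span < 1 or self.max_loop < 0:
            raise ValueError("min_total_span >= 1 and max_loop >= 0 required")
        if self.match_score <= 0 or self.mismatch_score >= 0 or self.gap_penalty >= 0:
            raise ValueError("expected match > 0, mismatch < 0, gap < 0")


@dataclass(frozen=True)
class InvertedRepeat:
    """One inverted repeat: two arms on the same EST enclosing a loop."""

    est_id: str
    left_arm: tuple[int, int]  # [start, end) on the EST
    right_arm: tuple[int, int]
    loop_len: int
    score: int
    arm_identity: float

    @property
    def span(self) -> int:
        return self.right_arm[1] - self.left_arm[0]


def _score_matrix_rows(
    s_codes: np.ndarray, r_codes: np.ndarray, match: int, mismatch: int
) -> np.ndarray:
    """Per-row substitution scores: row i gives score of s[i] vs every r[j].

    N (code 4) never matches anything, including another N.
    """
    eq = s_codes[:, None] == r_codes[None, :]
    eq &= s_codes[:, None] != 4
    return np.where(eq, match, mismatch).astype(np.int64)


_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODES[c] for c in seq), dtype=np.int8, count=len(seq))


def _sw_matrix(sub: np.ndarray, gap: int, row_ok: np.ndarray, col_ok: np.ndarray) -> np.ndarray:
    """Smith-Waterman with linear gaps; masked rows/columns are zeroed so no
    alignment can include a masked residue.  Returns H of shape (n+1, m+1)."""
    n, m = sub.shape
    gp = -gap
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    jarr = gp * np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        prev = H[i - 1]
        e = np.zeros(m + 1, dtype=np.int64)
        np.maximum(prev[:-1] + sub[i - 1], prev[1:] - gp, out=e[1:])
        np.maximum(e, 0, out=e)
        # horizontal gap chain via prefix max: H[j] = max_k<=j e[k] - gp*(j-k)
        row = np.maximum.accumulate(e + jarr) - jarr
        if not row_ok[i - 1]:
            row[:] = 0
        else:
            row[1:][~col_ok] = 0
        H[i] = row
    return H


def _traceback(
    H: np.ndarray, sub: np.ndarray, gap: int, i: int, j: int
) -> tuple[int, int, int, int]:
    """Walk back from endpoint (i, j); returns (i0, j0, n_columns, n_matches)."""
    ncol = nmatch = 0
    while H[i, j] > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            ncol += 1
            if sub[i - 1, j - 1] > 0:
                nmatch += 1
            i -= 1
            j -= 1
        elif i > 0 and h == H[i - 1, j] + gap:
            ncol += 1
            i -= 1
        elif j > 0 and h == H[i, j - 1] + gap:
            ncol += 1
            j -= 1
        else:  # pragma: no cover - integer DP cannot reach here
            raise AssertionError("inconsistent traceback")
    return i, j, ncol, nmatch


def find_inverted_repeats(
    est: ESTRecord, params: IRParams = IRParams()
) -> list[InvertedRepeat]:
    """All non-overlapping inverted repeats of ``est`` scoring >= min_score.

    Eligible endpoints additionally satisfy ``0 <= loop <= max_loop`` and
    total span >= ``min_total_span``.  Output is ordered by left-arm start.
    """
    n = est.length
    if n < params.min_total_span:
        return []
    s = est.seq
    r = revcomp(s)
    s_codes = _encode(s)
    r_codes = _encode(r)
    sub = _score_matrix_rows(s_codes, r_codes, params.match_score, params.mismatch_score)
    masked = np.zeros(n, dtype=bool)  # positions of s already used by an accepted IR

    hits: list[InvertedRepeat] = []
    while True:
        row_ok = ~masked
        col_ok = ~masked[::-1]  # r[j] is s[n-1-j]
        H = _sw_matrix(sub, params.gap_penalty, row_ok, col_ok)
        # eligible endpoints: score, loop window
        ii, jj = np.nonzero(H >= params.min_score)
        if ii.size == 0:
            break
        loops = n - jj - ii
        ok = (loops >= 0) & (loops <= params.max_loop)
        ii, jj = ii[ok], jj[ok]
        if ii.size == 0:
            break
        order = np.lexsort((jj, ii, -H[ii, jj]))
        accepted = None
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            i0, j0, ncol, nmatch = _traceback(H, sub, params.gap_penalty, i, j)
            left = (i0, i)
            right = (n - j, n - j0)
            span = right[1] - left[0]
            if span < params.min_total_span:
                continue
            if i <= i0 or j <= j0:
                continue
            accepted = InvertedRepeat(
                est_id=est.id,
                left_arm=left,
                right_arm=right,
                loop_len=n - j - i,
                score=int(H[i, j]),
                arm_identity=nmatch / ncol,
            )
            break
        if accepted is None:
            break
        hits.append(accepted)
        masked[accepted.left_arm[0] : accepted.left_arm[1]] = True
        masked[accepted.right_arm[0] : accepted.right_arm[1]] = True
    hits.sort(key=lambda h: (h.left_arm[0], h.right_arm[0]))
    return hits


def write_ir_tsv(hits: Sequence[InvertedRepeat], path: str | Path) -> None:
    """TSV report; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(
            "est_id\tleft_start\tleft_end\tright_start\tright_end\t"
            "loop_len\tscore\tarm_identity\n"
        )
        for h in hits:
            fh.write(
                f"{h.est_id}\t{h.left_arm[0] + 1}\t{h.left_arm[1]}\t"
                f"{h.right_arm[0] + 1}\t{h.right_arm[1]}\t{h.loop_len}\t"
                f"{h.score}\t{h.arm_identity:.4f}\n"
            )


def write_ir_gff3(hits: Sequence[InvertedRepeat], path: str | Path) -> None:
    """GFF3 report: one ``inverted_repeat`` parent with two arm children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, h in enumerate(hits):
            pid = f"ir{k:05d}"
            fh.write(
                f"{h.est_id}\tmircos\tinverted_repeat\t{h.left_arm[0] + 1}\t"
                f"{h.right_arm[1]}\t{h.score}\t.\t.\tID={pid}\n"
            )
            for arm_name, arm in (("left", h.left_arm), ("right", h.right_arm)):
                fh.write(
                    f"{h.est_id}\tmircos\trepeat_unit\t{arm[0] + 1}\t{arm[1]}\t"
                    f".\t.\t.\tID={pid}.{arm_name};Parent={pid}\n"
                )
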