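"""Conserved orthologous sequence (COS) detection between two EST datasets.

A desk-scale re-implementation of the BLASTn role in the pipeline: exact
word seeding, banded gapped extension (Smith-Waterman-Gotoh restricted to a
diagonal band around the seed, with x-drop early termination) and
Karlin-Altschul E-values.  A region qualifies as COS when the alignment
spans at least ``min_cos_length`` columns (gaps included, matching how BLAST
reports alignment length), exceeds ``min_identity`` and beats
``evalue_cos``.

E-values use ungapped lambda/K with gapped scores — a documented
approximation, acceptable because E serves only as a pass/fail threshold
here.  Gap cost convention: a gap of length g costs
``|gap_open| + g*|gap_extend|`` (existence + per-residue extension).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .seqio import ESTRecord

_NEG = -(10**9)


@dataclass(frozen=True)
class CosParams:
    word_size: int = 12
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5  # gap existence
    gap_extend: int = -2  # per gap position
    evalue_discovery: float = 1e-4
    evalue_cos: float = 1e-10
    min_cos_length: int = 400  # alignment columns, gaps included
    min_identity: float = 0.75
    band: int = 32  # half-width of the extension band around the seed diagonal
    xdrop: int = 20

    def __post_init__(self) -> None:
        if self.min_cos_length <= 0 or not 0 < self.min_identity <= 1:
            raise ValueError("bad COS thresholds")
        if self.evalue_cos > self.evalue_discovery:
            raise ValueError("evalue_cos must be <= evalue_discovery")


@dataclass(frozen=True)
class KarlinAltschulParams:
    lam: float
    K: float

    def evalue(self, score: int, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


def compute_karlin_altschul(
    match: int,
    mismatch: int,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    max_terms: int = 200,
) -> KarlinAltschulParams:
    """Ungapped Karlin-Altschul lambda and K for a match/mismatch scheme.

    lambda solves ``sum_ij p_i p_j exp(lambda s_ij) = 1`` by bracketed
    root-finding (tolerance 1e-12); K uses the standard lattice-case series

        K = delta * lambda * exp(-2 sigma) / (H * (1 - exp(-lambda*delta)))
        sigma = sum_k (1/k) [ E(e^{lambda S_k}; S_k < 0) + P(S_k >= 0) ]

    where S_k is the k-column random-walk score (distributions obtained by
    convolution) and delta the lattice span of the scores.  The series is
    truncated when a term falls below 1e-12 (terms decay geometrically) or
    at ``max_terms``.  Requires a negative expected per-column score.
    """
    p = np.asarray(base_freqs, dtype=float)
    if abs(p.sum() - 1) > 1e-9 or (p < 0).any():
        raise ValueError("base_freqs must be a probability vector")
    p_match = float((p**2).sum())
    expected = p_match * match + (1 - p_match) * mismatch
    if expected >= 0:
        raise ValueError("expected per-column score must be negative")
    if match <= 0:
        raise ValueError("match score must be positive")

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * match)
            + (1 - p_match) * math.exp(lam * mismatch)
            - 1.0
        )

    hi = 1.0
    while f(hi) < 0:
        hi *= 2
    lam = float(brentq(f, 1e-9, hi, xtol=1e-12))

    delta = math.gcd(match, abs(mismatch))
    lo_s = min(mismatch, 0)
    width = max(match, 0) - lo_s + 1
    pmf1 = np.zeros(width)
    pmf1[match - lo_s] = p_match
    pmf1[mismatch - lo_s] = 1 - p_match
    H = lam * (
        p_match * match * math.exp(lam * match)
        + (1 - p_match) * mismatch * math.exp(lam * mismatch)
    )

    sigma = 0.0
    pmf_k = pmf1.copy()
    offset = lo_s
    for k in range(1, max_terms + 1):
        values = offset + np.arange(pmf_k.size)
        neg = values < 0
        term = (
            float((pmf_k[neg] * np.exp(lam * values[neg])).sum())
            + float(pmf_k[~neg].sum())
        ) / k
        sigma += term
        if term < 1e-12:
            break
        pmf_k = np.convolve(pmf_k, pmf1)
        offset += lo_s
    K = delta * lam * math.exp(-2 * sigma) / (H * (1 - math.exp(-lam * delta)))
    return KarlinAltschulParams(lam=lam, K=float(K))


@dataclass
class CosRegion:
    """One aligned homologous region between an EST pair.

    ``colmap_a``/``colmap_b`` hold the aligned (non-gap) column coordinates
    as parallel monotone position arrays on a and b.
    """

    id: str
    est_a: str
    est_b: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    aligned_length: int  # alignment columns, gaps included
    n_matches: int
    score: int
    evalue: float
    colmap_a: np.ndarray
    colmap_b: np.ndarray

    @property
    def identity(self) -> float:
        return self.n_matches / self.aligned_length

    def project(self, interval: tuple[int, int]) -> tuple[int, int]:
        """Map an interval on a (within ``interval_a``) to b coordinates.

        Positions deleted in b collapse to the nearest aligned boundary;
        the projection of the full ``interval_a`` equals ``interval_b``.
        """
        return _project(self.colmap_a, self.colmap_b, interval, self.interval_a)

    def project_inverse(self, interval: tuple[int, int]) -> tuple[int, int]:
        return _project(self.colmap_b, self.colmap_a, interval, self.interval_b)


def _project(
    src: np.ndarray,
    dst: np.ndarray,
    interval: tuple[int, int],
    bounds: tuple[int, int],
) -> tuple[int, int]:
    start, end = interval
    if start < bounds[0] or end > bounds[1] or start >= end:
        raise ValueError(f"interval {interval} outside COS {bounds}")
    i = int(np.searchsorted(src, start, side="left"))
    j = int(np.searchsorted(src, end - 1, side="right")) - 1
    if j < i:  # interval falls entirely inside a deletion: collapse
        k = min(i, len(dst) - 1)
        return (int(dst[k]), int(dst[k]))
    return (int(dst[i]), int(dst[j]) + 1)


_CODEMAP = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODEMAP[c] for c in seq), dtype=np.int8, count=len(seq))


@dataclass
class Hsp:
    """A high-scoring pair from one banded extension (pre-filter)."""

    score: int
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    aligned_length: int
    n_matches: int
    colmap_a: np.ndarray
    colmap_b: np.ndarray


def banded_extend(a: str, b: str, diag: int, params: CosParams) -> Hsp | None:
    """Best local gapped alignment of a vs b within the band around ``diag``.

    Returns None when nothing scores above zero.  Row processing stops once
    the running row maximum drops ``xdrop`` below the best score seen.
    """
    la, lb = len(a), len(b)
    ac, bc = _encode(a), _encode(b)
    W = 2 * params.band + 1
    # diag = (a position) - (b position); aligned cells satisfy j = i - diag
    off0 = -diag - params.band  # j = i + off0 + w
    open_cost = -params.gap_open + -params.gap_extend  # first gap residue
    ext = -params.gap_extend
    Hm = np.full((la + 1, W), _NEG, dtype=np.int64)
    Fm = np.full((la + 1, W), _NEG, dtype=np.int64)
    Cm = np.full((la + 1, W), _NEG, dtype=np.int64)
    warr = np.arange(W)
    best = 0
    best_cell: tuple[int, int] | None = None
    for i in range(la + 1):
        j = i + off0 + warr
        inb = (j >= 0) & (j <= lb)
        if not inb.any():
            if i > 0 and (i + off0) > lb:
                break
            continue
        if i == 0:
            row = np.where(inb, 0, _NEG)
            Hm[0] = row
            Cm[0] = row
            continue
        jj = j - 1
        okd = inb & (jj >= 0) & (jj < lb)
        jcl = np.clip(jj, 0, lb - 1)
        bcj = bc[jcl]
        ai = int(ac[i - 1])
        sc = np.where((bcj == ai) & (ai != 4) & (bcj != 4),
                      params.match, params.mismatch)
        sub = np.where(okd, Hm[i - 1] + sc, _NEG)
        F = np.full(W, _NEG, dtype=np.int64)
        F[:-1] = np.maximum(Hm[i - 1, 1:] - open_cost, Fm[i - 1, 1:] - ext)
        C = np.maximum.reduce([sub, F, np.where(inb, 0, np.int64(_NEG))])
        # horizontal gap chain via prefix max (single-open gaps dominate)
        T = np.maximum.accumulate(C + ext * warr)
        row = np.maximum(C, T - ext * warr - open_cost + ext)
        row[~inb] = _NEG
        Hm[i] = row
        Fm[i] = F
        Cm[i] = C
        rmax = int(row.max())
        if rmax > best:
            best = rmax
            best_cell = (i, int(row.argmax()))
        if best > 0 and rmax < best - params.xdrop:
            break
    if best_cell is None:
        return None

    # traceback (integer scores: exact equality tests)
    i, w = best_cell
    cols: list[tuple[str, int, int]] = []  # (op, a_idx, b_idx); -1 = gap
    state = "H"
    while True:
        if state == "F":
            v = Fm[i, w]
            cols.append(("D", i - 1, -1))
            if w + 1 < W and v == Hm[i - 1, w + 1] - open_cost:
                state = "H"
            i, w = i - 1, w + 1
            continue
        v = Hm[i, w]
        if v <= 0:
            break
        if v > Cm[i, w]:
            # horizontal chain: walk left to the opening cell
            g = open_cost
            w2 = w - 1
            while w2 >= 0:
                j2 = i + off0 + w2
                cols.append(("I", -1, j2))
                if Cm[i, w2] - g == v:
                    break
                g += ext
                w2 -= 1
            if w2 < 0:  # pragma: no cover - integer DP cannot reach here
                raise AssertionError("inconsistent gap traceback")
            w = w2
            continue
        # v == Cm[i, w]: substitution, vertical gap, or fresh start
        j = i + off0 + w
        if i > 0 and j > 0 and Cm[i, w] == Hm[i - 1, w] + (
            params.match
            if (ac[i - 1] == bc[j - 1] and ac[i - 1] != 4 and bc[j - 1] != 4)
            else params.mismatch
        ):
            cols.append(("M", i - 1, j - 1))
            i -= 1
            continue
        if Cm[i, w] == Fm[i, w] and Fm[i, w] > _NEG // 2:
            state = "F"
            continue
        break  # fresh start (v == 0)
    cols.reverse()
    if not cols:
        return None
    a_idx = [c[1] for c in cols if c[1] >= 0]
    b_idx = [c[2] for c in cols if c[2] >= 0]
    ca = np.array([c[1] for c in cols if c[0] == "M"], dtype=np.int64)
    cb = np.array([c[2] for c in cols if c[0] == "M"], dtype=np.int64)
    n_matches = sum(
        1 for c in cols
        if c[0] == "M" and a[c[1]] == b[c[2]] and a[c[1]] != "N"
    )
    return Hsp(
        score=best,
        interval_a=(min(a_idx), max(a_idx) + 1),
        interval_b=(min(b_idx), max(b_idx) + 1),
        aligned_length=len(cols),
        n_matches=n_matches,
        colmap_a=ca,
        colmap_b=cb,
    )


def _word_index(ests: Sequence[ESTRecord], w: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for bi, est in enumerate(ests):
        seq = est.seq
        for q in range(est.length - w + 1):
            word = seq[q : q + w]
            if "N" in word:
                continue
            index.setdefault(word, []).append((bi, q))
    return index


def pair_hsps(a_seq: str, b_seq: str, params: CosParams) -> list[Hsp]:
    """All distinct HSPs between two sequences (one banded extension per
    seed-diagonal bucket, overlap-reduced by descending score)."""
    w = params.word_size
    seeds: dict[int, int] = {}  # diagonal bucket -> representative diagonal
    index: dict[str, list[int]] = {}
    for q in range(len(b_seq) - w + 1):
        word = b_seq[q : q + w]
        if "N" not in word:
            index.setdefault(word, []).append(q)
    for p in range(len(a_seq) - w + 1):
        word = a_seq[p : p + w]
        for q in index.get(word, ()):
            d = p - q
            seeds.setdefault(d // max(params.band, 1), d)
    hsps = [
        h
        for bucket, d in sorted(seeds.items())
        if (h := banded_extend(a_seq, b_seq, d, params)) is not None
    ]
    return _reduce_overlaps(hsps)


def _overlaps(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] < y[1] and y[0] < x[1]


def _reduce_overlaps(hsps: list[Hsp]) -> list[Hsp]:
    hsps = sorted(hsps, key=lambda h: (-h.score, h.interval_a, h.interval_b))
    kept: list[Hsp] = []
    for h in hsps:
        if any(
            _overlaps(h.interval_a, k.interval_a)
            or _overlaps(h.interval_b, k.interval_b)
            for k in kept
        ):
            continue
        kept.append(h)
    return kept


def find_cos(
    dataset_a: Sequence[ESTRecord],
    dataset_b: Sequence[ESTRecord],
    params: CosParams = CosParams(),
) -> list[CosRegion]:
    """COS regions between two EST datasets (a = query, b = database).

    Word seeds are hashed from b; each seed-diagonal bucket of an EST pair
    is extended once with banded gapped DP; HSPs pass discovery E-value,
    are overlap-reduced per pair by descending score, and the survivors are
    filtered by the three COS criteria (length, identity, E-value).
    E = K*m*n*exp(-lambda*S) with m the query length, n the total database
    length, and lambda/K calibrated on the database base composition.
    """
    if not dataset_a or not dataset_b:
        raise ValueError("both datasets must be non-empty")
    w = params.word_size
    counts = np.zeros(4)
    total_b = 0
    for est in dataset_b:
        for c, k in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
            counts[k] += est.seq.count(c)
        total_b += est.length
    freqs = counts / counts.sum()
    ka = compute_karlin_altschul(params.match, params.mismatch, freqs)

    index = _word_index(dataset_b, w)
    regions: list[CosRegion] = []
    for a_est in dataset_a:
        seeds: dict[tuple[int, int], int] = {}  # (b_idx, diag bucket) -> diag
        seq = a_est.seq
        for p in range(a_est.length - w + 1):
            word = seq[p : p + w]
            if "N" in word:
                continue
            for bi, q in index.get(word, ()):
                seeds.setdefault((bi, (p - q) // params.band), p - q)
        by_b: dict[int, list[Hsp]] = {}
        for (bi, _bucket), d in sorted(seeds.items()):
            h = banded_extend(seq, dataset_b[bi].seq, d, params)
            if h is None:
                continue
            if ka.evalue(h.score, a_est.length, total_b) > params.evalue_discovery:
                continue
            by_b.setdefault(bi, []).append(h)
        for bi, hsps in sorted(by_b.items()):
            for h in _reduce_overlaps(hsps):
                ev = ka.evalue(h.score, a_est.length, total_b)
                if (
                    h.aligned_length >= params.min_cos_length
                    and h.n_matches / h.aligned_length > params.min_identity
                    and ev < params.evalue_cos
                ):
                    regions.append(
                        CosRegion(
                            id="",
                            est_a=a_est.id,
                            est_b=dataset_b[bi].id,
                            interval_a=h.interval_a,
                            interval_b=h.interval_b,
                            aligned_length=h.aligned_length,
                            n_matches=h.n_matches,
                            score=h.score,
                            evalue=ev,
                            colmap_a=h.colmap_a,
                            colmap_b=h.colmap_b,
                        )
                    )
    regions.sort(key=lambda r: (r.est_a, r.est_b, r.interval_a[0]))
    for k, r in enumerate(regions):
        r.id = f"cos{k:05d}"
    return regions


def write_cos_tsv(regions: Sequence[CosRegion], path: str | Path) -> None:
    """BLAST outfmt-6-like table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write(
            "cos_id\tqseqid\tsseqid\tpident\tlength\tnident\tqstart\tqend\t"
            "sstart\tsend\tevalue\tscore\n"
        )
        for r in regions:
            fh.write(
                f"{r.id}\t{r.est_a}\t{r.est_b}\t{100 * r.identity:.2f}\t"
                f"{r.aligned_length}\t{r.n_matches}\t{r.interval_a[0] + 1}\t"
                f"{r.interval_a[1]}\t{r.interval_b[0] + 1}\t{r.interval_b[1]}\t"
                f"{r.evalue:.3e}\t{r.score}\n"
            )


def write_colmaps_json(regions: Sequence[CosRegion], path: str | Path) -> None:
    import json

    payload = {
        r.id: {"a": r.colmap_a.tolist(), "b": r.colmap_b.tolist()}
        for r in regions
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
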