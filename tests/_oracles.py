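"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an operation's expected output by explicit
enumeration or an unrelated algorithm, sharing no code with the
implementation it checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# duplex scan: explicit enumeration of every constrained structure

_PAIR_E = {
    ("A", "T"): -2.0, ("U", "A"): -2.0, ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("G", "T"): -1.0, ("U", "G"): -1.0,
}


def _pair_energy(mir_base: str, tgt_base: str, wobble: bool) -> float | None:
    e = _PAIR_E.get((mir_base, tgt_base))
    if e is None:
        return None
    if not wobble and e == -1.0:
        return None
    return e


def oracle_duplex_sites(
    mir_rna: str,
    target_dna: str,
    max_overhang: int = 2,
    max_mismatches: int = 1,
    mfe_fraction: float = 0.70,
    loop_penalty: float = 2.0,
    allow_bulge: bool = True,
    wobble: bool = True,
) -> dict[tuple[int, int], tuple[float, int, int]]:
    """Best structure per site interval: {(start, end): (energy, loops, mm)}.

    Enumerates every anchor, overhang combination, bulge placement and
    mismatch pattern allowed by the constraints, scoring with the pair-sum
    model, and keeps the best structure (min energy, fewer bulges, fewer
    mismatches) per distinct site interval passing the energy-ratio cutoff.
    """
    L = len(mir_rna)
    n = len(target_dna)
    perfect = sum(
        {"A": -2.0, "U": -2.0, "G": -3.0, "C": -3.0}[c] for c in mir_rna
    )
    cutoff = mfe_fraction * perfect + 1e-9
    best: dict[tuple[int, int], tuple[float, int, int]] = {}
    for o3 in range(max_overhang + 1):
        for o5 in range(max_overhang + 1):
            ks = list(range(L - 1 - o3, o5 - 1, -1))  # consumed miR positions
            if len(ks) < 2:
                continue
            # bulge variants: none; miR position b unpaired (interior);
            # one extra target base between consumption steps j-1 and j
            variants: list[tuple[list[int | None], int]] = [(list(ks), 0)]
            if allow_bulge:
                for bi in range(1, len(ks) - 1):
                    v: list[int | None] = list(ks)
                    v[bi] = None  # miR bulge: no target consumed for this k
                    variants.append((v, 1))
                for slot in range(1, len(ks)):
                    v = list(ks)
                    v.insert(slot, -1)  # target bulge marker: consumes target
                    variants.append((v, 1))
            for items, nloops in variants:
                for s in range(n):
                    t = s
                    mm = 0
                    energy = loop_penalty * nloops
                    ok = True
                    for it in items:
                        if it is None:  # miR bulge: skip miR base
                            continue
                        if t >= n:
                            ok = False
                            break
                        tc = target_dna[t]
                        if it == -1:  # target bulge: unpaired target base
                            if tc == "N":
                                pass  # an unpaired N is tolerated
                            t += 1
                            continue
                        e = _pair_energy(mir_rna[it], tc, wobble)
                        if e is None:
                            mm += 1
                            if mm > max_mismatches:
                                ok = False
                                break
                        else:
                            energy += e
                        t += 1
                    if not ok:
                        continue
                    if energy > cutoff:
                        continue
                    key = (s, t)
                    cand = (energy, nloops, mm)
                    prev = best.get(key)
                    if prev is None or cand < prev:
                        best[key] = cand
    return best


# ---------------------------------------------------------------------------
# inverted repeats: anchored-start-pair enumeration (O(n^4) cells)


def oracle_ir_candidates(
    seq: str,
    match: int = 3,
    mismatch: int = -4,
    gap: int = -12,
    min_score: int = 50,
    max_loop: int = 300,
    min_span: int = 30,
) -> list[tuple[int, int, int, int, int]]:
    """All (left_start, left_end, right_start, right_end, score) inverted
    repeats scoring >= min_score, by gapped alignment anchored at every
    start pair of the sequence vs its reverse complement.

    Only match-anchored starts/ends are enumerated: an optimal alignment
    never begins or ends with a mismatch or gap column (trimming it scores
    strictly higher), and trimmed variants shadow untrimmed ones in the
    overlap reduction.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    n = len(seq)
    r = "".join(comp[c] for c in reversed(seq))
    sc = np.where(
        (np.frombuffer(seq.encode(), np.uint8)[:, None]
         == np.frombuffer(r.encode(), np.uint8)[None, :])
        & (np.frombuffer(seq.encode(), np.uint8)[:, None] != ord("N")),
        match, mismatch,
    ).astype(np.int64)
    out = []
    NEG = -(10**9)
    for i0 in range(n):
        for j0 in range(n):
            if sc[i0, j0] != match:
                continue
            mx = n - i0
            my = n - j0
            D = np.full((mx + 1, my + 1), NEG, dtype=np.int64)
            D[0, 0] = 0
            gp = -gap
            yidx = np.arange(my, dtype=np.int64)
            for x in range(1, mx + 1):
                row = np.full(my + 1, NEG, dtype=np.int64)
                diag = D[x - 1, :-1] + sc[i0 + x - 1, j0 : j0 + my]
                up = D[x - 1, 1:] + gap
                base = np.maximum(diag, up)
                # horizontal gap chain via prefix max (linear gap costs)
                row[1:] = np.maximum.accumulate(base + gp * yidx) - gp * yidx
                D[x] = row
                ys = np.nonzero(row[1:] >= min_score)[0] + 1
                for y in ys:
                    y = int(y)
                    if sc[i0 + x - 1, j0 + y - 1] != match:
                        continue  # alignments end on a match column
                    left = (i0, i0 + x)
                    right = (n - (j0 + y), n - j0)
                    loop = right[0] - left[1]
                    span = right[1] - left[0]
                    if 0 <= loop <= max_loop and span >= min_span:
                        out.append(
                            (left[0], left[1], right[0], right[1], int(row[y]))
                        )
    return out


def oracle_ir_reduce(
    cands: list[tuple[int, int, int, int, int]],
) -> list[tuple[int, int, int, int, int]]:
    """Greedy non-overlap reduction by descending score (ties: leftmost,
    then longest), mirroring the documented reporting contract."""
    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    kept: list[tuple[int, int, int, int, int]] = []
    for c in sorted(cands, key=lambda c: (-c[4], c[0], -(c[3] - c[0]))):
        arms = [(c[0], c[1]), (c[2], c[3])]
        clash = any(
            overlaps(arm, karm)
            for k in kept
            for karm in [(k[0], k[1]), (k[2], k[3])]
            for arm in arms
        )
        if not clash:
            kept.append(c)
    return sorted(kept)


# ---------------------------------------------------------------------------
# secondary structure: exhaustive first-position decomposition


def oracle_fold_min_energy(seq: str, min_loop: int = 3) -> float:
    """Minimum pair-sum energy over all nested structures of ``seq``.

    Recursion on substrings: the first base is either unpaired or paired
    with some j (hairpin loop >= min_loop), considering every structure.
    """
    E = {
        ("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "T"): -2.0, ("T", "A"): -2.0,
        ("G", "T"): -1.0, ("T", "G"): -1.0,
    }

    @lru_cache(maxsize=None)
    def rec(s: str) -> float:
        if len(s) < min_loop + 2:
            return 0.0
        best = rec(s[1:])
        for j in range(min_loop + 1, len(s)):
            e = E.get((s[0], s[j]))
            if e is not None:
                best = min(best, e + rec(s[1:j]) + rec(s[j + 1 :]))
        return best

    return rec(seq)


# ---------------------------------------------------------------------------
# dinucleotide-preserving permutations of a short sequence


def oracle_dinuc_permutations(seq: str) -> set[str]:
    """All orderings with the same dinucleotide counts and terminals."""
    from itertools import permutations

    def counts(s: str) -> dict[str, int]:
        d: dict[str, int] = {}
        for a, b in zip(s, s[1:]):
            d[a + b] = d.get(a + b, 0) + 1
        return d

    ref = counts(seq)
    out = set()
    for p in set(permutations(seq)):
        s = "".join(p)
        if s[0] == seq[0] and s[-1] == seq[-1] and counts(s) == ref:
            out.add(s)
    return out
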