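"""Candidate pre-miRNA identification and hairpin validation.

A precursor candidate requires, inside one inverted repeat: a mature miRNA
match on one arm (ungapped, small Hamming distance), its star counterpart
on the opposite arm in reverse-complement orientation, and an outer
mature-to-star span consistent with the length of an orthologous precursor
of the same family.  Candidates are then validated by folding a 200-nt
window centred on the hairpin and checking that the mature sits on one arm
of a stem.

The builtin folding backend is an energy-weighted Nussinov-class dynamic
programme over the duplex pair-energy table (minimum hairpin loop 3 nt, no
pseudoknots); it is not a full nearest-neighbor thermodynamic model, and a
callable external backend can be plugged in where kcal/mol figures are
wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .cosalign import CosParams, pair_hsps
from .duplexscan import EnergyModel
from .irfinder import InvertedRepeat
from .seqio import (
    ESTRecord,
    MatureMiRNA,
    PrecursorReference,
    revcomp,
    to_dna,
)


@dataclass(frozen=True)
class PrecursorParams:
    window: int = 200
    max_mature_mismatch: int = 2
    max_star_mismatch: int = 3
    spacing_tolerance: float = 0.20  # fraction of the reference length
    star_search_pad: int = 4  # allowance around the arm for the 2-nt 3' offset
    min_paired_fraction_in_mature: float = 0.75
    min_stem_run_fraction: float = 0.45  # longest stacked helix / mature length
    energy_density_cutoff: float = -0.15  # model units per window nt
    fold_backend: str = "builtin"

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if min(self.max_mature_mismatch, self.max_star_mismatch) < 0:
            raise ValueError("mismatch tolerances must be >= 0")
        if self.spacing_tolerance < 0:
            raise ValueError("spacing_tolerance must be >= 0")


@dataclass(frozen=True)
class HairpinCandidate:
    est_id: str
    mirna: str
    family: str
    mature_site: tuple[int, int]  # EST coordinates
    star_site: tuple[int, int]
    mature_mismatches: int
    star_mismatches: int
    inter_match_distance: int  # outer span, mature start to star end
    matched_reference: PrecursorReference
    window: tuple[int, int] = (0, 0)
    window_seq: str = ""
    fold: str = ""
    fold_energy: float = 0.0
    status: str = "candidate"  # candidate | validated | dropped


def _hamming_scan(pattern: str, region: str) -> list[tuple[int, int]]:
    """(offset, mismatches) for every full-length ungapped placement."""
    lp, lr = len(pattern), len(region)
    if lr < lp:
        return []
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    reg = np.frombuffer(region.encode(), dtype=np.uint8)
    # N (in either) never matches
    isn = (reg == ord("N"))
    out = []
    for off in range(lr - lp + 1):
        seg = reg[off : off + lp]
        mm = int((seg != pat).sum() + (seg == pat)[isn[off : off + lp]].sum())
        out.append((off, mm))
    return out


def match_mature_and_star(
    ir: InvertedRepeat,
    est: ESTRecord,
    matures: Sequence[MatureMiRNA],
    refs: Sequence[PrecursorReference],
    params: PrecursorParams = PrecursorParams(),
) -> list[HairpinCandidate]:
    """Locate mature + star inside an inverted repeat of this EST.

    The mature is searched by ungapped sliding comparison (Hamming <=
    ``max_mature_mismatch``) on either strand of either arm; the star is the
    reverse complement of the matched orientation on the opposite arm
    (Hamming <= ``max_star_mismatch``), searched with a few extra flanking
    positions to allow the canonical 2-nt 3' offset.  Candidates whose outer
    mature-to-star span matches no reference length of the family (within
    ``spacing_tolerance``) are dropped, as are overlapping mature/star pairs.
    """
    if ir.est_id != est.id:
        raise ValueError("inverted repeat does not belong to this EST")
    arms = (ir.left_arm, ir.right_arm)
    refs_by_family: dict[str, list[PrecursorReference]] = {}
    for r in refs:
        refs_by_family.setdefault(r.family, []).append(r)

    out: list[HairpinCandidate] = []
    seen: set[tuple[str, tuple[int, int], tuple[int, int]]] = set()
    for m in matures:
        family_refs = refs_by_family.get(m.family)
        if not family_refs:
            continue
        mdna = to_dna(m.seq)
        for arm_idx, arm in enumerate(arms):
            arm_seq = est.seq[arm[0] : arm[1]]
            other = arms[1 - arm_idx]
            lo = max(0, other[0] - params.star_search_pad)
            hi = min(est.length, other[1] + params.star_search_pad)
            other_seq = est.seq[lo:hi]
            for pattern in (mdna, revcomp(mdna)):
                for off, mm in _hamming_scan(pattern, arm_seq):
                    if mm > params.max_mature_mismatch:
                        continue
                    mature_site = (arm[0] + off, arm[0] + off + len(mdna))
                    star_pat = revcomp(pattern)
                    star_hits = [
                        (smm, soff)
                        for soff, smm in _hamming_scan(star_pat, other_seq)
                        if smm <= params.max_star_mismatch
                    ]
                    if not star_hits:
                        continue
                    smm, soff = min(star_hits)
                    star_site = (lo + soff, lo + soff + len(star_pat))
                    if _overlap(mature_site, star_site):
                        continue
                    span = max(mature_site[1], star_site[1]) - min(
                        mature_site[0], star_site[0]
                    )
                    ref = _best_reference(span, family_refs, params.spacing_tolerance)
                    if ref is None:
                        continue
                    key = (m.name, mature_site, star_site)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        HairpinCandidate(
                            est_id=est.id,
                            mirna=m.name,
                            family=m.family,
                            mature_site=mature_site,
                            star_site=star_site,
                            mature_mismatches=mm,
                            star_mismatches=smm,
                            inter_match_distance=span,
                            matched_reference=ref,
                        )
                    )
    out.sort(key=lambda c: (c.mature_site, c.star_site, c.mirna))
    return out


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] < y[1] and y[0] < x[1]


def _best_reference(
    span: int, refs: Sequence[PrecursorReference], tol: float
) -> PrecursorReference | None:
    best = None
    best_dev = None
    for r in refs:
        dev = abs(span - r.precursor_length) / r.precursor_length
        if dev <= tol and (best_dev is None or dev < best_dev):
            best, best_dev = r, dev
    return best


def extract_window(
    est: ESTRecord, candidate: HairpinCandidate, window: int = 200
) -> HairpinCandidate:
    """Attach the window centred on the mature/star midpoint (truncated at
    EST ends, never padded)."""
    lo = min(candidate.mature_site[0], candidate.star_site[0])
    hi = max(candidate.mature_site[1], candidate.star_site[1])
    center = (lo + hi) // 2
    half = window // 2
    start = max(0, center - half)
    end = min(est.length, center + (window - half))
    return replace(
        candidate, window=(start, end), window_seq=est.seq[start:end]
    )


# ---------------------------------------------------------------------------
# builtin folding backend


def fold_nussinov(
    seq: str, model: EnergyModel = EnergyModel(), min_loop: int = 3
) -> tuple[str, float, list[tuple[int, int]]]:
    """Maximum-stability nested secondary structure by dynamic programming.

    Energy of a structure is the sum of pair energies over its base pairs
    (DNA input is treated with the RNA pair table: T plays U); hairpin loops
    keep at least ``min_loop`` unpaired bases and pseudoknots are excluded.
    Returns (dot-bracket, energy, pairs).
    """
    n = len(seq)
    codes = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
    s = np.fromiter((codes[c] for c in seq), dtype=np.int8, count=n)
    pe = np.zeros((5, 5))
    keymap = {
        ("G", "C"): "GC", ("C", "G"): "CG", ("A", "T"): "AU", ("T", "A"): "UA",
        ("G", "T"): "GU", ("T", "G"): "UG",
    }
    c_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    for (x, y), key in keymap.items():
        if key in ("GU", "UG") and not model.wobble_allowed:
            continue
        pe[c_of[x], c_of[y]] = model.pair_energy[key]
    if n == 0:
        return "", 0.0, []
    W = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        i_arr = np.arange(0, n - span)
        j_arr = i_arr + span
        best = W[i_arr + 1, j_arr].copy()
        np.minimum(best, W[i_arr, j_arr - 1], out=best)
        epair = pe[s[i_arr], s[j_arr]]
        can_pair = epair < 0
        inner = np.where(
            span >= min_loop + 2, W[i_arr + 1, j_arr - 1], 0.0
        )
        np.minimum(best, np.where(can_pair, inner + epair, np.inf), out=best)
        for idx, (i, j) in enumerate(zip(i_arr, j_arr)):
            if j - i >= 2:
                k = np.arange(i + 1, j)
                bif = (W[i, k] + W[k + 1, j]).min()
                if bif < best[idx]:
                    best[idx] = bif
        W[i_arr, j_arr] = best
    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j:
            w = W[i, j]
            if w == 0:
                return
            if w == W[i + 1, j]:
                i += 1
                continue
            if w == W[i, j - 1]:
                j -= 1
                continue
            eij = pe[s[i], s[j]]
            if eij < 0 and j - i > min_loop and w == (
                (W[i + 1, j - 1] if j - i >= min_loop + 2 else 0.0) + eij
            ):
                pairs.append((i, j))
                i, j = i + 1, j - 1
                continue
            for k in range(i + 1, j):
                if w == W[i, k] + W[k + 1, j]:
                    trace(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover - DP consistency
                raise AssertionError("fold traceback failed")

    trace(0, n - 1)
    dot = ["."] * n
    for i, j in pairs:
        dot[i], dot[j] = "(", ")"
    return "".join(dot), float(W[0, n - 1]), sorted(pairs)


FoldBackend = Callable[[str], tuple[str, float, list[tuple[int, int]]]]


def fold_and_validate(
    candidate: HairpinCandidate,
    model: EnergyModel = EnergyModel(),
    params: PrecursorParams = PrecursorParams(),
    backend: FoldBackend | None = None,
) -> HairpinCandidate:
    """Fold the candidate window and decide validated/dropped.

    Validation requires the mature to sit on one arm of a stem:

    * at least ``min_paired_fraction_in_mature`` of its bases are paired;
    * the longest contiguous stacked helix through the mature (consecutive
      positions whose partners descend by one) covers at least
      ``min_stem_run_fraction`` of the mature — one coherent duplex arm
      rather than the scattered short helices of background folds;
    * the fold energy density is at or below ``energy_density_cutoff``.
    """
    if not candidate.window_seq:
        raise ValueError("candidate has no window; call extract_window first")
    mstart, mend = candidate.mature_site
    wstart, wend = candidate.window
    if mend - mstart > len(candidate.window_seq):
        raise ValueError("window shorter than the mature span")
    if backend is None:
        fold, energy, pairs = fold_nussinov(candidate.window_seq, model)
    else:
        fold, energy, pairs = backend(candidate.window_seq)

    lo = max(mstart - wstart, 0)
    hi = min(mend - wstart, len(candidate.window_seq))
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    mat_pairs = [(i, partner[i]) for i in range(lo, hi) if i in partner]
    ok = False
    if mat_pairs:
        frac = len(mat_pairs) / (hi - lo)
        run = best_run = 0
        prev: int | None = None
        for i in range(lo, hi):
            p = partner.get(i)
            if p is not None:
                run = run + 1 if (prev is not None and p == prev - 1) else 1
                best_run = max(best_run, run)
            else:
                run = 0
            prev = p
        density = energy / len(candidate.window_seq)
        ok = (
            frac >= params.min_paired_fraction_in_mature
            and best_run / (hi - lo) >= params.min_stem_run_fraction
            and density <= params.energy_density_cutoff
        )
    return replace(
        candidate,
        fold=fold,
        fold_energy=energy,
        status="validated" if ok else "dropped",
    )


# ---------------------------------------------------------------------------
# accuracy benchmarking against a known-precursor reference set


def benchmark_precursor_recall(
    ests: Sequence[ESTRecord],
    known_precursors: Sequence[ESTRecord],
    find_candidates: Callable[[ESTRecord], Sequence[HairpinCandidate]],
    identity: float = 0.90,
    coverage: float = 0.70,
    align_params: CosParams | None = None,
) -> tuple[int, int, float]:
    """Recall of the candidate pipeline on ESTs that carry a known precursor.

    The truth set contains every EST matching one of ``known_precursors`` by
    local alignment at >= ``identity`` over >= ``coverage`` of the precursor
    length; recall is the fraction of truth ESTs for which
    ``find_candidates`` yields at least one validated candidate.  Raises on
    an empty truth set rather than reporting 0/0.
    """
    if not ests or not known_precursors:
        raise ValueError("both input sets must be non-empty")
    ap = align_params or CosParams(
        word_size=11, min_cos_length=1, min_identity=0.0, xdrop=50
    )
    truth: list[ESTRecord] = []
    for est in ests:
        for pre in known_precursors:
            hit = False
            for h in pair_hsps(est.seq, pre.seq, ap):
                cov = (h.interval_b[1] - h.interval_b[0]) / pre.length
                ident = h.n_matches / h.aligned_length
                if ident >= identity and cov >= coverage:
                    hit = True
                    break
            if hit:
                truth.append(est)
                break
    if not truth:
        raise ValueError("empty truth set: no EST matches a known precursor")
    recovered = sum(
        1
        for est in truth
        if any(c.status == "validated" for c in find_candidates(est))
    )
    return len(truth), recovered, recovered / len(truth)


# ---------------------------------------------------------------------------
# serialization


def write_candidates_tsv(
    candidates: Sequence[HairpinCandidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "est_id\tmirna\tfamily\tmature_start\tmature_end\tstar_start\t"
            "star_end\tmature_mm\tstar_mm\tspan\tref_length\twindow_start\t"
            "window_end\tfold_energy\tstatus\n"
        )
        for c in candidates:
            fh.write(
                f"{c.est_id}\t{c.mirna}\t{c.family}\t{c.mature_site[0] + 1}\t"
                f"{c.mature_site[1]}\t{c.star_site[0] + 1}\t{c.star_site[1]}\t"
                f"{c.mature_mismatches}\t{c.star_mismatches}\t"
                f"{c.inter_match_distance}\t"
                f"{c.matched_reference.precursor_length}\t"
                f"{c.window[0] + 1}\t{c.window[1]}\t{c.fold_energy:.1f}\t"
                f"{c.status}\n"
            )


def write_windows_fasta(
    candidates: Sequence[HairpinCandidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for k, c in enumerate(candidates):
            if c.window_seq:
                fh.write(
                    f">{c.est_id}|{c.mirna}|{k}\n{c.window_seq}\n"
                )


def write_vienna(
    candidates: Sequence[HairpinCandidate], path: str | Path
) -> None:
    """Vienna-style text: sequence line, structure line, ``(energy)``."""
    with open(path, "w") as fh:
        for c in candidates:
            if c.fold:
                fh.write(
                    f">{c.est_id}|{c.mirna}\n{c.window_seq}\n"
                    f"{c.fold} ({c.fold_energy:.1f})\n"
                )
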