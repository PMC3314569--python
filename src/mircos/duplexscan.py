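"""Constrained miRNA:EST duplex scanning — the target-prediction core.

The scanner finds binding sites of a mature miRNA on an EST under the
plant-target constraints used throughout the pipeline: at most one mismatch,
at most one bulge event of at most one unpaired nucleotide per side, up to
two unpaired miRNA nucleotides at each terminus (overhangs), and a duplex
energy at least 70% of the miRNA's perfect-match energy.

The energy model is a documented simple pair-sum (GC/CG -3, AU/UA -2, GU/UG
wobble -1 model units, +2 per bulge event); it is not a nearest-neighbor
thermodynamic model.  The selection logic depends only on the *ratio* of a
site's energy to the per-miRNA perfect-match energy, which a pair-sum model
preserves, so absolute kcal/mol values are deliberately out of scope.  A
1x1 internal loop (both strands keep one unpaired base) is counted as a
mismatch, not a bulge; G:U wobble counts as a pair, never a mismatch, and
can be disabled.

Implementation: a tiny state machine swept along the miRNA from its 3' end
(which pairs the 5'-most target base of the site), vectorized with numpy
over every candidate site start simultaneously.  States track the mismatch
budget, the bulge type (none / miRNA-side / target-side) and whether the
last consumed element was a bulge (bulges must be interior).  This
enumerates exhaustively the same structures as explicit per-start
enumeration, which the test suite uses as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import ESTRecord, MatureMiRNA, revcomp, to_dna

# base codes: A=0 C=1 G=2 T/U=3 N=4, padding/separator=5 (never valid)
_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4, "X": 5}
_INVALID = 5


@dataclass(frozen=True)
class EnergyModel:
    """Pair-sum duplex energy model (negative = stable), model units."""

    pair_energy: dict[str, float] = field(
        default_factory=lambda: {
            "GC": -3.0, "CG": -3.0, "AU": -2.0, "UA": -2.0, "GU": -1.0, "UG": -1.0,
        }
    )
    mismatch_energy: float = 0.0
    loop_event_penalty: float = 2.0
    wobble_allowed: bool = True

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.pair_energy.values()):
            raise ValueError("pair energies must be negative")
        if self.loop_event_penalty < 0:
            raise ValueError("penalties must be >= 0")


@dataclass(frozen=True)
class ScanParams:
    """Structural limits of an acceptable duplex.

    ``max_overhang`` limits the unpaired miRNA nucleotides at *each* of the
    5' and 3' termini; ``mfe_fraction`` is the fraction of the perfect-match
    energy a site must reach.
    """

    max_loops: int = 1
    max_loop_size: int = 1  # unpaired nt per side per bulge event
    max_mismatches: int = 1
    max_overhang: int = 2
    mfe_fraction: float = 0.70
    strand_mode: str = "both"  # forward | reverse | both

    def __post_init__(self) -> None:
        if min(self.max_loops, self.max_loop_size, self.max_mismatches,
               self.max_overhang) < 0:
            raise ValueError("limits must be >= 0")
        if not 0 < self.mfe_fraction <= 1:
            raise ValueError("mfe_fraction in (0, 1]")
        if self.strand_mode not in ("forward", "reverse", "both"):
            raise ValueError(f"bad strand_mode {self.strand_mode!r}")


@dataclass(frozen=True)
class DuplexHit:
    """One predicted miRNA binding site on an EST.

    ``site`` is 0-based half-open on the EST's forward strand; ``strand`` is
    '-' when the scan ran against the reverse complement.  ``energy``
    includes bulge penalties; ``stability_ratio = energy / perfect_energy``.
    """

    mirna: str
    est_id: str
    strand: str
    site: tuple[int, int]
    n_mismatch: int
    n_loops: int
    overhang5: int
    overhang3: int
    energy: float
    perfect_energy: float

    @property
    def stability_ratio(self) -> float:
        return self.energy / self.perfect_energy


def perfect_match_energy(m: MatureMiRNA | str, model: EnergyModel = EnergyModel()) -> float:
    """Energy of the miRNA bound full-length to its Watson-Crick complement.

    The perfect reference never uses G:U wobble, so each base contributes
    its canonical pair energy (A,U -> AU; G,C -> GC, etc.).
    """
    seq = m.seq if isinstance(m, MatureMiRNA) else m
    canonical = {"A": "AU", "U": "UA", "T": "UA", "G": "GC", "C": "CG"}
    total = 0.0
    for c in seq.upper():
        if c == "N":
            raise ValueError("perfect-match energy undefined for N")
        total += model.pair_energy[canonical[c]]
    return total


_LUT = np.full(128, _INVALID, dtype=np.int8)
for _c, _v in _CODES.items():
    _LUT[ord(_c)] = _v


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _tables(model: EnergyModel) -> tuple[np.ndarray, np.ndarray]:
    """(pair_bool, pair_energy) lookup over (miR code, target code)."""
    pb = np.zeros((5, 6), dtype=bool)
    pe = np.zeros((5, 6), dtype=np.float64)
    pairs = {(0, 3): "AU", (3, 0): "UA", (2, 1): "GC", (1, 2): "CG"}
    if model.wobble_allowed:
        pairs.update({(2, 3): "GU", (3, 2): "UG"})
    for (mc, tc), key in pairs.items():
        pb[mc, tc] = True
        pe[mc, tc] = model.pair_energy[key]
    return pb, pe


def _scan_codes(
    mir: np.ndarray,
    tgt: np.ndarray,
    params: ScanParams,
    model: EnergyModel,
    e_perfect: float,
) -> list[tuple[int, int, float, int, int, int, int]]:
    """Core sweep on encoded sequences.

    ``tgt`` must be padded on the right with >= len(mir)+2 invalid codes.
    Returns tuples ``(s, site_len, energy, mm, n_loops, o5, o3)`` with the
    best structure per site interval (min energy, then fewer bulges, then
    fewer mismatches).
    """
    if params.max_loops > 1 or params.max_loop_size > 1:
        raise NotImplementedError(
            "the sweep supports at most one bulge event of one nucleotide"
        )
    L = len(mir)
    n = len(tgt) - L - 2  # candidate anchor positions
    if n <= 0:
        return []
    pb, pe = _tables(model)
    # per-miR-position cost vectors over target positions, +inf = forbidden
    tix = tgt.astype(np.intp)
    pbk = pb[mir][:, tix]  # (L, padded)
    valid = tgt != _INVALID
    f32 = np.float32
    paircost = np.where(pbk, pe[mir][:, tix], np.inf).astype(f32)  # pair step
    mmcost = np.where(
        ~pbk & valid[None, :], model.mismatch_energy, np.inf
    ).astype(f32)
    bulgecost = np.where(valid, model.loop_event_penalty, np.inf).astype(f32)
    cutoff = params.mfe_fraction * e_perfect + 1e-9  # energies negative
    penalty = model.loop_event_penalty
    allow_bulge = params.max_loops >= 1 and params.max_loop_size >= 1
    INF = np.inf

    # candidate structures: key (s, site_len) -> (energy, n_loops, mm, o5, o3)
    best: dict[tuple[int, int], tuple[float, int, int, int, int]] = {}

    for o3 in range(params.max_overhang + 1):
        k0 = L - 1 - o3
        if k0 < 0:
            break
        # states: (mm, bulge, pending) -> [energy vector, target offset]
        # bulge: '' none, 'm' miRNA-side, 't' target-side
        base: np.ndarray | None = None  # surviving start indices (compacted)

        def tslice(arr: np.ndarray, f: int) -> np.ndarray:
            if base is None:
                return arr[f : f + n]
            return arr[base + f]

        def emit(E, f, mm, nloops, o5, o3):
            idx = np.nonzero(E <= cutoff)[0]
            for i in idx:
                s = int(i) if base is None else int(base[i])
                cand = (float(E[i]), nloops, mm, o5, o3)
                prev = best.get((s, f))
                if prev is None or cand[:3] < prev[:3]:
                    best[(s, f)] = cand

        states: dict[tuple[int, str, int], list] = {
            (0, "", 0): [paircost[k0, :n].copy(), 1]
        }
        if params.max_mismatches >= 1:
            states[(1, "", 0)] = [mmcost[k0, :n].copy(), 1]
        for k in range(k0 - 1, -1, -1):
            new: dict[tuple[int, str, int], list] = {}

            def fold(key: tuple[int, str, int], E: np.ndarray, f: int) -> None:
                cur = new.get(key)
                if cur is None:
                    new[key] = [E, f]
                else:
                    assert cur[1] == f
                    np.minimum(cur[0], E, out=cur[0])

            expanded = [(key, E, f) for key, (E, f) in states.items()]
            if allow_bulge:
                # target-side bulge: consume one unpaired target base (interior)
                for (mm, bulge, _pend), (E, f) in states.items():
                    if bulge:
                        continue
                    expanded.append(((mm, "t", 1), E + tslice(bulgecost, f), f + 1))
            for (mm, bulge, _pend), E, f in expanded:
                # pair step consuming miR position k
                fold((mm, bulge, 0), E + tslice(paircost[k], f), f + 1)
                # mismatch step
                if mm < params.max_mismatches:
                    fold((mm + 1, bulge, 0), E + tslice(mmcost[k], f), f + 1)
            if allow_bulge and k > 0:
                # miRNA-side bulge: position k unpaired (interior, so not k=0)
                for (mm, bulge, pend), (E, f) in states.items():
                    if bulge or pend:
                        continue
                    fold((mm, "m", 1), E + penalty, f)
            states = new
            if k <= params.max_overhang:
                o5 = k
                for (mm, bulge, pend), (E, f) in states.items():
                    if pend:
                        continue
                    emit(E, f, mm, 1 if bulge else 0, o5, o3)
            # repeatedly compact to surviving starts as the field thins out
            cur_len = n if base is None else len(base)
            if k0 - k >= 3 and k > 0 and cur_len > 256:
                alive = np.zeros(cur_len, dtype=bool)
                for E, _f in states.values():
                    alive |= np.isfinite(E)
                if alive.mean() < 0.6:
                    keep = np.nonzero(alive)[0]
                    base = keep if base is None else base[keep]
                    for st in states.values():
                        st[0] = st[0][keep]
    return [
        (s, f, e, mm, nl, o5, o3)
        for (s, f), (e, nl, mm, o5, o3) in best.items()
    ]


def _pad(codes: np.ndarray, extra: int) -> np.ndarray:
    return np.concatenate(
        [codes, np.full(extra, _INVALID, dtype=np.int8)]
    )


def scan_targets(
    m: MatureMiRNA,
    est: ESTRecord,
    params: ScanParams = ScanParams(),
    model: EnergyModel = EnergyModel(),
) -> list[DuplexHit]:
    """All acceptable binding sites of ``m`` on ``est``.

    Overlapping sites are all reported (site multiplicity is meaningful);
    at one site interval only the best structure is kept (lowest energy,
    then fewer bulges, then fewer mismatches).  Output is ordered by
    (site start, strand).
    """
    return _scan_many(m, [est], params, model)


def scan_dataset(
    matures: Sequence[MatureMiRNA],
    ests: Sequence[ESTRecord],
    params: ScanParams = ScanParams(),
    model: EnergyModel = EnergyModel(),
) -> list[DuplexHit]:
    """Scan every mature against every EST (vectorized over a whole dataset)."""
    if not ests:
        return []
    concat = _concat_targets(ests, max(len(m.seq) for m in matures) + 2)
    hits: list[DuplexHit] = []
    for m in matures:
        hits.extend(_scan_many(m, ests, params, model, concat))
    return hits


def _concat_targets(
    ests: Sequence[ESTRecord], sep: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per strand: (concatenated padded codes, per-EST start offsets)."""
    out = {}
    for strand in ("+", "-"):
        offsets: list[int] = []
        pos = 0
        chunks: list[np.ndarray] = []
        for est in ests:
            offsets.append(pos)
            seq = est.seq if strand == "+" else revcomp(est.seq)
            chunks.append(_pad(_encode(seq), sep))
            pos += est.length + sep
        out[strand] = (np.concatenate(chunks), np.array(offsets))
    return out


def _scan_many(
    m: MatureMiRNA,
    ests: Sequence[ESTRecord],
    params: ScanParams,
    model: EnergyModel,
    concat: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> list[DuplexHit]:
    if not ests:
        return []
    mir = _encode(m.seq)
    L = len(mir)
    e_perfect = perfect_match_energy(m, model)
    if concat is None:
        concat = _concat_targets(ests, L + 2)

    strands = {"forward": ["+"], "reverse": ["-"], "both": ["+", "-"]}[
        params.strand_mode
    ]
    hits: list[DuplexHit] = []
    for strand in strands:
        tgt, starts = concat[strand]
        offsets = starts.tolist()
        for s, f, energy, mm, nloops, o5, o3 in _scan_codes(
            mir, tgt, params, model, e_perfect
        ):
            i = int(np.searchsorted(starts, s, side="right")) - 1
            est = ests[i]
            local = s - offsets[i]
            if strand == "+":
                site = (local, local + f)
            else:
                site = (est.length - local - f, est.length - local)
            hits.append(
                DuplexHit(
                    mirna=m.name,
                    est_id=est.id,
                    strand=strand,
                    site=site,
                    n_mismatch=mm,
                    n_loops=nloops,
                    overhang5=o5,
                    overhang3=o3,
                    energy=energy,
                    perfect_energy=e_perfect,
                )
            )
    order = {e.id: i for i, e in enumerate(ests)}
    hits.sort(key=lambda h: (order[h.est_id], h.site[0], h.strand))
    return hits


def count_targeted_ests(
    hits: Iterable[DuplexHit], ests: Sequence[ESTRecord]
) -> tuple[int, int]:
    """(number of ESTs with >= 1 hit, number with >= 2 hits)."""
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.est_id] = counts.get(h.est_id, 0) + 1
    known = {e.id for e in ests}
    unknown = set(counts) - known
    if unknown:
        raise ValueError(f"hits reference unknown ESTs: {sorted(unknown)[:3]}")
    ge1 = sum(1 for v in counts.values() if v >= 1)
    ge2 = sum(1 for v in counts.values() if v >= 2)
    return ge1, ge2


def write_hits_tsv(hits: Sequence[DuplexHit], path: str | Path) -> None:
    """One row per hit; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(
            "mirna\test_id\tstrand\tstart\tend\tmm\tloops\toh5\toh3\t"
            "energy\tratio\n"
        )
        for h in hits:
            fh.write(
                f"{h.mirna}\t{h.est_id}\t{h.strand}\t{h.site[0] + 1}\t"
                f"{h.site[1]}\t{h.n_mismatch}\t{h.n_loops}\t{h.overhang5}\t"
                f"{h.overhang3}\t{h.energy:.1f}\t{h.stability_ratio:.3f}\n"
            )


def write_hits_gff3(hits: Sequence[DuplexHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, h in enumerate(hits):
            fh.write(
                f"{h.est_id}\tmircos\tmiRNA_target_site\t{h.site[0] + 1}\t"
                f"{h.site[1]}\t{h.energy:.1f}\t{h.strand}\t.\t"
                f"ID=hit{k:06d};Name={h.mirna};ratio={h.stability_ratio:.3f}\n"
            )
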