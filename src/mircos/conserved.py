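"""Functionally conserved targets: the same miRNA at corresponding COS positions.

The selection criterion at the heart of the comparative pipeline: a target
is called conserved when one mature miRNA has predicted sites inside a COS
region in *both* species, and the site from species a, projected through
the COS alignment, overlaps the species-b site by at least ``min_overlap``
nucleotides.  A relaxed mode (``require_position=False``) keeps any miRNA
with sites anywhere inside both COS intervals, ignoring position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .cosalign import CosRegion
from .duplexscan import DuplexHit
from .seqio import mirna_family


@dataclass(frozen=True)
class ConservedTarget:
    mirna: str
    cos_id: str
    est_a: str
    est_b: str
    site_a: tuple[int, int]
    site_b: tuple[int, int]
    projected_overlap: int


def _within(site: tuple[int, int], interval: tuple[int, int]) -> bool:
    return site[0] >= interval[0] and site[1] <= interval[1]


def intersect_conserved(
    hits_a: Sequence[DuplexHit],
    hits_b: Sequence[DuplexHit],
    cos_regions: Sequence[CosRegion],
    min_overlap: int = 10,
    require_position: bool = True,
) -> tuple[list[ConservedTarget], dict]:
    """Pair species-a and species-b sites of the same miRNA within each COS.

    For every COS region and every miRNA with at least one site inside each
    of the two COS intervals, each a-site is paired with the b-site of
    maximal overlap after projection through the alignment column map, and
    reported when the overlap reaches ``min_overlap``.  Returns the
    conserved targets plus a summary with the distinct mature-target and
    family counts and per-species EST counts.
    """
    by_est_a: dict[str, list[DuplexHit]] = {}
    for h in hits_a:
        by_est_a.setdefault(h.est_id, []).append(h)
    by_est_b: dict[str, list[DuplexHit]] = {}
    for h in hits_b:
        by_est_b.setdefault(h.est_id, []).append(h)

    out: list[ConservedTarget] = []
    for cos in cos_regions:
        a_in = [
            h for h in by_est_a.get(cos.est_a, ())
            if _within(h.site, cos.interval_a)
        ]
        b_in = [
            h for h in by_est_b.get(cos.est_b, ())
            if _within(h.site, cos.interval_b)
        ]
        if not a_in or not b_in:
            continue
        mirnas_b: dict[str, list[DuplexHit]] = {}
        for h in b_in:
            mirnas_b.setdefault(h.mirna, []).append(h)
        for ha in a_in:
            cands = mirnas_b.get(ha.mirna)
            if not cands:
                continue
            if not require_position:
                hb = cands[0]
                out.append(
                    ConservedTarget(
                        ha.mirna, cos.id, cos.est_a, cos.est_b,
                        ha.site, hb.site, 0,
                    )
                )
                continue
            proj = cos.project(ha.site)
            best = None
            for hb in cands:
                ov = min(proj[1], hb.site[1]) - max(proj[0], hb.site[0])
                if best is None or ov > best[0]:
                    best = (ov, hb)
            ov, hb = best
            if ov >= min_overlap:
                out.append(
                    ConservedTarget(
                        ha.mirna, cos.id, cos.est_a, cos.est_b,
                        ha.site, hb.site, ov,
                    )
                )
    out.sort(key=lambda t: (t.cos_id, t.site_a, t.mirna))
    summary = summarize_conserved(out)
    return out, summary


def summarize_conserved(targets: Sequence[ConservedTarget]) -> dict:
    return {
        "n_conserved_site_pairs": len(targets),
        "n_mature_targets": len({t.mirna for t in targets}),
        "n_families": len({mirna_family(t.mirna) for t in targets}),
        "n_ests_a": len({t.est_a for t in targets}),
        "n_ests_b": len({t.est_b for t in targets}),
    }


def write_conserved_tsv(targets: Sequence[ConservedTarget], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mirna\tcos_id\test_a\tsite_a_start\tsite_a_end\test_b\t"
            "site_b_start\tsite_b_end\toverlap\n"
        )
        for t in targets:
            fh.write(
                f"{t.mirna}\t{t.cos_id}\t{t.est_a}\t{t.site_a[0] + 1}\t"
                f"{t.site_a[1]}\t{t.est_b}\t{t.site_b[0] + 1}\t{t.site_b[1]}\t"
                f"{t.projected_overlap}\n"
            )


def write_conserved_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
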