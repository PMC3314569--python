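"""Paired synthetic EST datasets with planted ground truth.

The generator emulates, at reduced scale, the structure of two related
species' EST collections as the pipeline sees them: i.i.d. background
sequence of realistic length (400-800 nt), planted stem-loop precursors
(mature + loop + reverse-complement star, the star arm carrying a few
seeded substitutions to exercise mismatch tolerances), orthologous segment
pairs diverged at a controlled substitution rate (the COS structure), and
miRNA target sites planted either at corresponding positions inside an
orthologous pair (conserved) or outside any such pair (non-conserved).
Sites and precursors land on either strand with equal probability.

Everything is driven by one seeded generator, so identical configurations
produce byte-identical FASTA and manifest output.  The truth manifest
records every planted element with coordinates, and round-trips losslessly
through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import ESTRecord, MatureMiRNA, PrecursorReference, revcomp, to_dna, to_rna

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    n_ests: int = 200  # per species
    est_length: tuple[int, int] = (400, 800)  # uniform, inclusive
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_planted_precursors: int = 20
    n_conserved_targets: int = 15
    n_nonconserved_targets: int = 15
    cos_divergence: float = 0.10  # substitution rate outside planted sites
    cos_length: int = 500
    n_panel: int = 8  # generated 21-mers when no panel is supplied
    mirna_length: int = 21
    precursor_arm_max_subs: int = 2  # star-arm substitutions, 0..max inclusive
    loop_range: tuple[int, int] = (30, 60)
    seed: int = 7
    mirna_panel: tuple[MatureMiRNA, ...] | None = None

    def __post_init__(self) -> None:
        if min(
            self.n_ests, self.n_planted_precursors,
            self.n_conserved_targets, self.n_nonconserved_targets,
        ) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.cos_divergence < 1:
            raise ValueError("cos_divergence in [0, 1)")
        if self.cos_length < 1:
            raise ValueError("cos_length must be positive")
        if abs(sum(self.base_freqs) - 1) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


@dataclass
class SynthData:
    ests_a: list[ESTRecord]
    ests_b: list[ESTRecord]
    panel: list[MatureMiRNA]
    refs: list[PrecursorReference]
    manifest: list[dict]


def _rand_seq(rng: np.random.Generator, n: int, p: Sequence[float]) -> str:
    return "".join(rng.choice(_BASES, size=n, p=np.asarray(p)))


def _substitute(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for i in positions:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def generate(config: SynthConfig = SynthConfig()) -> SynthData:
    """Build both species' EST sets, the miRNA panel, references and manifest.

    Raises when the planted elements cannot be packed into the configured
    number/length of ESTs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lmin, lmax = cfg.est_length

    # miRNA panel
    if cfg.mirna_panel is not None:
        panel = list(cfg.mirna_panel)
    else:
        panel = []
        seen: set[str] = set()
        while len(panel) < cfg.n_panel:
            seq = to_rna(_rand_seq(rng, cfg.mirna_length, cfg.base_freqs))
            if seq in seen:
                continue
            seen.add(seq)
            k = len(panel) + 1
            panel.append(
                MatureMiRNA(
                    name=f"syn-miR{k}", family=f"miR{k}", species="syn", seq=seq
                )
            )
    if not panel and (cfg.n_planted_precursors or cfg.n_conserved_targets
                      or cfg.n_nonconserved_targets):
        raise ValueError("planting requested but the miRNA panel is empty")

    # orthologous precursor length references, one per family
    refs = []
    loop_lens: dict[str, int] = {}
    for m in panel:
        loop = int(rng.integers(cfg.loop_range[0], cfg.loop_range[1] + 1))
        loop_lens[m.family] = loop
        refs.append(
            PrecursorReference(
                family=m.family, species="syn",
                precursor_length=2 * len(m.seq) + loop,
            )
        )

    non_a = (cfg.n_nonconserved_targets + 1) // 2
    non_b = cfg.n_nonconserved_targets - non_a
    need_a = cfg.n_planted_precursors + cfg.n_conserved_targets + non_a
    need_b = cfg.n_conserved_targets + non_b
    if need_a > cfg.n_ests or need_b > cfg.n_ests:
        raise ValueError(
            f"infeasible packing: need {need_a}/{need_b} carrier ESTs of "
            f"{cfg.n_ests} per species"
        )
    if cfg.n_conserved_targets and cfg.cos_length + 20 > lmax:
        raise ValueError("cos_length does not fit the EST length range")
    max_pre = 2 * cfg.mirna_length + cfg.loop_range[1]
    if cfg.n_planted_precursors and max_pre > lmin:
        raise ValueError("precursors do not fit the shortest EST")

    # roles
    perm_a = rng.permutation(cfg.n_ests)
    perm_b = rng.permutation(cfg.n_ests)
    pre_idx = set(perm_a[: cfg.n_planted_precursors].tolist())
    cos_a_idx = perm_a[
        cfg.n_planted_precursors : cfg.n_planted_precursors + cfg.n_conserved_targets
    ].tolist()
    non_a_idx = perm_a[
        cfg.n_planted_precursors + cfg.n_conserved_targets : need_a
    ].tolist()
    cos_b_idx = perm_b[: cfg.n_conserved_targets].tolist()
    non_b_idx = perm_b[cfg.n_conserved_targets : need_b].tolist()

    def make_background(species: str, cos_carriers: set[int]) -> list[ESTRecord]:
        ests = []
        for i in range(cfg.n_ests):
            lo = max(lmin, cfg.cos_length + 20) if i in cos_carriers else lmin
            n = int(rng.integers(lo, lmax + 1))
            ests.append(
                ESTRecord(
                    id=f"{species}_{i:04d}", species=species,
                    seq=_rand_seq(rng, n, cfg.base_freqs),
                )
            )
        return ests

    ests_a = make_background("species_a", set(cos_a_idx))
    ests_b = make_background("species_b", set(cos_b_idx))
    manifest: list[dict] = []

    def splice(est: ESTRecord, start: int, insert: str) -> ESTRecord:
        seq = est.seq[:start] + insert + est.seq[start + len(insert) :]
        return ESTRecord(id=est.id, species=est.species, seq=seq)

    # planted precursors (species a)
    for i in sorted(pre_idx):
        m = panel[int(rng.integers(len(panel)))]
        mdna = to_dna(m.seq)
        loop = loop_lens[m.family]
        n_subs = int(rng.integers(0, cfg.precursor_arm_max_subs + 1))
        star = revcomp(mdna)
        if n_subs:
            pos = rng.choice(len(star), size=n_subs, replace=False)
            star = _substitute(star, sorted(int(x) for x in pos), rng)
        construct = mdna + _rand_seq(rng, loop, cfg.base_freqs) + star
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            construct = revcomp(construct)
        est = ests_a[i]
        start = int(rng.integers(0, est.length - len(construct) + 1))
        ests_a[i] = splice(est, start, construct)
        manifest.append(
            {
                "kind": "precursor", "species": "species_a", "est_id": est.id,
                "start": start, "end": start + len(construct),
                "mirna": m.name, "family": m.family, "strand": strand,
                "star_subs": n_subs, "loop_len": loop,
            }
        )

    # conserved targets inside orthologous (COS) segment pairs
    for t in range(cfg.n_conserved_targets):
        ia, ib = cos_a_idx[t], cos_b_idx[t]
        m = panel[int(rng.integers(len(panel)))]
        site = revcomp(to_dna(m.seq))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            site = revcomp(site)
        seg = _rand_seq(rng, cfg.cos_length, cfg.base_freqs)
        spos = int(rng.integers(20, cfg.cos_length - len(site) - 20))
        seg_a = seg[:spos] + site + seg[spos + len(site) :]
        # controlled divergence: an exact substitution count outside the
        # planted site, so the realized rate matches the configured rate
        eligible = np.concatenate(
            [np.arange(spos), np.arange(spos + len(site), cfg.cos_length)]
        )
        n_sub = int(round(cfg.cos_divergence * len(eligible)))
        positions = rng.choice(eligible, size=n_sub, replace=False)
        seg_b = _substitute(seg_a, sorted(int(x) for x in positions), rng)
        est_a, est_b = ests_a[ia], ests_b[ib]
        qa = int(rng.integers(0, est_a.length - cfg.cos_length + 1))
        qb = int(rng.integers(0, est_b.length - cfg.cos_length + 1))
        ests_a[ia] = splice(est_a, qa, seg_a)
        ests_b[ib] = splice(est_b, qb, seg_b)
        manifest.append(
            {
                "kind": "cos", "est_a": est_a.id, "est_b": est_b.id,
                "start_a": qa, "end_a": qa + cfg.cos_length,
                "start_b": qb, "end_b": qb + cfg.cos_length,
                "divergence": n_sub / cfg.cos_length,
            }
        )
        manifest.append(
            {
                "kind": "target", "conserved": True, "mirna": m.name,
                "family": m.family, "strand": strand,
                "est_a": est_a.id, "start_a": qa + spos,
                "end_a": qa + spos + len(site),
                "est_b": est_b.id, "start_b": qb + spos,
                "end_b": qb + spos + len(site),
            }
        )

    # non-conserved targets, outside any orthologous segment
    for t in range(cfg.n_nonconserved_targets):
        if t % 2 == 0:
            species, ests, idx = "species_a", ests_a, non_a_idx[t // 2]
        else:
            species, ests, idx = "species_b", ests_b, non_b_idx[t // 2]
        m = panel[int(rng.integers(len(panel)))]
        site = revcomp(to_dna(m.seq))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            site = revcomp(site)
        est = ests[idx]
        start = int(rng.integers(0, est.length - len(site) + 1))
        ests[idx] = splice(est, start, site)
        manifest.append(
            {
                "kind": "target", "conserved": False, "mirna": m.name,
                "family": m.family, "strand": strand, "species": species,
                "est_id": est.id, "start": start, "end": start + len(site),
            }
        )

    for entry in manifest:  # planted coordinates must lie within their EST
        _check_entry(entry, {e.id: e for e in ests_a}, {e.id: e for e in ests_b})
    return SynthData(
        ests_a=ests_a, ests_b=ests_b, panel=panel, refs=refs, manifest=manifest
    )


def _check_entry(entry: dict, by_a: dict, by_b: dict) -> None:
    def inside(est_id: str, start: int, end: int) -> None:
        est = by_a.get(est_id) or by_b.get(est_id)
        if est is None or not (0 <= start < end <= est.length):
            raise AssertionError(f"manifest entry out of bounds: {entry}")

    if entry["kind"] in ("precursor",):
        inside(entry["est_id"], entry["start"], entry["end"])
    elif entry["kind"] == "cos":
        inside(entry["est_a"], entry["start_a"], entry["end_a"])
        inside(entry["est_b"], entry["start_b"], entry["end_b"])
    elif entry["kind"] == "target":
        if entry.get("conserved"):
            inside(entry["est_a"], entry["start_a"], entry["end_a"])
            inside(entry["est_b"], entry["start_b"], entry["end_b"])
        else:
            inside(entry["est_id"], entry["start"], entry["end"])


def save_manifest(manifest: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def config_to_dict(cfg: SynthConfig) -> dict:
    d = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.__dict__.items()
        if k != "mirna_panel"
    }
    return d


def config_from_dict(d: dict) -> SynthConfig:
    kwargs = dict(d)
    for k in ("est_length", "base_freqs", "loop_range"):
        if k in kwargs:
            kwargs[k] = tuple(kwargs[k])
    return SynthConfig(**kwargs)
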