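"""Pipeline orchestration: the staged workflow over two EST datasets.

Each stage is a pure function of (inputs, configuration, seed) writing its
tables under ``outdir/<stage>/`` plus a ``run_meta.json`` (version, config
hash, seed, headline counts).  Stages can be run independently — a missing
upstream artifact raises :class:`MissingArtifactError` naming the file — or
chained with :func:`run_all`.  No timestamps are written, so re-running
with identical inputs and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__, conserved as conserved_mod
from .cosalign import CosParams, CosRegion, find_cos, write_colmaps_json, write_cos_tsv
from .duplexscan import (
    DuplexHit,
    EnergyModel,
    ScanParams,
    count_targeted_ests,
    scan_dataset,
    write_hits_tsv,
)
from .irfinder import IRParams, find_inverted_repeats, write_ir_tsv
from .precursor import (
    HairpinCandidate,
    PrecursorParams,
    extract_window,
    fold_and_validate,
    match_mature_and_star,
    write_candidates_tsv,
    write_vienna,
    write_windows_fasta,
)
from .seqio import (
    ESTRecord,
    MatureMiRNA,
    PrecursorReference,
    dedupe_matures,
    mirna_family,
    parse_mirbase_dat,
    read_fasta,
    to_rna,
    write_fasta,
    write_mature_set,
)
from .shufflestats import StatsParams, evaluate_mirnas, write_stats_tsv
from .synthetic_data import (
    SynthConfig,
    config_from_dict,
    config_to_dict,
    generate,
    save_manifest,
)

log = logging.getLogger("mircos")


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class MissingArtifactError(FileNotFoundError):
    """An upstream stage output is required but absent (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    outdir: Path = Path("mircos_out")
    fasta_a: Path | None = None
    fasta_b: Path | None = None
    species_a: str = "species_a"
    species_b: str = "species_b"
    mature_fasta: Path | None = None
    mirbase_dat: Path | None = None
    species_filter: set[str] | None = None
    refs_tsv: Path | None = None
    seed: int = 0
    precursor_datasets: str = "both"  # a | b | both
    conserved_min_overlap: int = 10
    conserved_require_position: bool = True
    synth: SynthConfig | None = None
    ir: IRParams = field(default_factory=IRParams)
    scan: ScanParams = field(default_factory=ScanParams)
    model: EnergyModel = field(default_factory=EnergyModel)
    precursor: PrecursorParams = field(default_factory=PrecursorParams)
    cos: CosParams = field(default_factory=CosParams)
    stats: StatsParams = field(default_factory=StatsParams)


_BLOCKS = {
    "ir": IRParams,
    "scan": ScanParams,
    "model": EnergyModel,
    "precursor": PrecursorParams,
    "cos": CosParams,
    "stats": StatsParams,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (unknown keys raise)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_mapping(raw, base=Path(path).parent)


def config_from_mapping(raw: dict, base: Path = Path(".")) -> PipelineConfig:
    cfg = PipelineConfig()
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        if key in _BLOCKS:
            cls = _BLOCKS[key]
            try:
                value = cls(**value)
            except TypeError as exc:
                raise ConfigError(f"bad {key} block: {exc}") from exc
        elif key == "synth":
            value = config_from_dict(value)
        elif key in ("fasta_a", "fasta_b", "mature_fasta", "mirbase_dat",
                     "refs_tsv", "outdir"):
            value = (base / value).resolve() if value is not None else None
        elif key == "species_filter" and value is not None:
            value = set(value)
        setattr(cfg, key, value)
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, set, frozenset)):
            return sorted(map(str, o)) if isinstance(o, (set, frozenset)) else str(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_meta(cfg: PipelineConfig, stage: str, counts: dict) -> None:
    d = cfg.outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": __version__,
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "counts": counts,
    }
    with open(d / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing {path} — run `{hint}` first"
        )
    return path


# ---------------------------------------------------------------------------
# input loading


def load_inputs(
    cfg: PipelineConfig,
) -> tuple[list[ESTRecord], list[ESTRecord], list[MatureMiRNA], list[PrecursorReference]]:
    if cfg.fasta_a is None or cfg.fasta_b is None:
        raise ConfigError("fasta_a and fasta_b must be configured (or simulated)")
    ests_a = read_fasta(_require(Path(cfg.fasta_a), "mircos simulate"), cfg.species_a)
    ests_b = read_fasta(_require(Path(cfg.fasta_b), "mircos simulate"), cfg.species_b)
    matures: list[MatureMiRNA] = []
    refs: list[PrecursorReference] = []
    if cfg.mirbase_dat is not None:
        matures, refs = parse_mirbase_dat(
            _require(Path(cfg.mirbase_dat), "provide mirbase_dat"),
            cfg.species_filter,
        )
    elif cfg.mature_fasta is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(
            str(_require(Path(cfg.mature_fasta), "mircos simulate")), "fasta"
        ):
            name = rec.id
            matures.append(
                MatureMiRNA(
                    name=name,
                    family=mirna_family(name),
                    species=name.split("-", 1)[0],
                    seq=to_rna(str(rec.seq)),
                )
            )
    else:
        raise ConfigError("either mature_fasta or mirbase_dat must be configured")
    matures = dedupe_matures(matures)
    if cfg.refs_tsv is not None:
        with open(_require(Path(cfg.refs_tsv), "mircos simulate")) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                refs.append(
                    PrecursorReference(
                        family=row["family"],
                        species=row["species"],
                        precursor_length=int(row["precursor_length"]),
                    )
                )
    return ests_a, ests_b, matures, refs


# ---------------------------------------------------------------------------
# stages


def run_simulate(cfg: PipelineConfig) -> dict:
    """Generate the paired synthetic datasets and wire the config paths."""
    if cfg.synth is None:
        raise ConfigError("no synth block in the configuration")
    d = cfg.outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    data = generate(cfg.synth)
    write_fasta(data.ests_a, d / "ests_a.fasta")
    write_fasta(data.ests_b, d / "ests_b.fasta")
    write_mature_set(data.panel, d / "matures.fasta", d / "matures.tsv")
    with open(d / "refs.tsv", "w") as fh:
        fh.write("family\tspecies\tprecursor_length\n")
        for r in data.refs:
            fh.write(f"{r.family}\t{r.species}\t{r.precursor_length}\n")
    save_manifest(data.manifest, d / "manifest.json")
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cfg.synth), fh)
    cfg.fasta_a = d / "ests_a.fasta"
    cfg.fasta_b = d / "ests_b.fasta"
    cfg.mature_fasta = d / "matures.fasta"
    cfg.refs_tsv = d / "refs.tsv"
    counts = {
        "n_ests_a": len(data.ests_a),
        "n_ests_b": len(data.ests_b),
        "n_panel": len(data.panel),
        "n_manifest": len(data.manifest),
    }
    _write_meta(cfg, "simulate", counts)
    log.info("simulate: %s", counts)
    return counts


def find_candidates_for_est(
    est: ESTRecord,
    matures: Sequence[MatureMiRNA],
    refs: Sequence[PrecursorReference],
    cfg: PipelineConfig,
) -> list[HairpinCandidate]:
    """IR detection + mature/star matching + fold validation for one EST."""
    out: list[HairpinCandidate] = []
    for ir in find_inverted_repeats(est, cfg.ir):
        for cand in match_mature_and_star(ir, est, matures, refs, cfg.precursor):
            cand = extract_window(est, cand, cfg.precursor.window)
            out.append(fold_and_validate(cand, cfg.model, cfg.precursor))
    return out


def run_precursors(cfg: PipelineConfig) -> dict:
    ests_a, ests_b, matures, refs = load_inputs(cfg)
    datasets = {
        "a": [("a", ests_a)],
        "b": [("b", ests_b)],
        "both": [("a", ests_a), ("b", ests_b)],
    }[cfg.precursor_datasets]
    d = cfg.outdir / "precursors"
    d.mkdir(parents=True, exist_ok=True)
    all_cands: list[HairpinCandidate] = []
    all_irs = []
    for _tag, ests in datasets:
        for est in ests:
            irs = find_inverted_repeats(est, cfg.ir)
            all_irs.extend(irs)
            for ir in irs:
                for cand in match_mature_and_star(
                    ir, est, matures, refs, cfg.precursor
                ):
                    cand = extract_window(est, cand, cfg.precursor.window)
                    all_cands.append(
                        fold_and_validate(cand, cfg.model, cfg.precursor)
                    )
    write_ir_tsv(all_irs, d / "inverted_repeats.tsv")
    write_candidates_tsv(all_cands, d / "candidates.tsv")
    write_windows_fasta(all_cands, d / "windows.fasta")
    write_vienna([c for c in all_cands if c.status == "validated"], d / "hairpins.vienna")
    counts = {
        "n_inverted_repeats": len(all_irs),
        "n_candidates": len(all_cands),
        "n_validated": sum(1 for c in all_cands if c.status == "validated"),
        "n_ests_with_validated": len(
            {c.est_id for c in all_cands if c.status == "validated"}
        ),
    }
    _write_meta(cfg, "precursors", counts)
    log.info("precursors: %s", counts)
    return counts


def run_targets(cfg: PipelineConfig) -> dict:
    ests_a, ests_b, matures, _refs = load_inputs(cfg)
    d = cfg.outdir / "targets"
    d.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    for tag, ests in (("a", ests_a), ("b", ests_b)):
        hits = scan_dataset(matures, ests, cfg.scan, cfg.model)
        write_hits_tsv(hits, d / f"hits_{tag}.tsv")
        ge1, ge2 = count_targeted_ests(hits, ests)
        counts[f"n_hits_{tag}"] = len(hits)
        counts[f"n_targeted_ests_{tag}"] = ge1
        counts[f"n_multi_targeted_ests_{tag}"] = ge2
        counts[f"n_ests_{tag}"] = len(ests)
    _write_meta(cfg, "targets", counts)
    log.info("targets: %s", counts)
    return counts


def run_cos(cfg: PipelineConfig) -> dict:
    ests_a, ests_b, _m, _r = load_inputs(cfg)
    d = cfg.outdir / "cos"
    d.mkdir(parents=True, exist_ok=True)
    regions = find_cos(ests_a, ests_b, cfg.cos)
    write_cos_tsv(regions, d / "cos.tsv")
    write_colmaps_json(regions, d / "colmaps.json")
    counts = {
        "n_cos_regions": len(regions),
        "n_ests_a_in_cos": len({r.est_a for r in regions}),
        "n_ests_b_in_cos": len({r.est_b for r in regions}),
    }
    _write_meta(cfg, "cos", counts)
    log.info("cos: %s", counts)
    return counts


def _read_hits_tsv(path: Path) -> list[DuplexHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            energy = float(row["energy"])
            ratio = float(row["ratio"])
            hits.append(
                DuplexHit(
                    mirna=row["mirna"],
                    est_id=row["est_id"],
                    strand=row["strand"],
                    site=(int(row["start"]) - 1, int(row["end"])),
                    n_mismatch=int(row["mm"]),
                    n_loops=int(row["loops"]),
                    overhang5=int(row["oh5"]),
                    overhang3=int(row["oh3"]),
                    energy=energy,
                    perfect_energy=energy / ratio if ratio else energy,
                )
            )
    return hits


def _read_cos(outdir: Path) -> list[CosRegion]:
    tsv = _require(outdir / "cos" / "cos.tsv", "mircos cos")
    cmap = _require(outdir / "cos" / "colmaps.json", "mircos cos")
    with open(cmap) as fh:
        colmaps = json.load(fh)
    regions = []
    with open(tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            cm = colmaps[row["cos_id"]]
            regions.append(
                CosRegion(
                    id=row["cos_id"],
                    est_a=row["qseqid"],
                    est_b=row["sseqid"],
                    interval_a=(int(row["qstart"]) - 1, int(row["qend"])),
                    interval_b=(int(row["sstart"]) - 1, int(row["send"])),
                    aligned_length=int(row["length"]),
                    n_matches=int(row["nident"]),
                    score=int(row["score"]),
                    evalue=float(row["evalue"]),
                    colmap_a=np.array(cm["a"], dtype=np.int64),
                    colmap_b=np.array(cm["b"], dtype=np.int64),
                )
            )
    return regions


def run_conserved(cfg: PipelineConfig) -> dict:
    d = cfg.outdir / "conserved"
    d.mkdir(parents=True, exist_ok=True)
    hits_a = _read_hits_tsv(
        _require(cfg.outdir / "targets" / "hits_a.tsv", "mircos targets")
    )
    hits_b = _read_hits_tsv(
        _require(cfg.outdir / "targets" / "hits_b.tsv", "mircos targets")
    )
    regions = _read_cos(cfg.outdir)
    targets, summary = conserved_mod.intersect_conserved(
        hits_a,
        hits_b,
        regions,
        min_overlap=cfg.conserved_min_overlap,
        require_position=cfg.conserved_require_position,
    )
    conserved_mod.write_conserved_tsv(targets, d / "conserved.tsv")
    conserved_mod.write_conserved_summary(summary, d / "summary.json")
    _write_meta(cfg, "conserved", summary)
    log.info("conserved: %s", summary)
    return summary


def run_stats(cfg: PipelineConfig) -> dict:
    ests_a, ests_b, matures, _refs = load_inputs(cfg)
    regions = _read_cos(cfg.outdir)
    hits_a = _read_hits_tsv(
        _require(cfg.outdir / "targets" / "hits_a.tsv", "mircos targets")
    )
    hits_b = _read_hits_tsv(
        _require(cfg.outdir / "targets" / "hits_b.tsv", "mircos targets")
    )
    d = cfg.outdir / "stats"
    d.mkdir(parents=True, exist_ok=True)
    # the statistical universe: ESTs organised in COS regions, both species
    in_cos_a = {r.est_a for r in regions}
    in_cos_b = {r.est_b for r in regions}
    subset = [e for e in ests_a if e.id in in_cos_a] + [
        e for e in ests_b if e.id in in_cos_b
    ]
    observed = [
        h for h in hits_a if h.est_id in in_cos_a
    ] + [h for h in hits_b if h.est_id in in_cos_b]
    sp = dataclasses.replace(cfg.stats, rng_seed=cfg.seed)
    stats = evaluate_mirnas(
        matures, subset, observed_hits=observed,
        params=sp, scan_params=cfg.scan, model=cfg.model,
    )
    write_stats_tsv(stats, d / "mirna_stats.tsv")
    counts = {
        "n_mirnas": len(stats),
        "n_evaluable": sum(1 for s in stats if s.evaluable),
        "n_passing": sum(1 for s in stats if s.passes),
        "n_cos_ests": len(subset),
    }
    _write_meta(cfg, "stats", counts)
    log.info("stats: %s", counts)
    return counts


def run_all(cfg: PipelineConfig) -> dict:
    summary: dict = {}
    if cfg.synth is not None:
        summary["simulate"] = run_simulate(cfg)
    summary["precursors"] = run_precursors(cfg)
    summary["targets"] = run_targets(cfg)
    summary["cos"] = run_cos(cfg)
    summary["conserved"] = run_conserved(cfg)
    summary["stats"] = run_stats(cfg)
    with open(cfg.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
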