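"""Sequence I/O: EST FASTA handling and miRBase ``miRNA.dat`` parsing.

ESTs are cDNA and are stored as DNA (``U`` normalised to ``T`` on input);
mature miRNAs come from miRBase and are stored as RNA.  Every cross-alphabet
comparison elsewhere in the package goes through :func:`to_dna` /
:func:`to_rna` explicitly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

#: records with more than this fraction of N are dropped with a warning
MAX_N_FRACTION = 0.10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqIOError(ValueError):
    """Malformed sequence input (bad character, duplicate id, empty record)."""


def to_dna(seq: str) -> str:
    """RNA → DNA (U→T), uppercased."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """DNA → RNA (T→U), uppercased."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ESTRecord:
    """One EST sequence; the unit of every scan in the pipeline."""

    id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("EST record with empty id")
        if not self.seq:
            raise SeqIOError(f"EST {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise SeqIOError(
                f"EST {self.id!r}: illegal character(s) {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA (RNA alphabet) with family/species provenance.

    ``source_accessions`` lists the names of all identical matures merged
    into this record by :func:`dedupe_matures`.
    """

    name: str
    family: str
    species: str
    seq: str
    source_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise SeqIOError(
                f"mature {self.name!r}: illegal character(s) {sorted(bad)!r}"
            )
        if not 19 <= len(self.seq) <= 25:
            raise SeqIOError(
                f"mature {self.name!r}: length {len(self.seq)} outside 19-25 nt"
            )
        if not self.source_accessions:
            object.__setattr__(self, "source_accessions", (self.name,))

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrecursorReference:
    """Length of a known (orthologous) pre-miRNA hairpin for one family."""

    family: str
    species: str
    precursor_length: int

    def __post_init__(self) -> None:
        if self.precursor_length <= 0:
            raise ValueError("precursor_length must be positive")


_FAMILY_RE = re.compile(r"(?:mir|MIR|miR|let|lin)-?0*(\d+)", re.IGNORECASE)


def mirna_family(name: str) -> str:
    """Family label from a miRNA name: ``ath-miR398a-5p`` → ``miR398``.

    Falls back to the name itself when no numeric family id is present.
    """
    m = _FAMILY_RE.search(name)
    if m is None:
        return name
    return f"miR{int(m.group(1))}"


def _species_prefix(name: str) -> str:
    return name.split("-", 1)[0] if "-" in name else ""


def read_fasta(path: str | Path, species: str = "") -> list[ESTRecord]:
    """Read an EST FASTA file into validated :class:`ESTRecord` objects.

    Sequences are uppercased and U is normalised to T.  Duplicate ids and
    characters outside ``{A,C,G,T,N}`` raise :class:`SeqIOError`; records
    with more than 10% N are dropped with a warning (EST data is noisy and
    heavily-masked reads carry no usable signal).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ESTRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate EST id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = to_dna(str(rec.seq))
        est = ESTRecord(id=rec.id, species=species, seq=seq)
        if est.seq.count("N") > MAX_N_FRACTION * est.length:
            warnings.warn(
                f"EST {est.id!r}: >{MAX_N_FRACTION:.0%} N, record dropped",
                stacklevel=2,
            )
            continue
        records.append(est)
    return records


def write_fasta(records: Iterable[ESTRecord], path: str | Path) -> None:
    """Write ESTs as FASTA, 60-column wrapped (round-trips byte-exactly)."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


def parse_mirbase_dat(
    path: str | Path,
    species_filter: set[str] | None = None,
) -> tuple[list[MatureMiRNA], list[PrecursorReference]]:
    """Parse a miRBase ``miRNA.dat`` EMBL flat file.

    Returns one (possibly redundant) :class:`MatureMiRNA` per ``miRNA``
    feature of each retained hairpin — a hairpin may carry several mature
    features — and one :class:`PrecursorReference` per hairpin, whose length
    is the hairpin sequence length.  ``species_filter`` keeps only hairpins
    whose name starts with one of the given prefixes (e.g. ``{"ath","osa"}``).

    Mature features whose coordinates exceed the hairpin raise; matures
    outside the canonical 19-25 nt range are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    matures: list[MatureMiRNA] = []
    refs: list[PrecursorReference] = []
    for rec in SeqIO.parse(str(path), "embl"):
        name = rec.name  # hairpin name from the ID line, e.g. ath-MIR398a
        prefix = _species_prefix(name)
        if species_filter is not None and prefix not in species_filter:
            continue
        hairpin = to_rna(str(rec.seq))
        refs.append(
            PrecursorReference(
                family=mirna_family(name),
                species=prefix,
                precursor_length=len(hairpin),
            )
        )
        for feat in rec.features:
            if feat.type != "miRNA":
                continue
            start, end = int(feat.location.start), int(feat.location.end)
            if end > len(hairpin) or start < 0:
                raise SeqIOError(
                    f"{name}: miRNA feature {start}..{end} exceeds hairpin "
                    f"length {len(hairpin)}"
                )
            product = feat.qualifiers.get("product", [None])[0] or name
            seq = hairpin[start:end]
            try:
                matures.append(
                    MatureMiRNA(
                        name=product,
                        family=mirna_family(product),
                        species=prefix,
                        seq=seq,
                    )
                )
            except SeqIOError as exc:
                warnings.warn(f"skipping mature {product!r}: {exc}", stacklevel=2)
    return matures, refs


def dedupe_matures(matures: Sequence[MatureMiRNA]) -> list[MatureMiRNA]:
    """Collapse exact-sequence duplicates into a non-redundant mature set.

    Comparison is case-insensitive on the RNA alphabet.  The first-seen name
    becomes canonical and all merged names accumulate in
    ``source_accessions``; output order is first occurrence, so the operation
    is deterministic and idempotent.
    """
    by_seq: dict[str, MatureMiRNA] = {}
    order: list[str] = []
    for m in matures:
        key = to_rna(m.seq)
        if key not in by_seq:
            by_seq[key] = MatureMiRNA(
                name=m.name,
                family=m.family,
                species=m.species,
                seq=key,
                source_accessions=tuple(m.source_accessions),
            )
            order.append(key)
        else:
            prev = by_seq[key]
            by_seq[key] = MatureMiRNA(
                name=prev.name,
                family=prev.family,
                species=prev.species,
                seq=key,
                source_accessions=prev.source_accessions
                + tuple(m.source_accessions),
            )
    return [by_seq[k] for k in order]


def write_mature_set(
    matures: Sequence[MatureMiRNA], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Serialize a non-redundant mature set as FASTA plus a provenance TSV."""
    with open(fasta_path, "w") as fh:
        for m in matures:
            fh.write(f">{m.name}\n{m.seq}\n")
    with open(tsv_path, "w") as fh:
        fh.write("name\tfamily\tspecies\tn_sources\n")
        for m in matures:
            fh.write(
                f"{m.name}\t{m.family}\t{m.species}\t{len(m.source_accessions)}\n"
            )
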