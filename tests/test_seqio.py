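"""EST FASTA handling, miRBase flat-file parsing and mature deduplication."""

import warnings

from hypothesis import given, settings
from hypothesis import strategies as st

import pytest

from mircos.seqio import (
    ESTRecord,
    MatureMiRNA,
    SeqIOError,
    dedupe_matures,
    mirna_family,
    parse_mirbase_dat,
    read_fasta,
    revcomp,
    to_dna,
    to_rna,
    write_fasta,
)

MIRBASE_FIXTURE = """\
ID   ath-MIR398a       standard; RNA; PLN; 82 BP.
XX
AC   MI0000999;
XX
DE   Arabidopsis thaliana miR398a stem-loop
XX
FH   Key             Location/Qualifiers
FH
FT   miRNA           5..25
FT                   /accession="MIMAT0900001"
FT                   /product="ath-miR398a-5p"
FT   miRNA           58..78
FT                   /accession="MIMAT0900002"
FT                   /product="ath-miR398a-3p"
XX
SQ   Sequence 82 BP; 20 A; 20 C; 20 G; 0 T; 22 other;
     aaaauguguucucaggucaccccuuugaacacaaggucuuaaggguuaucagggugaccu     60
     gagaacacauuuuaaaaaaaaa                                            82
//
ID   osa-MIR528       standard; RNA; PLN; 60 BP.
XX
AC   MI0000998;
XX
DE   Oryza sativa miR528 stem-loop
XX
FH   Key             Location/Qualifiers
FH
FT   miRNA           3..23
FT                   /accession="MIMAT0900003"
FT                   /product="osa-miR528"
XX
SQ   Sequence 60 BP; 15 A; 15 C; 15 G; 0 T; 15 other;
     ccuggaaggggcaugcagaggagcgaagcuucgccgaacucuucaugggcagggaggggc     60
//
"""


def test_read_fasta_normalizes_and_validates(tmp_path):
    p = tmp_path / "ests.fasta"
    p.write_text(">e1\nacgu\n")
    recs = read_fasta(p, species="x")
    assert len(recs) == 1
    assert recs[0].seq == "ACGT"
    assert recs[0].length == 4
    assert recs[0].species == "x"


def test_read_fasta_empty_file(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert read_fasta(p) == []


def test_read_fasta_wrapped_lines_match_independent_parse(tmp_path, rng):
    seqs = {
        f"w{i}": "".join(rng.choice(list("ACGT"), size=n))
        for i, n in enumerate((137, 60, 203))
    }
    text = ""
    for name, seq in seqs.items():
        text += f">{name}\n"
        for k in range(0, len(seq), 50):
            text += seq[k : k + 50] + "\n"
    p = tmp_path / "wrapped.fasta"
    p.write_text(text)
    recs = read_fasta(p)
    # independent parse: concatenate non-header lines per record
    manual: dict[str, str] = {}
    cur = None
    for line in text.splitlines():
        if line.startswith(">"):
            cur = line[1:]
            manual[cur] = ""
        else:
            manual[cur] += line
    assert {r.id: r.seq for r in recs} == manual
    assert [r.length for r in recs] == [len(s) for s in seqs.values()]


@pytest.mark.parametrize(
    "content,message",
    [
        (">a\nACGT\n>a\nACGT\n", "duplicate"),
        (">a\nAXGT\n", "illegal"),
        (">a\n\n>b\nACGT\n", "empty"),
    ],
)
def test_read_fasta_error_cases(tmp_path, content, message):
    p = tmp_path / "bad.fasta"
    p.write_text(content)
    with pytest.raises(SeqIOError, match=message):
        read_fasta(p)


def test_read_fasta_missing_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_fasta(tmp_path / "nope.fasta")


def test_read_fasta_drops_n_heavy_records_with_warning(tmp_path):
    p = tmp_path / "n.fasta"
    p.write_text(">ok\nACGTACGTAC\n>bad\nNNNNNACGTA\n")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        recs = read_fasta(p)
    assert [r.id for r in recs] == ["ok"]
    assert any("dropped" in str(w.message) for w in caught)


def test_fasta_round_trip_byte_exact(tmp_path, rng):
    recs = [
        ESTRecord(f"r{i}", "s", "".join(rng.choice(list("ACGT"), size=n)))
        for i, n in enumerate((59, 60, 61, 150))
    ]
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    write_fasta(recs, p1)
    back = read_fasta(p1, species="s")
    assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]
    write_fasta(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_alphabet_conversions():
    assert to_dna("augc") == "ATGC"
    assert to_rna("ATGC") == "AUGC"
    assert revcomp("ACGTN") == "NACGT"


def test_mirna_family_parsing():
    assert mirna_family("ath-miR398a-5p") == "miR398"
    assert mirna_family("osa-miR528") == "miR528"
    assert mirna_family("ath-MIR0398a") == "miR398"
    assert mirna_family("weird-name") == "weird-name"


def test_parse_mirbase_dat_features_and_filter(tmp_path):
    p = tmp_path / "miRNA.dat"
    p.write_text(MIRBASE_FIXTURE)
    matures, refs = parse_mirbase_dat(p)
    assert [m.name for m in matures] == [
        "ath-miR398a-5p", "ath-miR398a-3p", "osa-miR528"
    ]
    assert [r.precursor_length for r in refs] == [82, 60]
    assert refs[0].family == "miR398" and refs[0].species == "ath"
    assert matures[0].seq == to_rna(matures[0].seq)  # RNA alphabet
    assert len(matures[0].seq) == 21

    only_ath, refs_ath = parse_mirbase_dat(p, species_filter={"ath"})
    assert [m.name for m in only_ath] == ["ath-miR398a-5p", "ath-miR398a-3p"]
    assert len(refs_ath) == 1
    none, _ = parse_mirbase_dat(p, species_filter={"zma"})
    assert none == []


def test_parse_mirbase_dat_bad_coordinates(tmp_path):
    bad = MIRBASE_FIXTURE.replace("FT   miRNA           58..78",
                                  "FT   miRNA           58..99")
    p = tmp_path / "bad.dat"
    p.write_text(bad)
    with pytest.raises(SeqIOError, match="exceeds"):
        parse_mirbase_dat(p)


def _mat(name: str, seq: str) -> MatureMiRNA:
    return MatureMiRNA(name=name, family=mirna_family(name), species="x", seq=seq)


def test_dedupe_merges_and_is_idempotent():
    a = _mat("x-miR1", "ACGUACGUACGUACGUACGUA")
    b = _mat("x-miR1b", "ACGUACGUACGUACGUACGUA")
    c = _mat("x-miR2", "UUUUGGGGCCCCAAAAUUUUG")
    out = dedupe_matures([a, b, c])
    assert [m.name for m in out] == ["x-miR1", "x-miR2"]
    assert out[0].source_accessions == ("x-miR1", "x-miR1b")
    assert dedupe_matures(out) == out
    assert dedupe_matures([]) == []


def test_dedupe_conserves_source_count(default_synth, rng):
    pool = []
    for m in default_synth.panel:
        for k in range(int(rng.integers(1, 4))):
            pool.append(_mat(f"{m.name}.{k}", m.seq))
    out = dedupe_matures(pool)
    assert sum(len(m.source_accessions) for m in out) == len(pool)
    assert len({m.seq for m in out}) == len(out)


@given(
    picks=st.lists(st.tuples(st.integers(0, 5), st.integers(0, 3)),
                   max_size=20)
)
@settings(max_examples=40, deadline=None)
def test_dedupe_properties_hold_for_arbitrary_pools(picks):
    """Idempotence and source-count conservation over arbitrary inputs."""
    suffixes = ["AA", "AC", "AG", "AU", "CA", "CC"]
    seqs = ["ACGUACGUACGUACGUACG" + s for s in suffixes]
    pool = [_mat(f"x-miR{i}v{v}", seqs[i]) for i, v in picks]
    out = dedupe_matures(pool)
    assert dedupe_matures(out) == out
    assert sum(len(m.source_accessions) for m in out) == len(pool)
    assert len({m.seq for m in out}) == len(out)


def test_mature_validation():
    with pytest.raises(SeqIOError, match="length"):
        _mat("x-miR9", "ACGU")
    with pytest.raises(SeqIOError, match="illegal"):
        _mat("x-miR9", "ACGTACGTACGTACGTACGTA")  # DNA alphabet rejected
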