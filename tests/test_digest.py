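"""Tryptic digestion, FASTA reading and I/L canonicalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xenopept import (
    DigestParams,
    ProteinRecord,
    build_peptide_index,
    canonicalize_il,
    digest_protein,
    read_fasta,
)
from xenopept.digest import FastaParseError, read_index_tsv, write_index_tsv

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=120)


# ---------------------------------------------------------------- FASTA I/O

def test_read_fasta_concatenates_wrapped_lines(tmp_path):
    f = tmp_path / "a.fasta"
    f.write_text(">P1 some description\nMAKR\nLIPK\n")
    records = read_fasta(f)
    assert len(records) == 1
    assert records[0].accession == "P1"
    assert records[0].description == "some description"
    assert records[0].sequence == "MAKRLIPK"


def test_read_fasta_empty_file_and_case(tmp_path):
    f = tmp_path / "a.fasta"
    f.write_text("")
    assert read_fasta(f) == []
    f.write_text(">P1\nmak r\n")
    assert read_fasta(f)[0].sequence == "MAKR"


@pytest.mark.parametrize(
    "content, match",
    [
        (">P1\nMAKR\n>P1\nLIPK\n", "duplicate accession"),
        (">P1\n>P2\nMAKR\n", "empty sequence"),
        ("MAKR\n", "before first header"),
        (">\nMAKR\n", "empty header"),
    ],
)
def test_read_fasta_errors_name_the_line(tmp_path, content, match):
    f = tmp_path / "a.fasta"
    f.write_text(content)
    with pytest.raises(FastaParseError, match=match):
        read_fasta(f)


def test_read_fasta_agrees_with_biopython(tmp_path, rng):
    from Bio import SeqIO

    f = tmp_path / "r.fasta"
    with f.open("w") as handle:
        for i in range(20):
            seq = "".join(rng.choice(list(AA), size=rng.integers(10, 200)))
            handle.write(f">R{i} desc {i}\n")
            for j in range(0, len(seq), 60):
                handle.write(seq[j : j + 60] + "\n")
    ours = read_fasta(f)
    theirs = list(SeqIO.parse(str(f), "fasta"))
    assert [(r.accession, r.sequence) for r in ours] == [
        (r.id, str(r.seq)) for r in theirs
    ]


# ------------------------------------------------------- I/L canonical form

@pytest.mark.parametrize(
    "peptide, expected",
    [("PEPTIDE", "PEPTLDE"), ("ILLI", "LLLL"), ("", ""), ("MAKR", "MAKR")],
)
def test_canonicalize_examples(peptide, expected):
    assert canonicalize_il(peptide) == expected


@settings(derandomize=True, max_examples=200)
@given(sequences)
def test_canonicalize_idempotent_and_length_preserving(seq):
    canon = canonicalize_il(seq)
    assert canonicalize_il(canon) == canon
    assert len(canon) == len(seq)
    assert "I" not in canon
    # non-I positions unchanged
    assert all(a == b for a, b in zip(seq, canon) if a != "I")


# ----------------------------------------------------------------- digestion

def test_digest_example_one_missed(loose_params):
    rec = ProteinRecord("P1", "", "MAKRLIPK")
    peps = {(p.peptide, p.missed) for p in digest_protein(rec, loose_params)}
    assert peps == {("MAK", 0), ("R", 0), ("LIPK", 0), ("MAKR", 1), ("RLIPK", 1)}


def test_digest_proline_rule():
    rec = ProteinRecord("P1", "", "AKPGR")
    params = DigestParams(max_missed_cleavages=0, min_length=1, max_length=100)
    assert [p.peptide for p in digest_protein(rec, params)] == ["AKPGR"]
    no_rule = DigestParams(
        max_missed_cleavages=0, min_length=1, max_length=100, proline_rule=False
    )
    assert [p.peptide for p in digest_protein(rec, no_rule)] == ["AK", "PGR"]


def test_digest_empty_and_length_filter(loose_params):
    assert digest_protein(ProteinRecord("P", "", ""), loose_params) == []
    rec = ProteinRecord("P1", "", "MAKRLIPK")
    params = DigestParams(max_missed_cleavages=1, min_length=4, max_length=50)
    assert {p.peptide for p in digest_protein(rec, params)} == {
        "MAKR", "RLIPK", "LIPK"
    }


def test_digest_flags_nonstandard_residues(loose_params):
    rec = ProteinRecord("P1", "", "MAXKR")
    peps = digest_protein(rec, loose_params)
    flagged = [p for p in peps if p.has_nonstandard]
    assert flagged and all("X" in p.peptide for p in flagged)


@settings(derandomize=True, max_examples=300)
@given(sequences)
def test_reconstruction_and_composition(seq):
    """0-missed peptides concatenate to the source; each 1-missed peptide is
    the concatenation of two adjacent 0-missed peptides."""
    params = DigestParams(max_missed_cleavages=1, min_length=1, max_length=10_000)
    rec = ProteinRecord("P", "", seq)
    peps = digest_protein(rec, params)
    zero = [p for p in peps if p.missed == 0]
    assert "".join(p.peptide for p in zero) == seq
    pos = {p.start: i for i, p in enumerate(zero)}
    for p in peps:
        if p.missed == 1:
            i = pos[p.start]
            assert p.peptide == zero[i].peptide + zero[i + 1].peptide


@settings(derandomize=True, max_examples=200)
@given(sequences)
def test_digest_commutes_with_canonicalization(seq):
    """I/L are not cleavage-relevant: digest∘canonicalize == canonicalize∘digest."""
    params = DigestParams(max_missed_cleavages=1, min_length=1, max_length=10_000)
    a = [
        (canonicalize_il(p.peptide), p.start, p.missed)
        for p in digest_protein(ProteinRecord("P", "", seq), params)
    ]
    b = [
        (p.peptide, p.start, p.missed)
        for p in digest_protein(ProteinRecord("P", "", canonicalize_il(seq)), params)
    ]
    assert a == b


def test_digest_agrees_with_pyteomics(rng):
    from pyteomics import parser as pparser

    for _ in range(25):
        seq = "".join(rng.choice(list(AA), size=int(rng.integers(20, 200))))
        params = DigestParams(max_missed_cleavages=1, min_length=1, max_length=10_000)
        ours = {p.peptide for p in digest_protein(ProteinRecord("P", "", seq), params)}
        theirs = pparser.cleave(seq, "trypsin", missed_cleavages=1, min_length=1)
        assert ours == set(theirs)


# -------------------------------------------------------------------- index

def test_build_index_canonical_keys():
    params = DigestParams(max_missed_cleavages=0, min_length=1, max_length=100)
    index = build_peptide_index([ProteinRecord("P1", "", "MAKLIR")], params)
    assert set(index.keys()) == {"MAK", "LLR"}
    assert index.occurrences("LIR") == {("P1", 3, 0)}


def test_build_index_multi_occurrence_and_determinism(toy_graft, loose_params):
    index1 = build_peptide_index(toy_graft, loose_params)
    index2 = build_peptide_index(list(reversed(toy_graft)), loose_params)
    assert index1.mapping == index2.mapping
    # LIPK occurs in G2; MAK-like peptides in both toy proteins
    shared_key = canonicalize_il("MAK")
    accs = {acc for acc, _, _ in index1.mapping.get(shared_key, set())}
    assert "G1" in accs


def test_build_index_empty_input_raises(loose_params):
    with pytest.raises(ValueError):
        build_peptide_index([], loose_params)


def test_index_tsv_round_trip(tmp_path, toy_graft, loose_params):
    index = build_peptide_index(toy_graft, loose_params)
    path = tmp_path / "index.tsv"
    write_index_tsv(index, path)
    back = read_index_tsv(path, loose_params)
    assert back.mapping == index.mapping


def test_digest_params_validation():
    with pytest.raises(ValueError):
        DigestParams(min_length=10, max_length=5)
    with pytest.raises(ValueError):
        DigestParams(max_missed_cleavages=-1)
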