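"""Evidence parsing, xcorr/FDR filtering and unique-peptide counting."""

import pytest

from xenopept import (
    CountMatrix,
    FilterParams,
    PsmRecord,
    apply_fdr_threshold,
    count_unique_peptides,
    filter_by_xcorr,
    pass_xcorr,
    read_evidence_table,
    write_evidence_table,
)

GROUPS = {"S1": "control", "S2": "tumor"}


def _psm(pep="PEPTIDEK", acc=("P1",), sample="S1", charge=2, xcorr=3.0, decoy=False):
    return PsmRecord(
        sample_id=sample, accessions=acc, peptide=pep, charge=charge,
        xcorr=xcorr, is_decoy=decoy,
    )


# ------------------------------------------------------------------ table IO

def test_evidence_round_trip(tmp_path):
    records = [
        _psm(),
        _psm(pep="LLRK", acc=("P1", "P2"), sample="S2", charge=3, xcorr=2.75, decoy=True),
    ]
    path = tmp_path / "ev.tsv"
    write_evidence_table(records, path)
    back = read_evidence_table(path)
    assert [(r.sample_id, r.accessions, r.peptide, r.charge, r.xcorr, r.is_decoy) for r in back] == [
        (r.sample_id, r.accessions, r.peptide, r.charge, r.xcorr, r.is_decoy) for r in records
    ]
    assert back[1].accessions == ("P1", "P2")  # ';'-joined cell carries both


@pytest.mark.parametrize(
    "content, match",
    [
        ("sample\taccessions\tpeptide\tcharge\txcorr\n", "missing column"),
        (
            "sample\taccessions\tpeptide\tcharge\txcorr\tis_decoy\n"
            "S1\tP1\tPEPK\ttwo\t3.0\t0\n",
            "row 2",
        ),
        (
            "sample\taccessions\tpeptide\tcharge\txcorr\tis_decoy\n"
            "S1\tP1\tPEPK\t2\t3.0\t0\nS1\t\tPEPK\t2\t3.0\t0\n",
            "row 3",
        ),
    ],
)
def test_evidence_parse_errors(tmp_path, content, match):
    path = tmp_path / "bad.tsv"
    path.write_text(content)
    with pytest.raises(ValueError, match=match):
        read_evidence_table(path)


# --------------------------------------------------------------- xcorr gate

@pytest.mark.parametrize(
    "charge, xcorr, expected",
    [
        (1, 1.81, True), (1, 1.8, False),
        (2, 2.3, True), (2, 2.2, False),
        (3, 2.5, False), (3, 2.51, True),
        (4, 3.5, False), (4, 3.6, True),
        (5, 3.6, True), (7, 3.5, False),  # charges >4 inherit the +4 cutoff
    ],
)
def test_pass_xcorr_strict_thresholds(charge, xcorr, expected):
    params = FilterParams()
    assert pass_xcorr(_psm(charge=charge, xcorr=xcorr), params) is expected


def test_filter_by_xcorr_idempotent():
    params = FilterParams()
    records = [_psm(xcorr=2.3), _psm(xcorr=2.1), _psm(charge=3, xcorr=2.6)]
    once = filter_by_xcorr(records, params)
    assert filter_by_xcorr(once, params) == once
    assert [r.xcorr for r in once] == [2.3, 2.6]


# ----------------------------------------------------------------- FDR gate

def test_fdr_no_decoys_retains_everything():
    records = [_psm(xcorr=2.3 + 0.01 * i) for i in range(100)]
    kept, fdr, cut = apply_fdr_threshold(records, FilterParams())
    assert len(kept) == 100
    assert fdr == 0.0
    assert cut == pytest.approx(2.3)


def test_fdr_single_decoy_among_few_targets_forces_tightening():
    # 99 targets, 1 decoy below them all: full set has FDR 1/99 > 1%,
    # so the gate must cut the decoy away
    records = [_psm(xcorr=3.0 + 0.01 * i) for i in range(99)]
    records.append(_psm(xcorr=2.0, decoy=True))
    kept, fdr, cut = apply_fdr_threshold(records, FilterParams(fdr_max=0.01))
    assert len(kept) == 99
    assert fdr == 0.0
    assert cut > 2.0


def test_fdr_unachievable_reports_best():
    records = [_psm(xcorr=3.0, decoy=True), _psm(xcorr=2.5)]
    with pytest.raises(ValueError, match="best achievable"):
        apply_fdr_threshold(records, FilterParams(fdr_max=0.01))


def test_fdr_retained_set_monotone_in_ceiling(rng):
    records = [
        _psm(pep=f"PEP{i}K", xcorr=float(rng.uniform(1.0, 5.0)),
             decoy=bool(rng.random() < 0.2))
        for i in range(400)
    ]
    sizes = []
    for fdr_max in (0.20, 0.10, 0.05):
        kept, fdr, _ = apply_fdr_threshold(records, FilterParams(fdr_max=fdr_max))
        assert fdr <= fdr_max
        sizes.append(len(kept))
    assert sizes[0] >= sizes[1] >= sizes[2]


def test_fdr_order_independent(rng):
    records = [
        _psm(pep=f"PEP{i}K", xcorr=float(rng.uniform(1.0, 5.0)),
             decoy=bool(rng.random() < 0.1))
        for i in range(200)
    ]
    kept1, fdr1, cut1 = apply_fdr_threshold(records, FilterParams(fdr_max=0.05))
    shuffled = list(records)
    rng.shuffle(shuffled)
    kept2, fdr2, cut2 = apply_fdr_threshold(shuffled, FilterParams(fdr_max=0.05))
    assert (fdr1, cut1) == (fdr2, cut2)
    assert set(kept1) == set(kept2)


def test_fdr_estimate_tracks_realized_false_proportion(rng):
    """On spiked data with known score distributions, the estimated FDR at
    the chosen cut bounds the realized false proportion (Monte-Carlo)."""
    records = []
    truth = {}
    for i in range(4000):
        pep = f"TRUE{i}K"
        records.append(_psm(pep=pep, xcorr=float(rng.normal(3.5, 0.6))))
        truth[pep] = True
    for i in range(4000):
        # incorrect targets and decoys share the null score distribution
        score = float(abs(rng.normal(1.4, 0.5)))
        if rng.random() < 0.5:
            records.append(_psm(pep=f"FALSE{i}K", xcorr=score))
            truth[f"FALSE{i}K"] = False
        else:
            records.append(_psm(pep=f"DEC{i}K", xcorr=score, decoy=True))
    kept, fdr, _ = apply_fdr_threshold(records, FilterParams(fdr_max=0.01))
    realized = sum(not truth[r.peptide] for r in kept) / len(kept)
    assert fdr <= 0.01
    assert realized <= 0.01 + 3 / len(kept) ** 0.5


# ----------------------------------------------------------------- counting

def test_count_distinct_sequences_not_spectra():
    records = [
        _psm(pep="AAAK"), _psm(pep="AAAK"), _psm(pep="LIRK"),
    ]
    m = count_unique_peptides(records, GROUPS)
    assert m.counts.loc["P1", "S1"] == 2


def test_count_merges_il_equivalent_peptides():
    records = [_psm(pep="LIRK"), _psm(pep="ILRK")]
    m = count_unique_peptides(records, GROUPS)
    assert m.counts.loc["P1", "S1"] == 1


def test_count_empty_records_gives_zero_matrix():
    m = count_unique_peptides([], GROUPS)
    assert m.counts.shape == (0, 2)
    assert list(m.counts.columns) == ["S1", "S2"]


def test_count_multimapped_increments_each_and_flags():
    records = [_psm(pep="AAAK", acc=("P1", "P2"))]
    m = count_unique_peptides(records, GROUPS)
    assert m.counts.loc["P1", "S1"] == 1
    assert m.counts.loc["P2", "S1"] == 1
    assert m.shared_proteins == {"P1", "P2"}
    excl = count_unique_peptides(records, GROUPS, exclude_shared=True)
    assert excl.counts.shape[0] == 0


def test_count_spectral_mode_counts_rows():
    records = [_psm(pep="AAAK"), _psm(pep="AAAK"), _psm(pep="LIRK")]
    m = count_unique_peptides(records, GROUPS, mode="spectral_counts")
    assert m.counts.loc["P1", "S1"] == 3


def test_count_unknown_sample_raises():
    with pytest.raises(ValueError, match="no group label"):
        count_unique_peptides([_psm(sample="S9")], GROUPS)


def test_count_invariant_to_order_and_duplication(rng):
    records = [
        _psm(pep=f"PEP{i % 7}K", acc=(f"P{i % 3}",), sample="S1")
        for i in range(30)
    ]
    base = count_unique_peptides(records, GROUPS)
    shuffled = list(records)
    rng.shuffle(shuffled)
    doubled = shuffled + shuffled
    again = count_unique_peptides(doubled, GROUPS)
    assert base.counts.sort_index().equals(again.counts.sort_index())


def test_count_matrix_tsv_round_trip(tmp_path):
    records = [_psm(pep="AAAK"), _psm(pep="LIRK", sample="S2")]
    m = count_unique_peptides(records, GROUPS)
    path = tmp_path / "counts.tsv"
    m.to_tsv(path)
    back = CountMatrix.from_tsv(path)
    assert back.counts.equals(m.counts)
    assert back.groups == m.groups


def test_psm_validation():
    with pytest.raises(ValueError):
        _psm(pep="")
    with pytest.raises(ValueError):
        _psm(charge=0)
    with pytest.raises(ValueError):
        FilterParams(fdr_max=1.5)
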