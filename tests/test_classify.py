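import pytest

from mitoscribe.classify import (
    LABELS,
    classify_all,
    classify_transcript,
    cleavage_direction_evidence,
    detect_utrs,
    tally_polycistron_types,
    transcripts_of_unit,
)
from mitoscribe.coords import CoordinateError
from mitoscribe.transcripts import TranscriptAlignment as T


def test_bicistronic_coi_nd3(refined):
    c = classify_transcript(T("a", "J", 1, 1891), refined, tol=3)
    assert c.label == "mature_multi"
    assert c.sense_genes() == ["COI", "ND3"]


def test_polycistron_with_antisense_content(refined):
    c = classify_transcript(T("a", "J", 4409, 6659), refined, tol=3)
    assert c.label == "polycistronic"
    assert c.content_names == ["trnI", "CYTB", "astrnY", "ND2"]


def test_five_prime_truncation_is_degraded(refined):
    c = classify_transcript(T("a", "J", 1100, 1539), refined, tol=3)
    assert c.label == "degraded"
    assert c.truncation == "5prime"
    assert not c.end5_matched and c.end3_matched


def test_ncrna_cr(refined):
    cr1 = refined.get("CR1")
    c = classify_transcript(T("a", "J", cr1.start + 2, cr1.end - 2), refined, tol=3)
    assert c.label == "ncRNA_CR"


def test_antisense(refined):
    # N-strand transcript over the J-strand gene COI
    c = classify_transcript(T("a", "N", 1, 1539), refined, tol=3)
    assert c.label == "antisense"
    assert c.content_names == ["asCOI"]


def test_out_of_genome_errors(refined):
    with pytest.raises(CoordinateError):
        classify_transcript(T("a", "J", 1, 20_000), refined)


def test_single_label_totality(classified):
    for c in classified:
        assert c.label in LABELS
    assert len(classified) > 0


def test_mature_requires_matched_ends(classified):
    for c in classified:
        if c.label in ("mature_mono", "mature_multi"):
            assert c.end5_matched and c.end3_matched


def test_tally_polycistron_types(refined):
    ts = (
        [T(f"a{i}", "J", 4409, 6659) for i in range(3)]  # trnI/CYTB/astrnY/ND2
        + [T(f"b{i}", "J", 1, 1955) for i in range(2)]  # COI/ND3/trnL2
    )
    classified = classify_all(ts, refined, tol=3)
    df = tally_polycistron_types(classified)
    assert len(df) == 2
    assert sorted(df["count"]) == [2, 3]
    assert df["count"].sum() == sum(c.label == "polycistronic" for c in classified)


def test_tally_empty():
    assert len(tally_polycistron_types([])) == 0


def test_cleavage_reverse_vote_trnv_lrrna(refined):
    trnv = refined.get("trnV")
    lrrna = refined.get("lrRNA")
    # trnV+lrRNA precursor still carrying the internal trnV junction,
    # 3' flush with the cut site before the absent downstream tRNA
    t = T("a", "J", trnv.start, lrrna.end)
    ev = cleavage_direction_evidence(classify_all([t], refined), refined)
    votes = {e.junction[1]: e.direction_votes for e in ev}
    assert any(v["reverse"] == 1 for v in votes.values())
    assert all(v["forward"] == 0 for v in votes.values())


def test_cleavage_forward_vote_coi_nd3_trnl2_coii(refined):
    coii = refined.get("COII")
    t = T("a", "J", 1, coii.end)  # COI/ND3/trnL2/COII, upstream trnS2 absent
    ev = cleavage_direction_evidence(classify_all([t], refined), refined)
    votes = {e.junction[1]: e.direction_votes for e in ev}
    assert "trnS2" in votes and votes["trnS2"]["forward"] == 1


def test_mature_mono_trna_no_votes(refined):
    trng = refined.get("trnG")
    t = T("a", "J", trng.start, trng.end)
    ev = cleavage_direction_evidence(classify_all([t], refined), refined)
    assert sum(sum(e.direction_votes.values()) for e in ev) == 0


def test_mature_unit_no_votes(refined):
    # a fully processed bicistronic unit witnesses neither direction
    t = T("a", "J", 1, 1891)  # mature COI/ND3
    ev = cleavage_direction_evidence(classify_all([t], refined), refined)
    assert sum(sum(e.direction_votes.values()) for e in ev) == 0


def test_utr_lengths_coiii(refined):
    for end, utr3 in ((3872, 5), (3987, 120)):
        c = classify_transcript(T("a", "J", 2959, end, polyA_len=20), refined, tol=3)
        report = detect_utrs(c, refined)
        assert report.gene == "COIII"
        assert report.utr5_len == 0
        assert report.utr3_len == utr3
        assert report.utr3_retained
        assert report.polyadenylation_site == end


def test_utr_flush(refined):
    c = classify_transcript(T("a", "J", 2959, 3867), refined, tol=3)
    report = detect_utrs(c, refined)
    assert (report.utr5_len, report.utr3_len) == (0, 0)
    assert not report.utr3_retained


def test_utr_type_errors(refined):
    degraded = classify_transcript(T("a", "J", 1100, 1539), refined, tol=3)
    with pytest.raises(TypeError):
        detect_utrs(degraded, refined)
    trna = classify_transcript(
        T("b", "J", refined.get("trnG").start, refined.get("trnG").end), refined
    )
    with pytest.raises(TypeError):
        detect_utrs(trna, refined)


def test_transcripts_of_unit(refined):
    ts = [
        T("m1", "J", 5678, 6659),  # ND2 isoform
        T("m2", "J", 5678, 6400),  # truncated ND2
        T("p1", "J", 4409, 6659),  # precursor carrying other genes
    ]
    classified = classify_all(ts, refined, tol=3)
    unit = transcripts_of_unit(classified, ["ND2"])
    ids = {c.transcript.id for c in unit}
    assert ids == {"m1", "m2"}
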