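from mitoscribe.classify import classify_all
from mitoscribe.regulatory import (
    build_transcription_model,
    call_tis_tts,
    end_pileups,
    find_cr_repeats,
    scan_cr_motifs,
)
from mitoscribe.simulate import make_toy_genome
from mitoscribe.transcripts import TranscriptAlignment as T


def _calls(ts, refined, **kw):
    return end_pileups(classify_all(ts, refined, tol=3), refined, **kw)


def test_antisense_five_prime_pileup(refined):
    # four N-strand antisense transcripts initiating at 13864 inside lrRNA
    ts = [T(f"t{i}", "N", 13500, 13864) for i in range(4)]
    calls = _calls(ts, refined)
    five = [c for c in calls if c.end_type == "five_prime"]
    assert len(five) == 1
    assert (five[0].position, five[0].strand, five[0].support) == (13864, "N", 4)


def test_scattered_ends_no_call(refined):
    ts = [T(f"t{i}", "N", 13450 + 10 * i, 13864) for i in range(4)]
    calls = _calls(ts, refined)
    assert all(c.end_type != "three_prime" for c in calls)


def test_boundary_ends_excluded(refined):
    ts = [T(f"t{i}", "J", 1, 1539) for i in range(6)]  # flush mature COI
    assert _calls(ts, refined) == []


def test_degraded_transcripts_excluded(refined):
    ts = [T(f"t{i}", "J", 1100, 1539) for i in range(6)]  # 5'-truncated COI
    assert _calls(ts, refined) == []


def test_min_site_support(refined):
    ts = [T(f"t{i}", "N", 13500, 13864) for i in range(2)]
    assert _calls(ts, refined, min_site_support=3) == []
    assert len(_calls(ts, refined, min_site_support=2)) > 0


def test_in_cr_flag_and_call_names(refined):
    # ncRNA transcripts wholly inside CR2 (9478-9736)
    ts = [T(f"t{i}", "J", 9550, 9700) for i in range(5)]
    calls = call_tis_tts(_calls(ts, refined), refined)
    by_type = {c.end_type: c for c in calls}
    assert by_type["five_prime"].call == "TIS_candidate"
    assert by_type["five_prime"].in_CR == "CR2"
    assert by_type["three_prime"].call == "TTS_candidate"
    assert by_type["three_prime"].in_CR == "CR2"


def test_run_around_three_prime_excluded(refined):
    # a 3'-end pileup one base before a same-strand 5'-end pileup marks a
    # polymerase running back into its own initiation site, not a terminator
    ts = [T(f"a{i}", "J", 9550, 9700) for i in range(5)]
    ts += [T(f"b{i}", "J", 9610, 9549) for i in range(5)]  # full-circle stop at 9549
    for t in ts:
        if t.start > t.end:
            t.wraps_origin = True
    calls = _calls(ts, refined)
    three = {c.position for c in calls if c.end_type == "three_prime"}
    assert 9549 not in three


def test_motif_ga_n_t():
    hits = scan_cr_motifs("CCGAAAATCC")
    ga = [h for h in hits if h.motif_class == "GA_n_T"]
    assert len(ga) == 1
    assert (ga[0].start, ga[0].end, ga[0].detail) == (3, 8, "n=4")


def test_motif_ta_repeat_and_runs():
    hits = scan_cr_motifs("CCTATATATATACCAAAAAGG")
    classes = {h.motif_class for h in hits}
    assert "TA_repeat" in classes
    ta = next(h for h in hits if h.motif_class == "TA_repeat")
    assert "units=5" in ta.detail
    polya = next(h for h in hits if h.motif_class == "polyA_run")
    assert polya.detail == "run=5"


def test_planted_stem_loop():
    stem, loop = "AAACCCGG", "GAG"
    seq = "CTCTC" + stem + loop + "CCGGGTTT" + "CTCTC"
    hits = scan_cr_motifs(seq, min_stem=5, max_loop=8)
    sl = [h for h in hits if h.motif_class == "stem_loop"]
    assert sl, "planted hairpin not found"
    best = max(sl, key=lambda h: h.end - h.start)
    assert "stem=8" in best.detail and "loop=3" in best.detail
    assert (best.start, best.end) == (6, 6 + 2 * 8 + 3 - 1)


def test_no_stem_loop_in_plain_sequence():
    hits = scan_cr_motifs("ACACACACAC", min_stem=5)
    assert not [h for h in hits if h.motif_class == "stem_loop"]


def test_planted_cr_repeat_recovered():
    ann, seq = make_toy_genome(8, seed=1, duplicated_cr=True, repeat_len=140)
    crs = ann.crs()
    assert len(crs) == 2
    pairs = find_cr_repeats(
        seq, (crs[0].start, crs[0].end), (crs[1].start, crs[1].end), min_len=100
    )
    assert pairs, "planted repeat not recovered"
    best = pairs[0]
    assert best.length >= 120
    assert best.identity >= 0.9
    # reported coordinates really do match
    a = seq[best.posA - 1 : best.posA - 1 + best.length]
    b = seq[best.posB - 1 : best.posB - 1 + best.length]
    matches = sum(x == y for x, y in zip(a, b))
    assert matches / best.length == best.identity


def test_no_repeat_between_unrelated_windows():
    ann, seq = make_toy_genome(8, seed=4)
    cr = ann.crs()[0]
    gene = next(r for r in ann.records if r.category == "rRNA")
    pairs = find_cr_repeats(
        seq, (cr.start, cr.end), (gene.start, gene.end), min_len=50
    )
    assert pairs == []


def test_transcription_model_summary(refined, sim, classified):
    calls = call_tis_tts(end_pileups(classified, refined), refined)
    model = build_transcription_model(calls, classified, refined)
    assert set(model.strands) == {"J", "N"}
    n_tis = [c.position for c in model.strands["N"].tis]
    assert any(abs(p - 13864) <= 3 for p in n_tis)
    for strand in ("J", "N"):
        assert set(model.strands[strand].fully_transcribed_crs) == {"CR1", "CR2"}
    d = model.to_dict()
    assert "undetected_antisense_blocks" in d
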