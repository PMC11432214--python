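import numpy as np
import pytest
from scipy import stats

from mitoscribe.classify import classify_all, cleavage_direction_evidence
from mitoscribe.simulate import (
    ScenarioError,
    default_scenario,
    make_toy_genome,
    simulate_transcripts,
    truth_table,
)


def _key(t):
    return (t.id, t.strand, t.start, t.end, t.wraps_origin, t.polyA_len)


def test_determinism_same_seed():
    a = simulate_transcripts(default_scenario(n_transcripts=300))
    b = simulate_transcripts(default_scenario(n_transcripts=300))
    assert [_key(t) for t in a.transcripts] == [_key(t) for t in b.transcripts]
    assert [vars(x) for x in a.truths] == [vars(y) for y in b.truths]


def test_different_seed_differs():
    a = simulate_transcripts(default_scenario(n_transcripts=300))
    b = simulate_transcripts(default_scenario(n_transcripts=300, seed=7))
    assert [_key(t) for t in a.transcripts] != [_key(t) for t in b.transcripts]


def test_reverse_only_cleavage_purity(refined):
    sc = default_scenario(
        reverse_fraction=1.0, degradation_fraction=0.0, end_noise_sd=0.0,
        n_transcripts=1500,
    )
    res = simulate_transcripts(sc)
    ev = cleavage_direction_evidence(classify_all(res.transcripts, refined), refined)
    rev = sum(e.direction_votes["reverse"] for e in ev)
    fwd = sum(e.direction_votes["forward"] for e in ev)
    assert rev > 0 and fwd == 0


def test_forward_only_cleavage_purity(refined):
    sc = default_scenario(
        reverse_fraction=0.0, degradation_fraction=0.0, end_noise_sd=0.0,
        n_transcripts=1500,
    )
    res = simulate_transcripts(sc)
    ev = cleavage_direction_evidence(classify_all(res.transcripts, refined), refined)
    rev = sum(e.direction_votes["reverse"] for e in ev)
    fwd = sum(e.direction_votes["forward"] for e in ev)
    assert fwd > 0 and rev == 0


def test_strand_draw_tracks_tis_strengths():
    # min_length=1 so no strand-asymmetric short-fragment drops skew the count
    sc = default_scenario(n_transcripts=2000, min_length=1)
    sc.tis = {"J": [(3880, 3.0)], "N": [(13864, 1.0)]}
    res = simulate_transcripts(sc)
    n_j = sum(t.strand == "J" for t in res.transcripts)
    n = len(res.transcripts)
    # initiations split 3:1 by summed strand strength
    p = stats.binomtest(n_j, n, 0.75).pvalue
    assert p > 1e-4


def test_degradation_bookkeeping():
    res = simulate_transcripts(default_scenario(n_transcripts=800))
    df = truth_table(res.truths)
    degraded = df[df["trim_len"] > 0]
    assert set(degraded["degraded_end"]) <= {"5prime", "3prime"}
    assert (df.loc[df["trim_len"] == 0, "degraded_end"].isna()).all()
    frac = len(degraded) / len(df)
    assert 0.1 < frac < 0.3


def test_min_length_enforced_and_dropped_reported():
    sc = default_scenario(n_transcripts=500, min_length=400)
    res = simulate_transcripts(sc)
    assert res.n_dropped_short > 0
    assert len(res.transcripts) + res.n_dropped_short == 500
    L = sc.annotation.genome_length
    for t in res.transcripts:
        length = (t.end - t.start + 1) if not t.wraps_origin else (L - t.start + 1 + t.end)
        assert length >= 400


def test_scenario_validation_errors():
    with pytest.raises(ScenarioError, match="completion"):
        default_scenario(cleavage_completion=1.5).validate()
    sc = default_scenario()
    sc.tis = {"J": [], "N": []}
    with pytest.raises(ScenarioError, match="TIS"):
        sc.validate()
    sc = default_scenario()
    sc.tts = {"J": [(3950, 2.0)], "N": []}
    with pytest.raises(ScenarioError, match="read-through"):
        sc.validate()


def test_transcripts_validate_against_genome():
    res = simulate_transcripts(default_scenario(n_transcripts=400))
    L = 14_965
    for t in res.transcripts:
        t.validate(L)  # raises on any malformed coordinate


def test_toy_genome_determinism_and_structure():
    ann1, seq1 = make_toy_genome(8, seed=3)
    ann2, seq2 = make_toy_genome(8, seed=3)
    assert seq1 == seq2
    assert [r.name for r in ann1.records] == [r.name for r in ann2.records]
    assert ann1.genome_length == len(seq1)
    cats = {r.category for r in ann1.records}
    assert {"PCG", "tRNA", "rRNA", "CR"} <= cats
    assert ann1.validate() == []  # toy genomes carry no table quirks


def test_toy_genome_too_few_genes():
    with pytest.raises(ValueError, match="at least 4"):
        make_toy_genome(3)
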