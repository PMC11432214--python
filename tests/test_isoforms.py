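import random

from mitoscribe.isoforms import (
    cluster_isoforms,
    degradation_orientation,
    isoform_table,
)
from mitoscribe.transcripts import TranscriptAlignment as T

L = 14_965


def _nd2_like(n1=135, n2=18):
    ts = [T(f"i1_{i}", "J", 5678, 6659) for i in range(n1)]
    ts += [T(f"i2_{i}", "J", 5678, 6582) for i in range(n2)]
    return ts


def test_two_nd2_isoforms():
    clusters, leftovers = cluster_isoforms(
        _nd2_like(), tol=3, min_support=5, unit="ND2", genome_length=L
    )
    assert [(c.end5, c.end3, c.support) for c in clusters] == [
        (5678, 6659, 135),
        (5678, 6582, 18),
    ]
    assert clusters[0].length(L) == 982
    assert leftovers == []


def test_low_support_species_becomes_leftover():
    ts = _nd2_like(n1=135, n2=4)
    clusters, leftovers = cluster_isoforms(ts, tol=3, min_support=5, genome_length=L)
    assert len(clusters) == 1
    assert len(leftovers) == 4


def test_all_identical_one_cluster():
    ts = [T(f"t{i}", "J", 100, 400) for i in range(30)]
    clusters, leftovers = cluster_isoforms(ts, tol=3, min_support=5, genome_length=L)
    assert len(clusters) == 1 and clusters[0].support == 30 and not leftovers


def test_tol_zero_exact_grouping():
    ts = [T(f"a{i}", "J", 100, 400) for i in range(6)] + [
        T(f"b{i}", "J", 100, 401) for i in range(6)
    ]
    clusters, _ = cluster_isoforms(ts, tol=0, min_support=5, genome_length=L)
    assert len(clusters) == 2
    clusters, _ = cluster_isoforms(ts, tol=3, min_support=5, genome_length=L)
    assert len(clusters) == 1 and clusters[0].support == 12


def test_five_simulated_clusters_recovered():
    rng = random.Random(3)
    planted = [(13820, 14902, 133), (13820, 14500, 116), (13900, 14902, 62), (13820, 14200, 64), (14000, 14902, 22)]
    ts = []
    for k, (e5, e3, n) in enumerate(planted):
        for i in range(n):
            ts.append(
                T(
                    f"c{k}_{i}",
                    "J",
                    e5 + rng.randint(-1, 1),
                    e3 + rng.randint(-1, 1),
                )
            )
    clusters, _ = cluster_isoforms(ts, tol=3, min_support=5, genome_length=L)
    assert len(clusters) == 5
    for e5, e3, n in planted:
        match = [
            c for c in clusters if abs(c.end5 - e5) <= 3 and abs(c.end3 - e3) <= 3
        ]
        assert len(match) == 1 and match[0].support == n


def test_order_permutation_determinism():
    ts = _nd2_like()
    rng = random.Random(9)
    shuffled = list(ts)
    rng.shuffle(shuffled)
    a, _ = cluster_isoforms(ts, tol=3, min_support=5, genome_length=L)
    b, _ = cluster_isoforms(shuffled, tol=3, min_support=5, genome_length=L)
    assert [(c.end5, c.end3, c.support) for c in a] == [
        (c.end5, c.end3, c.support) for c in b
    ]


def test_n_strand_bio_ends_used():
    # N-strand species: bio 5' is the high coordinate
    ts = [T(f"t{i}", "N", 9856, 11532) for i in range(8)]
    clusters, _ = cluster_isoforms(ts, tol=3, min_support=5, genome_length=L)
    assert (clusters[0].end5, clusters[0].end3) == (11532, 9856)
    assert clusters[0].length(L) == 1677


def test_degradation_orientation_three_to_five():
    ts = _nd2_like(n1=20, n2=0)
    # ragged 3' ends, intact 5' ends: 3'->5' exonuclease
    ts += [T(f"d{i}", "J", 5678, 6659 - 50 - 17 * i) for i in range(6)]
    clusters, _ = cluster_isoforms(ts, tol=3, min_support=5, genome_length=L)
    prof = degradation_orientation(ts, clusters, tol=3, unit="ND2", genome_length=L)
    assert prof.orientation == "three_to_five"
    assert prof.n_truncated == 6
    assert prof.end3_spread > 0 and prof.end5_spread == 0


def test_degradation_orientation_five_to_three_and_none():
    ts = _nd2_like(n1=20, n2=0)
    clusters, _ = cluster_isoforms(ts, tol=3, min_support=5, genome_length=L)
    assert degradation_orientation(ts, clusters, genome_length=L).orientation == "none"
    ragged = ts + [T(f"d{i}", "J", 5678 + 40 + 11 * i, 6659) for i in range(4)]
    prof = degradation_orientation(ragged, clusters, genome_length=L)
    assert prof.orientation == "five_to_three"


def test_isoform_table_columns():
    clusters, _ = cluster_isoforms(_nd2_like(), tol=3, min_support=5, unit="ND2", genome_length=L)
    df = isoform_table(clusters, L)
    assert list(df.columns) == ["unit", "end5", "end3", "support", "length"]
    assert df.loc[0, "length"] == 982
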