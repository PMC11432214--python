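import random

import pytest

from mitoscribe import coords
from mitoscribe.annotation import (
    GeneRecord,
    MitoAnnotation,
    ReconciliationError,
    adjacent_relations,
    all_overlapping_pairs,
    compare_annotations,
    gene_length,
)
from mitoscribe.simulate import make_toy_genome


def test_fixture_gene_counts(refined):
    genes = refined.genes()
    assert len(genes) == 37
    by_cat = {}
    for g in genes:
        by_cat[g.category] = by_cat.get(g.category, 0) + 1
    assert by_cat == {"PCG": 13, "tRNA": 22, "rRNA": 2}
    assert len(refined.crs()) == 2
    assert refined.genome_length == 14_965


def test_printed_gene_lengths(refined):
    expected = {"COIII": 909, "ND5": 1677, "ND4": 1304, "ND4L": 279, "ATP8": 169}
    for name, length in expected.items():
        assert gene_length(refined.get(name), refined.genome_length) == length


def test_gene_length_brute_force_oracle():
    rng = random.Random(7)
    L = 14_965
    for _ in range(1000):
        s = rng.randint(1, L)
        e = rng.randint(1, L)
        wraps = s > e
        rec = GeneRecord("g", "tRNA", "J", s, e, wraps_origin=wraps)
        assert rec.length(L) == len(list(coords.positions(s, e, L, wraps)))


def test_adjacent_relations_spec_pairs(dna, refined):
    rel_dna = {(a, b): (o, s) for a, b, o, s in adjacent_relations(dna)}
    assert rel_dna[("ND3", "trnL2")] == (1, 0)  # one-base overlap
    rel_ref = {(a, b): (o, s) for a, b, o, s in adjacent_relations(refined)}
    assert rel_ref[("ND3", "trnL2")] == (0, 0)  # flush after refinement


def test_adjacent_relations_exclusivity(refined):
    for _a, _b, overlap, spacer in adjacent_relations(refined):
        assert overlap >= 0 and spacer >= 0
        assert not (overlap > 0 and spacer > 0)


def test_adjacent_relations_interval_oracle(refined):
    L = refined.genome_length
    for a, b, overlap, _s in adjacent_relations(refined):
        ra, rb = refined.get(a), refined.get(b)
        brute = len(
            set(coords.positions(ra.start, ra.end, L, ra.wraps_origin))
            & set(coords.positions(rb.start, rb.end, L, rb.wraps_origin))
        )
        assert overlap == brute


def test_one_free_base_spacer():
    ann = MitoAnnotation(
        100,
        [
            GeneRecord("a", "tRNA", "J", 1, 50),
            GeneRecord("b", "tRNA", "J", 52, 99),
        ],
    )
    rel = {(x, y): (o, s) for x, y, o, s in adjacent_relations(ann)}
    assert rel[("a", "b")] == (0, 1)


def test_tiling_identity_on_toy_genomes():
    for seed in range(5):
        ann, _ = make_toy_genome(9, seed=seed)
        L = ann.genome_length
        rel = adjacent_relations(ann)
        total = (
            sum(r.length(L) for r in ann.records)
            - sum(o for _a, _b, o, _s in rel)
            + sum(s for _a, _b, _o, s in rel)
        )
        assert total == L


def test_validate_hard_errors():
    with pytest.raises(ValueError, match="duplicate"):
        MitoAnnotation(
            100,
            [GeneRecord("a", "tRNA", "J", 1, 60), GeneRecord("a", "tRNA", "J", 61, 99)],
        ).validate()
    with pytest.raises(ValueError, match="strand"):
        MitoAnnotation(100, [GeneRecord("a", "tRNA", "X", 1, 60)]).validate()


def test_validate_soft_warnings(refined):
    warnings = refined.validate()
    # printed-table quirks surface as warnings, not errors
    assert any("ND4L" in w for w in warnings)


def test_compare_annotations_matches_published_diff(dna, refined):
    diff = compare_annotations(dna, refined)
    moved = set(diff.changed_genes())
    published = {
        "ND3", "COIII", "CYTB", "ND2", "ND1", "ATP6", "ND6",
        "trnR", "trnT", "srRNA", "lrRNA",
    }
    assert published <= moved
    assert moved - published <= {"CR2"}  # CR2 shifts with the trnT boundary


def test_eliminated_overlaps(dna, refined):
    diff = compare_annotations(dna, refined)
    eliminated = {frozenset(p) for p in diff.eliminated_overlaps}
    assert eliminated == {
        frozenset(p)
        for p in [
            ("ND3", "trnL2"),
            ("trnF", "srRNA"),
            ("srRNA", "ATP8"),
            ("trnV", "lrRNA"),
            ("lrRNA", "trnS2"),
            ("ATP8", "ATP6"),
        ]
    }
    assert frozenset(("trnV", "lrRNA")) in eliminated


def test_compare_annotations_identity(refined):
    diff = compare_annotations(refined, refined)
    assert diff.is_empty()


def test_compare_annotations_gene_set_mismatch(refined):
    other = MitoAnnotation(
        refined.genome_length, [r for r in refined.records if r.name != "COI"]
    )
    with pytest.raises(ReconciliationError, match="COI"):
        compare_annotations(refined, other)


def test_all_overlapping_pairs_refined(refined):
    pairs = {frozenset((a, b)) for a, b, _ in all_overlapping_pairs(refined)}
    # the refinement keeps only the biologically persistent overlaps
    assert frozenset(("ND4", "ND4L")) in pairs
    assert frozenset(("ND3", "trnL2")) not in pairs
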