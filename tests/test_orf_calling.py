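"""ORF enumeration, coding-potential scoring, best-ORF selection."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrproteo.orf_calling import (
    CODING_POTENTIAL_COEFFS,
    CandidateORF,
    enumerate_candidate_orfs,
    fickett_position_bias,
    genomic_footprint,
    locate_stop_and_junctions,
    mark_reference_starts,
    score_candidates,
    score_coding_potential,
    select_best_orf,
    transcript_to_genomic,
)
from lrproteo.reference_model import Exon
from oracles import brute_force_orf_scan


def test_no_aug_means_no_candidates():
    assert enumerate_candidate_orfs("t", "CCCGGGTTTCCC" * 10) == []


def test_fifty_nt_boundary_inclusive():
    seq = "ATG" + "GCC" * 15 + "TAA"  # 51 nt, start through stop inclusive
    cands = enumerate_candidate_orfs("t", seq)
    assert len(cands) == 1 and cands[0].orf_nt_length == 51
    shorter = "ATG" + "GCC" * 14 + "TAA"  # 48 nt
    assert enumerate_candidate_orfs("t", shorter) == []


def test_nested_orfs_sharing_a_stop_are_distinct_candidates():
    seq = "ATG" + "GCA" * 10 + "ATG" + "GCC" * 20 + "TAA"
    cands = enumerate_candidate_orfs("t", seq)
    assert len(cands) == 2
    assert {c.upstream_augs_skipped for c in cands} == {0, 1}
    assert len({c.stop_nt for c in cands}) == 1


def test_n_codon_truncates_candidate():
    seq = "ATG" + "GCC" * 20 + "GNC" + "GCC" * 10 + "TAA"
    (c,) = enumerate_candidate_orfs("t", seq)
    assert not c.has_stop_codon
    assert c.stop_nt == 3 + 60
    assert c.protein_sequence == "M" + "A" * 20


def test_enumeration_matches_brute_force_scanner_on_random_sequences():
    rng = random.Random(11)
    for i in range(500):
        n = rng.randint(60, 2000)
        seq = "".join(rng.choice("ACGTN" if i % 7 == 0 else "ACGT") for _ in range(n))
        got = [(c.start_nt, c.stop_nt, c.has_stop_codon)
               for c in enumerate_candidate_orfs("t", seq)]
        assert got == brute_force_orf_scan(seq)


def test_score_is_deterministic_and_monotone_in_coverage():
    seq = "ATG" + "GCC" * 40 + "TAA" + "CACGCA" * 40
    cands = enumerate_candidate_orfs("t", seq)
    (c,) = cands
    s1 = score_coding_potential(c, seq)
    s2 = score_coding_potential(c, seq)
    assert s1 == s2 and 0.0 <= s1 <= 1.0
    # same ORF on a shorter transcript covers more of it -> score >=
    short = seq[: c.stop_nt + 30]
    assert score_coding_potential(c, short) >= s1


def test_logistic_standin_matches_hand_computed_sigmoid():
    seq = "ATG" + "GAACAC" * 16 + "TAA"  # 102-nt ORF covering the transcript
    (c,) = enumerate_candidate_orfs("t", seq)
    b0, b1, b2, b3 = CODING_POTENTIAL_COEFFS
    coverage = c.orf_nt_length / len(seq)
    codons = min((c.orf_nt_length // 3) / 100, 1.0)
    bias = fickett_position_bias(seq[c.start_nt : c.stop_nt])
    expected = 1.0 / (1.0 + math.exp(-(b0 + b1 * coverage + b2 * codons + b3 * bias)))
    assert score_coding_potential(c, seq) == pytest.approx(expected)


def test_external_score_table_overrides_standin():
    seq = "ATG" + "GCC" * 20 + "TAA"
    cands = enumerate_candidate_orfs("t", seq)
    score_candidates(cands, seq, scores={("t", 0): 0.123})
    assert cands[0].coding_potential == 0.123


def make_cand(start=0, length=90, ref=False, skipped=0, cp=0.5, stop=True):
    return CandidateORF(
        pb_accession="t",
        start_nt=start,
        stop_nt=start + length,
        has_stop_codon=stop,
        protein_sequence="M" * (length // 3 - 1),
        coding_potential=cp,
        start_matches_reference=ref,
        upstream_augs_skipped=skipped,
    )


def test_single_candidate_selected_with_tier_only():
    b = select_best_orf([make_cand()])
    assert b.selection_tier == "only"
    assert select_best_orf([]) is None


def test_reference_start_beats_longer_novel_orf():
    a = make_cand(start=300, length=270, ref=True, skipped=3)  # 90 aa
    b = make_cand(start=0, length=600, ref=False, skipped=0)  # 200 aa
    best = select_best_orf([a, b])
    assert best.orf is a and best.selection_tier == "reference-start"


def test_fewest_skipped_augs_decides_between_novel_starts():
    a = make_cand(start=0, skipped=0, cp=0.2)
    b = make_cand(start=60, skipped=2, cp=0.9)
    best = select_best_orf([a, b])
    assert best.orf is a and best.selection_tier == "fewest-skipped"


def test_selection_is_a_total_order_invariant_to_input_permutation():
    cands = [
        make_cand(start=0, length=90, cp=0.5),
        make_cand(start=9, length=120, cp=0.5),
        make_cand(start=18, length=120, cp=0.7),
        make_cand(start=27, length=90, ref=True, skipped=1),
    ]
    picks = set()
    for perm in itertools.permutations(cands):
        picks.add(select_best_orf(list(perm)).orf.start_nt)
    assert len(picks) == 1


@given(st.lists(
    st.tuples(st.integers(0, 50), st.booleans(), st.integers(0, 4),
              st.floats(0, 1, allow_nan=False), st.integers(60, 300)),
    min_size=2, max_size=6))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_selection_agrees_with_exhaustive_sort(specs):
    cands = [
        make_cand(start=s, length=(l // 3) * 3, ref=r, skipped=k, cp=c)
        for s, r, k, c, l in specs
    ]
    best = select_best_orf(cands).orf
    ranked = sorted(
        cands,
        key=lambda c: (
            not c.start_matches_reference,
            c.upstream_augs_skipped,
            -c.coding_potential,
            -c.orf_nt_length,
            c.start_nt,
        ),
    )
    assert best is ranked[0]


# ---------------------------------------------------------------------------
# Coordinate mapping


def plus_exons(coords):
    return [Exon("c", s, e, "+") for s, e in coords]


def test_transcript_to_genomic_both_strands():
    ex = plus_exons([(100, 110), (120, 130)])
    assert transcript_to_genomic(0, ex) == 100
    assert transcript_to_genomic(10, ex) == 120
    rev = [Exon("c", 120, 130, "-"), Exon("c", 100, 110, "-")]
    assert transcript_to_genomic(0, rev) == 129
    assert transcript_to_genomic(10, rev) == 109
    with pytest.raises(ValueError):
        transcript_to_genomic(20, ex)


def test_genomic_footprint_splits_at_junctions():
    ex = plus_exons([(100, 110), (120, 130)])
    assert genomic_footprint(5, 15, ex) == [(105, 110), (120, 125)]


def test_junctions_after_stop_counts():
    # 5 exons of 30 nt; stop codon's last base in exon 2 -> 3 junctions after
    ex = plus_exons([(i * 100, i * 100 + 30) for i in range(5)])
    orf = make_cand(start=0, length=45)
    stop_g, after = locate_stop_and_junctions(orf, ex)
    assert after == 3
    assert stop_g == 100 + 14  # 45th base, exon 2 offset 14
    # mono-exonic: zero junctions after stop
    orf2 = make_cand(start=0, length=45)
    assert locate_stop_and_junctions(orf2, plus_exons([(0, 90)]))[1] == 0
    # stop in last exon: zero
    orf3 = make_cand(start=0, length=150)
    assert locate_stop_and_junctions(orf3, ex)[1] == 0
    # stop-less ORF: undefined
    orf4 = make_cand(length=60, stop=False)
    assert locate_stop_and_junctions(orf4, ex) == (None, None)


def test_true_orf_recovered_with_and_without_decoy_augs():
    rng = random.Random(5)
    codons = [a + b + c for a in "ACG" for b in "ACG" for c in "ACG"]
    clean_codons = [c for c in codons if c != "ATG"]
    recovered = with_decoy = total = 0
    for i in range(100):
        cds = "ATG" + "".join(rng.choice(clean_codons) for _ in range(60)) + "TAA"
        utr5 = "".join(rng.choice(clean_codons) for _ in range(4))
        seq = utr5 + cds + "CCACCA"
        true_start = len(utr5)
        cands = enumerate_candidate_orfs("t", seq)
        score_candidates(cands, seq)
        mark_reference_starts(
            cands, plus_exons([(0, len(seq))]), annotated_starts={true_start}
        )
        if select_best_orf(cands).orf.start_nt == true_start:
            recovered += 1
        # plant an upstream decoy AUG out of frame with the true start
        decoy_seq = "CATGCC" + seq
        cands = enumerate_candidate_orfs("t", decoy_seq)
        score_candidates(cands, decoy_seq)
        mark_reference_starts(
            cands, plus_exons([(0, len(decoy_seq))]), annotated_starts={true_start + 6}
        )
        if select_best_orf(cands).orf.start_nt == true_start + 6:
            with_decoy += 1
        total += 1
    assert recovered == total  # 100% with no decoys
    assert with_decoy >= 0.95 * total
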