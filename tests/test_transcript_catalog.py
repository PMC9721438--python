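"""CPM, FSM/NIC/NNC classification, and gene-level expression summaries."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_catalog, ref_transcript
from lrproteo import datasets
from lrproteo.reference_model import Exon
from lrproteo.transcript_catalog import (
    FSM,
    NIC,
    NNC,
    OTHER,
    LongReadTranscript,
    classify_transcript,
    coexpressed_isoform_genes,
    compute_cpm,
    filter_min_abundance,
    length_deltas_vs_reference,
    major_principal_concordance,
    rank_gene_set_by_abundance,
    round_percent,
    summarize_all_genes,
    summarize_gene_expression,
)
from oracles import brute_force_transcript_class


def lrt(acc, exon_coords, gene="GA", strand="+", chrom="chrT", cpm=0.0, fl=0):
    exons = [Exon(chrom, s, e, strand) for s, e in exon_coords]
    if strand == "-":
        exons = exons[::-1]
    return LongReadTranscript(
        pb_accession=acc, exons=exons, gene_id=gene, cpm=cpm, fl_count=fl
    )


# ---------------------------------------------------------------------------
# CPM


def test_cpm_single_transcript_takes_the_whole_library():
    assert compute_cpm({"t": 7}) == {"t": pytest.approx(1_000_000)}


def test_cpm_hand_arithmetic():
    cpm = compute_cpm({"t1": 3, "t2": 1})
    assert cpm["t1"] == pytest.approx(750_000)
    assert cpm["t2"] == pytest.approx(250_000)


def test_min_count_reaching_one_cpm_at_study_library_size():
    total = datasets.HUVEC_COUNTS["total_long_reads"]
    need = math.ceil(total / 1e6)
    assert need == 4
    cpm = compute_cpm({"t": need, "rest": total - need})
    assert cpm["t"] >= 1.0
    cpm = compute_cpm({"t": need - 1, "rest": total - need + 1})
    assert cpm["t"] < 1.0


def test_cpm_empty_dataset_errors():
    with pytest.raises(ValueError, match="empty dataset"):
        compute_cpm({"t": 0})


@given(st.dictionaries(st.text("ab", min_size=1, max_size=4),
                       st.integers(0, 10_000), min_size=1).filter(
                           lambda d: sum(d.values()) > 0))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_cpm_conserves_the_million_and_preserves_order(counts):
    cpm = compute_cpm(counts)
    assert sum(cpm.values()) == pytest.approx(1e6, rel=1e-9)
    items = sorted(counts)
    for a, b in zip(items, items[1:]):
        assert (counts[a] <= counts[b]) == (cpm[a] <= cpm[b])


@pytest.mark.parametrize("cpm,kept", [(1.0, True), (0.9, False), (1.5, True)])
def test_min_abundance_boundary_inclusive(cpm, kept):
    t = lrt("PB.1.1", [(0, 100)], cpm=cpm)
    assert (t in filter_min_abundance([t])) is kept


def test_min_abundance_counts_and_monotonicity():
    rng = random.Random(7)
    ts = [lrt(f"PB.1.{i}", [(0, 100)], cpm=rng.uniform(0, 2)) for i in range(100)]
    kept = filter_min_abundance(ts)
    assert len(kept) == sum(1 for t in ts if t.cpm >= 1.0)
    stricter = {t.pb_accession for t in filter_min_abundance(ts, 1.5)}
    assert stricter <= {t.pb_accession for t in kept}


# ---------------------------------------------------------------------------
# Classification


def test_fsm_by_junction_chain_identity(toy_catalog):
    q = lrt("PB.1.1", [(100, 200), (300, 400), (500, 600), (700, 800)])
    c = classify_transcript(q, toy_catalog)
    assert c.category == FSM and c.matched_reference_transcript == "GA-201"


def test_nic_known_sites_novel_chain():
    # reference: T1 with junctions J1,J2,J3 and T2 with J1,J4
    t1 = ref_transcript("T1", "G", [(0, 10), (20, 30), (40, 50), (60, 70)])
    t2 = ref_transcript("T2", "G", [(0, 10), (20, 35), (60, 70)])
    cat = make_catalog([t1, t2])
    # query chain (J1, J2): every site annotated, ordered chain unseen
    q = lrt("PB.1.1", [(0, 10), (20, 30), (40, 70)], gene="G")
    c = classify_transcript(q, cat)
    assert c.category == NIC and not c.novel_sites


def test_nnc_on_shifted_acceptor(toy_catalog):
    # acceptor of the second intron shifted 27 nt into the exon
    q = lrt("PB.1.1", [(100, 200), (300, 400), (527, 600), (700, 800)])
    c = classify_transcript(q, toy_catalog)
    assert c.category == NNC
    assert ("acceptor", 527) in c.novel_sites


def test_intergenic_and_mono_exonic_handling(toy_catalog):
    q = lrt("PB.9.1", [(9000, 9400)], gene=None)
    assert classify_transcript(q, toy_catalog).category == OTHER
    # mono-exonic contained in no mono-exonic reference -> OTHER
    q2 = lrt("PB.1.1", [(120, 180)])
    assert classify_transcript(q2, toy_catalog).category == OTHER


def test_classification_matches_brute_force_oracle_on_random_transcripts():
    rng = random.Random(42)
    # a reference locus with several chains over a shared site pool
    refs = []
    for i in range(4):
        bounds = sorted(rng.sample(range(0, 2000, 10), 8))
        exons = [(bounds[j], bounds[j + 1]) for j in range(0, 8, 2)]
        refs.append(ref_transcript(f"R{i}", "G", exons))
    cat = make_catalog(refs)
    ref_chains = [
        (tuple((j.donor, j.acceptor) for j in r.junctions), "chrT", "+") for r in refs
    ]
    donors = sorted({j.donor for r in refs for j in r.junctions})
    acceptors = sorted({j.acceptor for r in refs for j in r.junctions})
    agree = 0
    for i in range(3000):
        n_j = rng.randint(1, 4)
        ds = sorted(rng.sample(donors + [d + rng.choice([-3, 5]) for d in donors], n_j))
        js = []
        prev = -1
        ok = True
        for d in ds:
            a_pool = [a for a in acceptors if a > d + 1] or [d + 7]
            a = rng.choice(a_pool + [a_pool[0] + rng.choice([-2, 4])])
            if d <= prev or a <= d:
                ok = False
                break
            js.append((d, a))
            prev = a
        if not ok:
            continue
        exons = [(0 if k == 0 else js[k - 1][1], js[k][0]) for k in range(len(js))]
        exons.append((js[-1][1], js[-1][1] + 50))
        if any(s >= e for s, e in exons):
            continue
        q = lrt(f"PB.1.{i}", exons, gene="G")
        got = classify_transcript(q, cat).category
        want = brute_force_transcript_class(
            [(j.donor, j.acceptor) for j in q.junctions], "chrT", "+", ref_chains
        )
        assert got == want, (exons, got, want)
        agree += 1
    assert agree >= 1000  # enough randomized instances actually exercised


def test_every_multiexonic_transcript_gets_exactly_one_category(smoke_run):
    _, result = smoke_run
    cats = {c.category for c in result.transcript_classes.values()}
    assert cats <= {FSM, NIC, NNC, OTHER}
    assert len(result.transcript_classes) == len(result.transcripts)


# ---------------------------------------------------------------------------
# Gene summaries


def table1_gene(gene):
    rows = [r for r in datasets.HUVEC_TABLE1 if r[0] == gene]
    return [
        lrt(acc, [(0, 100)], gene=gene, cpm=cpm, fl=int(cpm * 10))
        for _, acc, _, cpm in rows
    ]


def test_cdh5_major_isoform_from_table1(toy_catalog):
    s = summarize_gene_expression(table1_gene("CDH5"), toy_catalog, {})
    assert s.major_isoform == "PB.10443.2"
    assert s.isoforms[0].cpm == pytest.approx(2402.9)
    assert len(s.minor_isoforms) == len(s.isoforms) - 1


def test_single_isoform_gene_is_its_own_major(toy_catalog):
    s = summarize_gene_expression([lrt("PB.1.1", [(0, 100)], cpm=5.0)], toy_catalog, {})
    assert s.major_isoform == "PB.1.1" and s.minor_isoforms == []


def test_equal_cpm_tie_breaks_to_lower_accession_suffix(toy_catalog):
    a = lrt("PB.1.12", [(0, 100)], cpm=5.0, fl=10)
    b = lrt("PB.1.3", [(0, 100)], cpm=5.0, fl=10)
    s = summarize_gene_expression([a, b], toy_catalog, {})
    assert s.major_isoform == "PB.1.3"


def test_major_principal_concordance_fractions(toy_catalog):
    def summary(gene, matches, n_iso=2):
        ts = [lrt(f"PB.1.{i}", [(0, 100)], gene=gene, cpm=10 - i) for i in range(n_iso)]
        s = summarize_gene_expression(ts, toy_catalog, {})
        s.major_matches_principal = matches
        return s

    all_match = {f"G{i}": summary(f"G{i}", True) for i in range(4)}
    assert major_principal_concordance(all_match) == (0, 0.0)
    one_off = dict(all_match)
    one_off["G0"] = summary("G0", False)
    assert major_principal_concordance(one_off) == (1, 0.25)
    # single-isoform genes are excluded from the denominator
    one_off["G9"] = summary("G9", False, n_iso=1)
    assert major_principal_concordance(one_off) == (1, 0.25)


def test_coexpression_filter_boundaries(toy_catalog):
    def gene_summary(gene, cpms):
        ts = [lrt(f"PB.1.{i}", [(0, 100)], gene=gene, cpm=c) for i, c in enumerate(cpms)]
        return summarize_gene_expression(ts, toy_catalog, {})

    summaries = {
        "FLT1": gene_summary("FLT1", datasets.table1_cpms("FLT1")),
        "LOW": gene_summary("LOW", [10.0, 2.9]),
        "EDGE": gene_summary("EDGE", [3.0, 3.0]),
    }
    assert coexpressed_isoform_genes(summaries) == ["EDGE", "FLT1"]
    # raising the floor never grows the list
    assert set(coexpressed_isoform_genes(summaries, min_cpm=10)) <= {"EDGE", "FLT1"}


def test_rank_gene_set_by_abundance(toy_catalog):
    def gene_summary(gene, cpms):
        ts = [lrt(f"PB.1.{i}", [(0, 100)], gene=gene, cpm=c) for i, c in enumerate(cpms)]
        return summarize_gene_expression(ts, toy_catalog, {})

    summaries = {
        "A": gene_summary("A", [50.0]),
        "B": gene_summary("B", [100.0, 200.0]),
        "SRSF5": gene_summary("SRSF5", datasets.table1_cpms("SRSF5")),
    }
    ranked = rank_gene_set_by_abundance(summaries, ["A", "B", "C", "SRSF5"])
    assert ranked[0] == ("B", pytest.approx(300.0))
    assert dict(ranked)["SRSF5"] == pytest.approx(198.5)
    assert "C" not in dict(ranked)
    assert rank_gene_set_by_abundance(summaries, ["Z"]) == []


def test_length_deltas_vs_principal(toy_catalog):
    toy_catalog.transcripts["GA-201"].protein_sequence = "M" * 459
    res = length_deltas_vs_reference(
        {"PB.1.1": "M" * 300, "PB.1.2": "M" * 459, "PB.1.3": "M" * 470},
        {"PB.1.1": "GA", "PB.1.2": "GA", "PB.1.3": "GA"},
        toy_catalog,
    )
    assert res.deltas["PB.1.1"] == -159
    assert res.deltas["PB.1.2"] == 0
    assert res.median_shortening == 159
    assert res.mean_gain == pytest.approx(11.0)


@pytest.mark.parametrize(
    "num,den,expected", [(8174, 10000, 82), (5879, 10000, 59), (6193, 10000, 62),
                         (5738, 10000, 57), (0, 1, 0), (1, 200, 1)]
)
def test_round_percent_half_away_from_zero(num, den, expected):
    assert round_percent(num, den) == expected
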