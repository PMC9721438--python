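"""Peptide mapping, evidence scenarios, nominations, novel peptides."""

import random

import numpy as np
import pytest

from lrproteo.database_builder import (
    GENCODE,
    PACBIO,
    HybridDatabase,
    ProteinDatabaseEntry,
    format_pacbio_label,
)
from lrproteo.peptide_evidence import (
    MULTI_CONFIRMED,
    NOM_ADDITIONAL,
    NOM_AMBIGUOUS,
    NOM_NONE,
    ONE_CONFIRMED,
    SHARED_ONLY,
    SINGLE_ISOFORM_IN_DB,
    PeptideIdentification,
    PeptideIndex,
    classify_gene_scenarios,
    detect_novel_peptides,
    digest,
    digest_reference,
    filter_identifications,
    map_peptides,
    nominate_by_transcript_abundance,
    rna_protein_correlation,
)
from lrproteo.transcript_catalog import GeneExpressionSummary
from oracles import brute_force_digest, naive_peptide_scan


def pid(seq, q=0.001, psm=1):
    return PeptideIdentification(sequence=seq, q_value=q, psm_count=psm)


# ---------------------------------------------------------------------------
# q-value filtering


def test_default_tier_is_inclusive_at_one_percent():
    peps = [pid("A", 0.01), pid("B", 0.0100001), pid("C", 0.002)]
    kept = {p.sequence for p in filter_identifications(peps)}
    assert kept == {"A", "C"}


def test_strict_novel_tier_is_exclusive():
    peps = [pid("A", 0.001), pid("B", 0.0009)]
    kept = {p.sequence for p in filter_identifications(peps, 0.001, strict=True)}
    assert kept == {"B"}


def test_filter_counts():
    rng = random.Random(3)
    peps = [pid(f"P{i}", rng.uniform(0, 0.02)) for i in range(100)]
    kept = filter_identifications(peps)
    assert len(kept) == sum(1 for p in peps if p.q_value <= 0.01)


# ---------------------------------------------------------------------------
# digestion


def test_digest_rule_application():
    assert digest("AAKBBRPCC", min_len=1) >= {"AAK", "BBRPCC"}
    full = digest("AAKBBRPCC", missed_cleavages=0, min_len=1, max_len=50)
    assert full == {"AAK", "BBRPCC"}
    with_missed = digest("AAKBBRPCC", missed_cleavages=1, min_len=1)
    assert "AAKBBRPCC" in with_missed


def test_digest_matches_brute_force_enumeration():
    rng = random.Random(19)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(200):
        prot = "".join(rng.choice(aas) for _ in range(rng.randint(10, 200)))
        for mc in (0, 1, 2):
            assert digest(prot, missed_cleavages=mc) == brute_force_digest(
                prot, missed_cleavages=mc
            ), prot


def test_reference_digest_union_and_il_option():
    d = digest_reference(["MAAAAAAKIIIIIIIK"], il_equivalent=True)
    assert "LLLLLLLK" in d and "IIIIIIIK" not in d


# ---------------------------------------------------------------------------
# mapping


def entry(label, gene, seq, source=PACBIO, cpm=None):
    return ProteinDatabaseEntry(
        label=label, gene=gene, sequence=seq, source=source, cpm_sum=cpm,
        representative=label.split("|")[1] if "|" in label else None,
    )


def mini_db():
    # gene GA: two isoforms sharing a core, one with a distinctive region
    core = "MAAAAAAK"
    e1 = entry("GA|PB.1.1|pFSM|50.0", "GA", core + "CCCDDDEEEK" + "FFFGGGHHHK", cpm=50.0)
    e2 = entry("GA|PB.1.2|pNNC|30.0", "GA", core + "CCCDDDEEEK" + "WWWYYYVVVK", cpm=30.0)
    # gene GB: single entry
    e3 = entry("GB|PB.2.1|pNIC|10.0", "GB", "MSSSSSSKRTTTTTTK", cpm=10.0)
    # reference-sourced gene GC
    e4 = entry("GC-P201", "GC", "MNNNNNNKQQQQQQQK", source=GENCODE)
    return HybridDatabase(
        entries=[e1, e2, e3, e4],
        gene_source_map={"GA": PACBIO, "GB": PACBIO, "GC": GENCODE},
        thresholds={},
    )


def test_mapping_uniqueness_and_unmapped():
    db = mini_db()
    peps = [pid("FFFGGGHHHK"), pid("CCCDDDEEEK"), pid("NOTTHEREAK")]
    maps, unmapped = map_peptides(peps, db)
    by_seq = {m.peptide.sequence: m for m in maps}
    assert by_seq["FFFGGGHHHK"].is_unique_isoform
    assert not by_seq["CCCDDDEEEK"].is_unique_isoform
    assert by_seq["CCCDDDEEEK"].hit_genes == {"GA"}
    assert [p.sequence for p in unmapped] == ["NOTTHEREAK"]


def test_mapping_agrees_with_naive_digest_legal_scan():
    db = mini_db()
    pool = sorted(
        set().union(*(digest(e.sequence, min_len=4) for e in db.entries))
    ) + ["MAAAAAA", "AAAK"]
    index = PeptideIndex(db.entries, min_len=4)
    pairs = [(e.label, e.sequence) for e in db.entries]
    for pep in pool:
        got = index.lookup(pep)
        want = {
            lab
            for lab in naive_peptide_scan(pep, pairs)
            if 4 <= len(pep) <= 50
        }
        assert got == want, pep


def test_scenario_partition_and_labels():
    db = mini_db()
    peps = [
        pid("FFFGGGHHHK"),  # unique to GA entry 1
        pid("WWWYYYVVVK"),  # unique to GA entry 2
        pid("MSSSSSSK"),  # GB: single entry in DB
        pid("QQQQQQQK"),  # GC single reference entry
    ]
    maps, _ = map_peptides(peps, db)
    ev = classify_gene_scenarios(maps, db)
    assert ev["GA"].scenario == MULTI_CONFIRMED
    assert ev["GB"].scenario == SINGLE_ISOFORM_IN_DB
    assert ev["GC"].scenario == SINGLE_ISOFORM_IN_DB
    assert len(ev) == 3  # scenario counts partition the evidenced genes


def test_shared_only_and_one_confirmed():
    db = mini_db()
    maps, _ = map_peptides([pid("CCCDDDEEEK")], db)
    ev = classify_gene_scenarios(maps, db)
    assert ev["GA"].scenario == SHARED_ONLY
    maps2, _ = map_peptides([pid("CCCDDDEEEK"), pid("FFFGGGHHHK")], db)
    ev2 = classify_gene_scenarios(maps2, db)
    assert ev2["GA"].scenario == ONE_CONFIRMED
    assert ev2["GA"].confirmed_entries == ["GA|PB.1.1|pFSM|50.0"]


def test_nomination_rules_and_boundary():
    db = mini_db()
    # SHARED_ONLY: both GA entries >= 25 CPM -> co-expression nomination
    maps, _ = map_peptides([pid("CCCDDDEEEK")], db)
    ev = classify_gene_scenarios(maps, db)
    nominate_by_transcript_abundance(ev, db)
    assert ev["GA"].nomination == NOM_AMBIGUOUS
    assert len(ev["GA"].nominated_entries) == 2
    assert ev["GA"].coexpression_nominated
    # ONE_CONFIRMED: the unconfirmed 30-CPM entry is nominated additionally
    maps2, _ = map_peptides([pid("CCCDDDEEEK"), pid("FFFGGGHHHK")], db)
    ev2 = classify_gene_scenarios(maps2, db)
    nominate_by_transcript_abundance(ev2, db)
    assert ev2["GA"].nomination == NOM_ADDITIONAL
    assert ev2["GA"].nominated_entries == ["GA|PB.1.2|pNNC|30.0"]
    # boundary: 24.9 CPM is not nominated; raising cpm_min never adds entries
    db.entries[1].cpm_sum = 24.9
    ev3 = classify_gene_scenarios(maps, db)
    nominate_by_transcript_abundance(ev3, db)
    assert "GA|PB.1.2|pNNC|30.0" not in ev3["GA"].nominated_entries
    ev4 = classify_gene_scenarios(maps, db)
    nominate_by_transcript_abundance(ev4, db, cpm_min=100.0)
    assert set(ev4["GA"].nominated_entries) <= set(ev3["GA"].nominated_entries)
    db.entries[1].cpm_sum = 30.0
    # reference-sourced genes are never nominated
    maps5, _ = map_peptides([pid("MNNNNNNK"), pid("QQQQQQQK")], db)
    ev5 = classify_gene_scenarios(maps5, db)
    nominate_by_transcript_abundance(ev5, db)
    assert ev5["GC"].nomination == NOM_NONE


# ---------------------------------------------------------------------------
# novel peptides


def test_novel_peptide_requires_absence_from_all_reference_digests():
    db = mini_db()
    ref_digest = digest_reference(["MAAAAAAKCCCDDDEEEKFFFGGGHHHK"])
    peps = [pid("WWWYYYVVVK", q=0.0005), pid("FFFGGGHHHK", q=0.0005),
            pid("CCCDDDEEEK", q=0.005)]
    maps, _ = map_peptides(peps, db)
    novel = detect_novel_peptides(peps, maps, [ref_digest], db)
    assert [n.sequence for n in novel] == ["WWWYYYVVVK"]
    # strict tier: q = 0.005 candidates are excluded even if absent
    assert all(n.q_value < 0.001 for n in novel)


def test_novelty_soundness_reference_database_yields_no_novel_peptides():
    db = mini_db()
    for e in db.entries:
        e.source = GENCODE  # pretend the whole database is the reference
    refs = digest_reference([e.sequence for e in db.entries])
    peps = [pid("WWWYYYVVVK", q=0.0005)]
    maps, _ = map_peptides(peps, db)
    assert detect_novel_peptides(peps, maps, [refs], db) == []


# ---------------------------------------------------------------------------
# RNA-protein correlation


def summaries_with_cpm(cpms):
    out = {}
    for gene, c in cpms.items():
        out[gene] = GeneExpressionSummary(
            gene_id=gene, isoforms=[], major_isoform="", minor_isoforms=[],
            principal_transcript=None, major_matches_principal=False,
            total_gene_cpm=c,
        )
    return out


class FakeMapping:
    def __init__(self, gene, psm):
        self.peptide = pid("X", psm=psm)
        self.hit_genes = {gene}
        self.is_multi_gene = False


def test_exact_loglinear_relation_gives_r2_one():
    # cpm = 10^(2i) - 1 and psm = 10^i - 1 sit exactly on a slope-1/2 line
    # in log10(x + 1) space
    cpms = {f"G{i}": 10.0 ** (2 * i) - 1 for i in range(5)}
    maps = [FakeMapping(f"G{i}", 10**i - 1) for i in range(5)]
    res = rna_protein_correlation(summaries_with_cpm(cpms), maps)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    assert res.slope == pytest.approx(0.5, abs=1e-12)


def test_constant_psm_gives_r2_zero():
    cpms = {f"G{i}": float(i + 1) for i in range(5)}
    maps = [FakeMapping(g, 7) for g in cpms]
    res = rna_protein_correlation(summaries_with_cpm(cpms), maps)
    assert res.r_squared == 0.0


def test_insufficient_pairs_raises():
    cpms = {"G0": 1.0, "G1": 2.0}
    with pytest.raises(ValueError, match="insufficient"):
        rna_protein_correlation(
            summaries_with_cpm(cpms), [FakeMapping("G0", 1), FakeMapping("G1", 2)]
        )


def test_planted_slope_recovered_on_synthetic_pairs():
    from scipy.stats import linregress

    from lrproteo.synthetic_data import simulate_rna_protein_pairs

    cpm, psm = simulate_rna_protein_pairs(2000, slope=0.8, noise_sd=0.25, seed=7)
    fit = linregress(np.log10(cpm + 1), np.log10(psm + 1))
    assert abs(fit.slope - 0.8) < 2 * fit.stderr
    # analytic R^2 of the generating model: var(bx)/(var(bx)+sd^2) with
    # x ~ U(0,3) shifted through log10(cpm+1); approximate x variance 0.75
    expected_r2 = (0.8**2 * 0.72) / (0.8**2 * 0.72 + 0.25**2)
    assert fit.rvalue**2 == pytest.approx(expected_r2, abs=0.05)
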