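"""End-to-end pipeline orchestration and run reporting.

Runs the stages in order — reference loading, long-read ingestion and
classification, ORF calling, protein classification, hybrid database
construction, peptide evidence — from one set of input paths and one
:class:`Thresholds`, writes every intermediate table, and assembles a
:class:`RunReport` of the bookkeeping counts (transcript classes, gene
multiplicities, database composition, evidence scenarios, nominations,
novel-peptide events) with nearest-integer percentages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

from . import (
    database_builder as dbb,
    orf_calling as orf,
    peptide_evidence as pev,
    protein_classification as pcl,
    reference_model as ref,
    transcript_catalog as tca,
)
from .transcript_catalog import round_percent

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every numeric threshold of the analysis, with its study default."""

    min_transcript_cpm: float = 1.0
    coexpression_min_cpm: float = 3.0
    hybrid_min_gene_cpm: float = 3.0
    hybrid_length_window_nt: tuple[int, int] = (1000, 4000)
    nomination_min_cpm: float = 25.0
    min_orf_nt: int = 50
    nmd_max_junctions_after_stop: int = 2
    peptide_q_max: float = 0.01
    novel_peptide_q_strict: float = 0.001
    missed_cleavages: int = 2


@dataclass
class RunReport:
    transcript_classes: dict[str, int] = field(default_factory=dict)
    transcripts_retained: int = 0
    genes_detected: int = 0
    multi_isoform_genes: int = 0
    single_isoform_genes: int = 0
    major_not_principal: int = 0
    major_not_principal_fraction: float = 0.0
    removal_ledger: dict[str, int] = field(default_factory=dict)
    db_entries_by_source: dict[str, int] = field(default_factory=dict)
    db_genes_by_source: dict[str, int] = field(default_factory=dict)
    scenario_counts: dict[str, int] = field(default_factory=dict)
    nomination_counts: dict[str, int] = field(default_factory=dict)
    novel_peptides_total: int = 0
    novel_peptides_by_event: dict[str, int] = field(default_factory=dict)
    rna_protein_r2: float | None = None
    rna_protein_slope: float | None = None
    rna_protein_slope_stderr: float | None = None
    rna_protein_n: int = 0
    percentages: dict[str, int] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    catalog: ref.ReferenceCatalog
    transcripts: list[tca.LongReadTranscript]
    transcript_classes: dict[str, tca.TranscriptClass]
    summaries: dict[str, tca.GeneExpressionSummary]
    best_orfs: dict[str, orf.BestORF]
    protein_classes: dict[str, pcl.ProteinClass]
    retained: list[str]
    removal_ledger: dict[str, str]
    db: dbb.HybridDatabase
    mappings: list[pev.PeptideMapping]
    evidence: dict[str, pev.GeneEvidence]
    novel_peptides: list[pev.NovelPeptide]
    correlation: pev.CorrelationResult | None
    report: RunReport


def run_pipeline(
    reference_gtf,
    genome_fasta,
    longread_gtf,
    counts_tsv,
    peptides_tsv,
    appris_tsv=None,
    contaminants_fasta=None,
    second_reference_fasta=None,
    thresholds: Thresholds | None = None,
    outdir=None,
) -> PipelineResult:
    """Execute all stages in order; write stage outputs under ``outdir``."""
    th = thresholds or Thresholds()

    catalog = ref.load_annotation(reference_gtf, genome_fasta, appris_tsv)
    reference_proteins = ref.group_reference_proteins(catalog)

    transcripts = tca.load_long_read_models(longread_gtf, counts_tsv, catalog)
    retained_tx = tca.filter_min_abundance(transcripts, th.min_transcript_cpm)
    classes = {t.pb_accession: tca.classify_transcript(t, catalog) for t in retained_tx}
    summaries = tca.summarize_all_genes(retained_tx, catalog, classes)

    best_orfs = orf.call_best_orfs(retained_tx, catalog, th.min_orf_nt)
    protein_classes = pcl.classify_all_proteins(
        best_orfs, retained_tx, classes, catalog
    )
    retained, ledger = dbb.filter_protein_isoforms(
        best_orfs, protein_classes, th.nmd_max_junctions_after_stop
    )
    tx_by_acc = {t.pb_accession: t for t in retained_tx}
    grouped = dbb.group_orfs_by_sequence(retained, best_orfs, protein_classes, tx_by_acc)
    hiconf = dbb.select_high_confidence_genes(
        summaries, catalog, th.hybrid_min_gene_cpm, th.hybrid_length_window_nt
    )
    contaminants = (
        dbb.read_protein_fasta(contaminants_fasta) if contaminants_fasta else []
    )
    db = dbb.build_hybrid_database(
        grouped,
        reference_proteins,
        contaminants,
        hiconf,
        catalog,
        thresholds=dataclasses.asdict(th),
    )

    peptides = pev.load_peptide_table(peptides_tsv)
    filtered = pev.filter_identifications(peptides, th.peptide_q_max)
    index = pev.PeptideIndex(db.entries, th.missed_cleavages)
    mappings, unmapped = pev.map_peptides(filtered, db, index)
    evidence = pev.classify_gene_scenarios(mappings, db)
    pev.nominate_by_transcript_abundance(evidence, db, th.nomination_min_cpm)

    ref_digest = pev.digest_reference(
        [r.sequence for r in reference_proteins], th.missed_cleavages
    )
    digests = [ref_digest]
    if second_reference_fasta:
        digests.append(
            pev.digest_reference(
                [s for _, s in dbb.read_protein_fasta(second_reference_fasta)],
                th.missed_cleavages,
            )
        )
    novel = pev.detect_novel_peptides(
        filtered, mappings, digests, db, th.novel_peptide_q_strict
    )
    pev.annotate_all_novel_events(novel, db, tx_by_acc, best_orfs, catalog)

    correlation = None
    try:
        correlation = pev.rna_protein_correlation(summaries, mappings)
    except ValueError:
        log.warning("RNA-protein correlation skipped: insufficient pairs")

    report = build_report(
        th, retained_tx, classes, summaries, ledger, db, evidence, novel, correlation
    )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        j = lambda name: os.path.join(str(outdir), name)
        tca.write_classification_tsv(retained_tx, classes, j("transcript_classes.tsv"))
        tca.write_bed12(retained_tx, j("transcripts.bed12"))
        orf.write_orf_table(best_orfs, j("orfs.tsv"))
        pcl.write_protein_classification_tsv(
            protein_classes,
            {a: tx_by_acc[a].gene_id for a in protein_classes},
            j("protein_classes.tsv"),
        )
        dbb.write_removal_ledger(ledger, j("removal_ledger.tsv"))
        dbb.write_protein_fasta(db, j("hybrid_database.fa"))
        dbb.write_gene_source_map(db, j("gene_source_map.tsv"))
        pev.write_gene_evidence_tsv(evidence, j("gene_evidence.tsv"))
        pev.write_novel_peptides_tsv(novel, j("novel_peptides.tsv"))
        render_report(report, j("report"))

    return PipelineResult(
        catalog=catalog,
        transcripts=retained_tx,
        transcript_classes=classes,
        summaries=summaries,
        best_orfs=best_orfs,
        protein_classes=protein_classes,
        retained=retained,
        removal_ledger=ledger,
        db=db,
        mappings=mappings,
        evidence=evidence,
        novel_peptides=novel,
        correlation=correlation,
        report=report,
    )


def build_report(
    th, transcripts, classes, summaries, ledger, db, evidence, novel, correlation
) -> RunReport:
    r = RunReport(thresholds=dataclasses.asdict(th))
    for c in classes.values():
        r.transcript_classes[c.category] = r.transcript_classes.get(c.category, 0) + 1
    r.transcripts_retained = len(transcripts)
    r.genes_detected = len(summaries)
    r.multi_isoform_genes = sum(1 for s in summaries.values() if len(s.isoforms) >= 2)
    r.single_isoform_genes = r.genes_detected - r.multi_isoform_genes
    mism, frac = tca.major_principal_concordance(summaries)
    r.major_not_principal = mism
    r.major_not_principal_fraction = frac
    for reason in ledger.values():
        r.removal_ledger[reason] = r.removal_ledger.get(reason, 0) + 1
    for e in db.entries:
        r.db_entries_by_source[e.source] = r.db_entries_by_source.get(e.source, 0) + 1
    for src in db.gene_source_map.values():
        r.db_genes_by_source[src] = r.db_genes_by_source.get(src, 0) + 1
    for ev in evidence.values():
        r.scenario_counts[ev.scenario] = r.scenario_counts.get(ev.scenario, 0) + 1
        r.nomination_counts[ev.nomination] = r.nomination_counts.get(ev.nomination, 0) + 1
    r.novel_peptides_total = len(novel)
    for np_ in novel:
        r.novel_peptides_by_event[np_.event] = (
            r.novel_peptides_by_event.get(np_.event, 0) + 1
        )
    if correlation is not None:
        r.rna_protein_r2 = correlation.r_squared
        r.rna_protein_slope = correlation.slope
        r.rna_protein_slope_stderr = correlation.stderr
        r.rna_protein_n = correlation.n
    if r.multi_isoform_genes:
        r.percentages["major_not_principal"] = round_percent(
            r.major_not_principal, r.multi_isoform_genes
        )
    if r.genes_detected:
        r.percentages["multi_isoform_genes"] = round_percent(
            r.multi_isoform_genes, r.genes_detected
        )
    total_tx = sum(r.transcript_classes.values())
    if total_tx:
        for cat, n in sorted(r.transcript_classes.items()):
            r.percentages[f"transcripts_{cat}"] = round_percent(n, total_tx)
    return r


def render_report(report: RunReport, path_prefix) -> None:
    """Write the report as JSON (machine) and a plain-text summary (human)."""
    data = dataclasses.asdict(report)
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
    with open(f"{path_prefix}.txt", "w") as fh:
        fh.write("Long-read proteogenomics run report\n")
        fh.write("===================================\n\n")
        fh.write(f"Transcripts retained (>= min CPM): {report.transcripts_retained}\n")
        for cat in ("FSM", "NIC", "NNC", "OTHER"):
            if cat in report.transcript_classes:
                pct = report.percentages.get(f"transcripts_{cat}")
                fh.write(
                    f"  {cat}: {report.transcript_classes[cat]}"
                    + (f" ({pct}%)\n" if pct is not None else "\n")
                )
        fh.write(
            f"Genes detected: {report.genes_detected} "
            f"(multi-isoform {report.multi_isoform_genes}, "
            f"{report.percentages.get('multi_isoform_genes', 0)}%)\n"
        )
        fh.write(
            f"Major isoform != APPRIS principal: {report.major_not_principal} "
            f"({report.percentages.get('major_not_principal', 0)}% of "
            f"multi-isoform genes)\n"
        )
        fh.write(f"Removal ledger: {report.removal_ledger}\n")
        fh.write(
            f"Database genes by source: {report.db_genes_by_source}; "
            f"entries by source: {report.db_entries_by_source}\n"
        )
        fh.write(f"Evidence scenarios: {report.scenario_counts}\n")
        fh.write(f"Nominations: {report.nomination_counts}\n")
        fh.write(
            f"Novel peptides: {report.novel_peptides_total} "
            f"by event {report.novel_peptides_by_event}\n"
        )
        if report.rna_protein_r2 is not None:
            fh.write(
                f"RNA-protein correlation: R^2 = {report.rna_protein_r2:.3f} "
                f"(slope {report.rna_protein_slope:.3f} +/- "
                f"{report.rna_protein_slope_stderr:.3f}, n = {report.rna_protein_n})\n"
            )
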