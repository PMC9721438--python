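"""Published summary numbers from the HUVEC long-read proteogenomics study.

These are the dataset-level component counts reported for the human
umbilical vein endothelial cell (HUVEC) Iso-Seq + MS experiment (raw data:
SRA PRJNA832812, MassIVE MSV000089326).  The raw sequencing and spectral
data are far beyond desk scale, but the bookkeeping arithmetic that ties
the component counts together — category shares, scenario partitions,
database composition totals — is reproducible from the counts alone and is
exercised by :func:`huvec_bookkeeping`.

``HUVEC_TABLE1`` carries the per-transcript CPM table of endothelial genes
co-expressing multiple isoforms, used in examples and tests of the
gene-summary operations.
"""

from __future__ import annotations

from .transcript_catalog import round_percent

# Dataset-level counts -------------------------------------------------------

HUVEC_COUNTS = {
    "total_long_reads": 3_608_972,
    "transcripts_total": 53_863,
    "genes_detected": 10_426,
    "transcripts_fsm": 31_668,
    "transcripts_novel": 22_195,
    "transcripts_nic": 13_746,
    "transcripts_nnc": 8_449,
    "multi_isoform_genes": 8_522,
    "single_isoform_genes": 1_904,
    "major_not_principal_genes": 2_143,
    "splice_factors_detected": 85,
    "median_shortening_aa": 159,
    "mean_gain_aa": 11,
    # hybrid database composition
    "db_gencode_genes": 12_699,
    "db_gencode_entries": 44_836,
    "db_pacbio_genes": 7_283,
    "db_pacbio_entries": 26_675,
    "db_contaminant_entries": 264,
    "db_total_genes": 19_982,
    "db_total_entries": 71_511,
    # peptide evidence scenarios
    "evidenced_genes": 10_444,
    "shared_only_genes": 5_993,
    "unique_evidence_genes": 4_451,
    "single_isoform_db_genes": 1_748,
    "multi_isoform_db_unique_genes": 2_703,
    "one_confirmed_genes": 2_597,
    "shared_only_with_pacbio": 3_436,
    "nominated_ambiguous_genes": 2_280,
    "coexpression_nominated_genes": 247,
    "nominated_additional_genes": 180,
    "unique_supported_isoform_genes": 2_597,
    # novel peptides
    "novel_peptides_fdr1": 108,
    "novel_peptides_strict": 39,
    "rna_protein_r2": 0.66,
}

# Table 1: endothelial genes co-expressing multiple isoforms (gene,
# PB accession, matched reference isoform or None, CPM).
HUVEC_TABLE1 = [
    ("CD34", "PB.1222.12", "CD34-201", 13.9),
    ("CD34", "PB.1222.24", None, 9.8),
    ("CD34", "PB.1222.26", "CD34-202", 226.7),
    ("CD34", "PB.1222.27", "CD34-201", 344.7),
    ("CD34", "PB.1222.29", None, 12.8),
    ("CD34", "PB.1222.31", "CD34-203", 27.8),
    ("CELF1", "PB.7605.14", None, 9.4),
    ("CELF1", "PB.7605.21", None, 4.5),
    ("CELF1", "PB.7605.23", None, 6.8),
    ("CELF1", "PB.7605.28", None, 58.3),
    ("CELF1", "PB.7605.29", "CELF1-201", 13.2),
    ("CELF1", "PB.7605.56", None, 5.3),
    ("CELF1", "PB.7605.70", None, 27.1),
    ("CELF1", "PB.7605.76", None, 47.0),
    ("CELF1", "PB.7605.81", None, 10.1),
    ("CDH5", "PB.10443.1", "CDH5-209", 216.5),
    ("CDH5", "PB.10443.11", "CDH5-201", 3.0),
    ("CDH5", "PB.10443.15", None, 321.8),
    ("CDH5", "PB.10443.18", None, 3.0),
    ("CDH5", "PB.10443.2", "CDH5-201", 2402.9),
    ("CDH5", "PB.10443.22", "CDH5-201", 44.0),
    ("CDH5", "PB.10443.26", None, 9.0),
    ("CDH5", "PB.10443.28", "CDH5-201", 13.5),
    ("CDH5", "PB.10443.33", None, 4.5),
    ("CDH5", "PB.10443.36", "CDH5-201", 20.7),
    ("CDH5", "PB.10443.38", "CDH5-201", 28.2),
    ("CDH5", "PB.10443.40", "CDH5-208", 5.6),
    ("CDH5", "PB.10443.45", None, 27.1),
    ("CDH5", "PB.10443.49", None, 9.8),
    ("CDH5", "PB.10443.50", "CDH5-209", 6.4),
    ("CDH5", "PB.10443.52", "CDH5-201", 10.5),
    ("CDH5", "PB.10443.57", None, 3.0),
    ("FLT1", "PB.8882.15", "FLT1-204", 42.9),
    ("FLT1", "PB.8882.22", "FLT1-207", 23.7),
    ("FLT1", "PB.8882.27", "FLT1-207", 9.4),
    ("FLT1", "PB.8882.30", "FLT1-207", 29.7),
    ("FLT1", "PB.8882.9", "FLT1-201", 6.4),
    ("NRP1", "PB.6952.10", None, 32.0),
    ("NRP1", "PB.6952.12", None, 3.8),
    ("NRP1", "PB.6952.35", None, 4.1),
    ("NRP1", "PB.6952.54", None, 3.4),
    ("NRP1", "PB.6952.58", None, 5.6),
    ("PECAM1", "PB.11293.22", None, 29.3),
    ("PECAM1", "PB.11293.23", None, 38.7),
    ("PECAM1", "PB.11293.54", None, 6.0),
    ("PECAM1", "PB.11293.55", None, 5.3),
    ("PECAM1", "PB.11293.64", "PECAM1-203", 524.8),
    ("PECAM1", "PB.11293.68", None, 32.7),
    ("PECAM1", "PB.11293.7", None, 6.4),
    ("PECAM1", "PB.11293.70", None, 12.8),
    ("PECAM1", "PB.11293.71", None, 4.5),
    ("PECAM1", "PB.11293.80", None, 5.6),
    ("PECAM1", "PB.11293.81", None, 29.3),
    ("PECAM1", "PB.11293.83", None, 3.4),
    ("PECAM1", "PB.11293.9", None, 5.3),
    ("PECAM1", "PB.11293.95", None, 3.8),
    ("PECAM1", "PB.11293.98", None, 3.4),
    ("SRSF5", "PB.9356.16", "SRSF5-201", 10.5),
    ("SRSF5", "PB.9356.17", "SRSF5-217", 103.8),
    ("SRSF5", "PB.9356.21", "SRSF5-217", 68.4),
    ("SRSF5", "PB.9356.4", "SRSF5-207", 15.8),
]


def table1_cpms(gene: str) -> list[float]:
    return [cpm for g, _, _, cpm in HUVEC_TABLE1 if g == gene]


def huvec_bookkeeping(counts: dict | None = None) -> dict[str, float]:
    """Recompute the study's bookkeeping identities from component counts.

    Every value here is derived arithmetic over the component counts —
    category shares and percentages (nearest-integer, half away from zero),
    partition sums, the minimum read count reaching 1 CPM at the dataset's
    library size, and database composition totals.
    """
    import math

    c = counts or HUVEC_COUNTS
    out = {
        "novel_transcripts": c["transcripts_nic"] + c["transcripts_nnc"],
        "transcripts_total_check": c["transcripts_fsm"]
        + c["transcripts_nic"]
        + c["transcripts_nnc"],
        "fsm_percent": round_percent(c["transcripts_fsm"], c["transcripts_total"]),
        "novel_percent": round_percent(c["transcripts_novel"], c["transcripts_total"]),
        "nic_percent_of_novel": round_percent(
            c["transcripts_nic"], c["transcripts_novel"]
        ),
        "nnc_percent_of_novel": round_percent(
            c["transcripts_nnc"], c["transcripts_novel"]
        ),
        "multi_isoform_gene_percent": round_percent(
            c["multi_isoform_genes"], c["genes_detected"]
        ),
        "major_not_principal_percent": round_percent(
            c["major_not_principal_genes"], c["multi_isoform_genes"]
        ),
        "min_count_for_1cpm": math.ceil(c["total_long_reads"] / 1e6),
        "db_total_genes": c["db_gencode_genes"] + c["db_pacbio_genes"],
        "db_total_entries": c["db_gencode_entries"] + c["db_pacbio_entries"],
        "db_total_entries_with_contaminants": c["db_gencode_entries"]
        + c["db_pacbio_entries"]
        + c["db_contaminant_entries"],
        "evidenced_genes": c["shared_only_genes"] + c["unique_evidence_genes"],
        "unique_evidence_genes": c["single_isoform_db_genes"]
        + c["multi_isoform_db_unique_genes"],
        "shared_only_percent": round_percent(
            c["shared_only_genes"], c["evidenced_genes"]
        ),
        "unique_evidence_percent": round_percent(
            c["unique_evidence_genes"], c["evidenced_genes"]
        ),
        "single_isoform_db_percent": round_percent(
            c["single_isoform_db_genes"], c["evidenced_genes"]
        ),
        "multi_isoform_db_unique_percent": round_percent(
            c["multi_isoform_db_unique_genes"], c["evidenced_genes"]
        ),
        "one_confirmed_percent": round_percent(
            c["unique_supported_isoform_genes"], c["evidenced_genes"]
        ),
        "nominated_ambiguous_percent": round_percent(
            c["nominated_ambiguous_genes"], c["shared_only_genes"]
        ),
        "nominated_ambiguous_percent_of_pacbio_shared": round_percent(
            c["nominated_ambiguous_genes"], c["shared_only_with_pacbio"]
        ),
        "coexpression_nominated_percent": round_percent(
            c["coexpression_nominated_genes"], c["shared_only_genes"]
        ),
        "nominated_additional_percent": round_percent(
            c["nominated_additional_genes"], c["shared_only_genes"]
        ),
        "srsf5_total_cpm": round(sum(table1_cpms("SRSF5")), 1),
        "flt1_coexpressed_isoforms": sum(
            1 for cpm in table1_cpms("FLT1") if cpm >= 3.0
        ),
        "cdh5_major_cpm": max(table1_cpms("CDH5")),
    }
    return out
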