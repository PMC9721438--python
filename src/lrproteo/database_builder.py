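"""Hybrid protein database construction for MS searching.

Predicted proteins are filtered (truncation, class, NMD rules), grouped by
identical sequence within a gene with summed transcript CPM, and combined
with grouped reference proteins into the hybrid search database: sample
(long-read-derived) entries for high-confidence genes — aggregate gene
abundance >= 3 CPM and mean annotated transcript length 1-4 kbp — and
reference entries for every other annotated gene, plus contaminants.

Sample entry labels follow ``<Gene>|<PB accession>|<SQANTI Protein class>|
<CPM>`` with CPM printed to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .orf_calling import BestORF
from .protein_classification import PFSM, PNIC, PNNC, ProteinClass
from .reference_model import ReferenceCatalog, ReferenceProteinEntry
from .transcript_catalog import GeneExpressionSummary, LongReadTranscript

PACBIO = "PACBIO"
GENCODE = "GENCODE"
CONTAMINANT = "CONTAMINANT"

REMOVED_TRUNCATION = "truncation"
REMOVED_CLASS = "class"
REMOVED_NMD = "NMD"

DEFAULT_MIN_GENE_CPM = 3.0
DEFAULT_LENGTH_WINDOW_NT = (1000, 4000)
DEFAULT_NMD_MAX_JUNCTIONS_AFTER_STOP = 2


@dataclass
class ProteinDatabaseEntry:
    label: str
    gene: str | None
    sequence: str
    source: str  # PACBIO / GENCODE / CONTAMINANT
    protein_class: str | None = None  # PACBIO only
    cpm_sum: float | None = None  # PACBIO only
    member_accessions: list[str] = field(default_factory=list)
    representative: str | None = None


@dataclass
class HybridDatabase:
    entries: list[ProteinDatabaseEntry]
    gene_source_map: dict[str, str]
    thresholds: dict

    def by_gene(self) -> dict[str, list[ProteinDatabaseEntry]]:
        out: dict[str, list[ProteinDatabaseEntry]] = {}
        for e in self.entries:
            if e.gene is not None:
                out.setdefault(e.gene, []).append(e)
        return out

    def entry(self, label: str) -> ProteinDatabaseEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)


def filter_protein_isoforms(
    best_orfs: dict[str, BestORF],
    protein_classes: dict[str, ProteinClass],
    nmd_max_junctions_after_stop: int = DEFAULT_NMD_MAX_JUNCTIONS_AFTER_STOP,
) -> tuple[list[str], dict[str, str]]:
    """Apply the truncation, class and NMD filters; keep a removal ledger.

    Removal reasons, first match recorded: (1) ORF without a stop codon ->
    truncation suspect; (2) protein class outside {pFSM, pNIC, pNNC} ->
    class; (3) pNNC with more than ``nmd_max_junctions_after_stop`` junctions
    after the stop codon -> NMD.  The NMD rule is scoped to pNNC only: pFSM
    and pNIC isoforms are exempt regardless of junction count.

    Returns (retained accessions, ledger accession -> reason); retained +
    ledger partition the input.
    """
    retained: list[str] = []
    ledger: dict[str, str] = {}
    for acc in sorted(best_orfs):
        o = best_orfs[acc].orf
        cls = protein_classes[acc].category
        if not o.has_stop_codon:
            ledger[acc] = REMOVED_TRUNCATION
        elif cls not in (PFSM, PNIC, PNNC):
            ledger[acc] = REMOVED_CLASS
        elif (
            cls == PNNC
            and o.junctions_after_stop is not None
            and o.junctions_after_stop > nmd_max_junctions_after_stop
        ):
            ledger[acc] = REMOVED_NMD
        else:
            retained.append(acc)
    return retained, ledger


def group_orfs_by_sequence(
    retained: list[str],
    best_orfs: dict[str, BestORF],
    protein_classes: dict[str, ProteinClass],
    transcripts: dict[str, LongReadTranscript],
) -> list[ProteinDatabaseEntry]:
    """Group retained transcripts producing identical ORF sequences.

    One entry per (gene, protein sequence); cpm_sum is the sum of member
    CPMs; the representative accession is the highest-CPM member (ties to
    the smaller PB accession suffix) and contributes the entry's class and
    label.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for acc in retained:
        t = transcripts[acc]
        seq = best_orfs[acc].orf.protein_sequence
        groups.setdefault((t.gene_id, seq), []).append(acc)
    entries = []
    for (gene, seq), members in sorted(groups.items()):
        rep = min(members, key=lambda a: (-transcripts[a].cpm, transcripts[a].suffix_key))
        cpm_sum = sum(transcripts[a].cpm for a in members)
        cls = protein_classes[rep].category
        entries.append(
            ProteinDatabaseEntry(
                label=format_pacbio_label(gene, rep, cls, cpm_sum),
                gene=gene,
                sequence=seq,
                source=PACBIO,
                protein_class=cls,
                cpm_sum=cpm_sum,
                member_accessions=sorted(members),
                representative=rep,
            )
        )
    return entries


def format_pacbio_label(gene: str, pb_accession: str, cls: str, cpm: float) -> str:
    return f"{gene}|{pb_accession}|{cls}|{cpm:.1f}"


def select_high_confidence_genes(
    summaries: dict[str, GeneExpressionSummary],
    catalog: ReferenceCatalog,
    min_gene_cpm: float = DEFAULT_MIN_GENE_CPM,
    length_window_nt: tuple[int, int] = DEFAULT_LENGTH_WINDOW_NT,
) -> set[str]:
    """Genes whose long-read sampling is considered complete.

    A gene qualifies iff its aggregate transcript abundance is at least
    ``min_gene_cpm`` and its mean annotated (reference) transcript length
    falls inside ``length_window_nt``, boundaries inclusive.  Genes absent
    from the catalog are excluded with a warning.
    """
    import warnings

    lo, hi = length_window_nt
    out = set()
    for gid, s in summaries.items():
        if gid not in catalog.genes:
            warnings.warn(f"gene {gid} absent from reference catalog; excluded")
            continue
        mean_len = catalog.genes[gid].mean_annotated_length
        if s.total_gene_cpm >= min_gene_cpm and lo <= mean_len <= hi:
            out.add(gid)
    return out


def build_hybrid_database(
    grouped_entries: list[ProteinDatabaseEntry],
    reference_proteins: list[ReferenceProteinEntry],
    contaminants: list[tuple[str, str]],
    high_confidence_genes: set[str],
    catalog: ReferenceCatalog,
    thresholds: dict | None = None,
) -> HybridDatabase:
    """Assemble the hybrid database.

    High-confidence genes contribute their sample (PacBio) entries; every
    other catalog gene contributes its grouped reference entries (including
    genes absent from the long-read data); contaminant sequences are
    appended verbatim and carry no gene.  The gene source map covers every
    catalog gene exactly once.  Duplicate labels are a hard error.
    """
    gene_source_map = {
        gid: (PACBIO if gid in high_confidence_genes else GENCODE)
        for gid in catalog.genes
    }
    entries: list[ProteinDatabaseEntry] = []
    for e in grouped_entries:
        if gene_source_map.get(e.gene) == PACBIO:
            entries.append(e)
    for r in reference_proteins:
        if gene_source_map.get(r.gene, GENCODE) == GENCODE:
            entries.append(
                ProteinDatabaseEntry(
                    label=r.accession,
                    gene=r.gene,
                    sequence=r.sequence,
                    source=GENCODE,
                    member_accessions=list(r.member_transcripts),
                )
            )
    for name, seq in contaminants:
        entries.append(
            ProteinDatabaseEntry(label=name, gene=None, sequence=seq, source=CONTAMINANT)
        )
    labels = [e.label for e in entries]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate database labels: {dup[:5]}")
    return HybridDatabase(
        entries=entries,
        gene_source_map=gene_source_map,
        thresholds=thresholds
        or {
            "min_gene_cpm": DEFAULT_MIN_GENE_CPM,
            "length_window_nt": list(DEFAULT_LENGTH_WINDOW_NT),
        },
    )


def write_protein_fasta(db: HybridDatabase | list[ProteinDatabaseEntry], path) -> None:
    entries = db.entries if isinstance(db, HybridDatabase) else db
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.label}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")


def read_protein_fasta(path) -> list[tuple[str, str]]:
    """(header, sequence) pairs; the full header line is the label."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.description, str(rec.seq)))
    return out


def write_gene_source_map(db: HybridDatabase, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsource\n")
        for gid in sorted(db.gene_source_map):
            fh.write(f"{gid}\t{db.gene_source_map[gid]}\n")


def write_removal_ledger(ledger: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("pb_accession\treason\n")
        for acc in sorted(ledger):
            fh.write(f"{acc}\t{ledger[acc]}\n")


def write_browser_tracks(transcripts, path, name_of=None) -> None:
    """BED12 genome-browser track of transcript models (exon block structure)."""
    from .transcript_catalog import write_bed12

    write_bed12(transcripts, path, name_of=name_of)
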