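"""Long-read transcript catalog: CPM, FSM/NIC/NNC classification, summaries.

Implements the transcript-level half of the analysis: ingest long-read
transcript models (GTF exon chains + full-length read counts), compute counts
per million (CPM), classify each multi-exonic transcript against the
reference by splice-junction connectivity, and derive the gene-level
summaries the study reports (major/minor isoforms, APPRIS concordance,
co-expressed isoform genes, ranked gene-set abundance, amino-acid length
deltas of novel isoforms).

Classification categories follow SQANTI nomenclature:

* **FSM** (full splice match) — junction chain equal to a reference chain;
* **NIC** (novel in catalog) — all donor/acceptor sites annotated, chain new;
* **NNC** (novel not in catalog) — at least one unannotated donor/acceptor;
* **OTHER** — intergenic or mono-exonic without a mono-exonic reference match
  (absorbs SQANTI's remaining categories, which are out of scope here).
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .reference_model import Exon, Junction, ReferenceCatalog, junctions_of

FSM = "FSM"
NIC = "NIC"
NNC = "NNC"
OTHER = "OTHER"


@dataclass
class LongReadTranscript:
    """An observed long-read transcript model."""

    pb_accession: str  # PB.<cluster>.<n>
    exons: list[Exon]  # 5'->3' transcript order
    fl_count: int = 0
    cpm: float = 0.0
    gene_id: str | None = None
    spliced_sequence: str | None = None

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def junctions(self) -> tuple[Junction, ...]:
        return junctions_of(self.exons)

    @property
    def length_nt(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def suffix_key(self) -> tuple:
        """Numeric sort key for PB.<cluster>.<n> accessions."""
        m = re.match(r"PB\.(\d+)\.(\d+)$", self.pb_accession)
        if m:
            return (int(m.group(1)), int(m.group(2)))
        return (float("inf"), self.pb_accession)


@dataclass
class TranscriptClass:
    category: str
    matched_reference_transcript: str | None = None
    novel_sites: list[tuple[str, int]] = field(default_factory=list)
    reason: str | None = None


def compute_cpm(fl_counts: dict[str, int]) -> dict[str, float]:
    """Full-length read counts per million: count / total * 1e6.

    The denominator is the total full-length reads assigned to the supplied
    transcript models.  Raises ``ValueError("empty dataset")`` when the total
    is zero.
    """
    total = sum(fl_counts.values())
    if total <= 0:
        raise ValueError("empty dataset")
    if any(c < 0 for c in fl_counts.values()):
        raise ValueError("negative full-length read count")
    return {k: c / total * 1e6 for k, c in fl_counts.items()}


def attach_cpm(transcripts: list[LongReadTranscript]) -> None:
    """Compute and attach CPM in place from the transcripts' fl_counts."""
    cpm = compute_cpm({t.pb_accession: t.fl_count for t in transcripts})
    for t in transcripts:
        t.cpm = cpm[t.pb_accession]


def filter_min_abundance(
    transcripts: list[LongReadTranscript], min_cpm: float = 1.0
) -> list[LongReadTranscript]:
    """Retain transcripts with cpm >= min_cpm (boundary inclusive)."""
    return [t for t in transcripts if t.cpm >= min_cpm]


class GeneAssigner:
    """Assign long-read transcripts to reference genes by exonic overlap.

    The gene on the same strand with the largest total exonic overlap wins;
    ties break toward the gene sharing more splice sites, then gene id.
    """

    def __init__(self, catalog: ReferenceCatalog):
        self.catalog = catalog
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for gid, g in catalog.genes.items():
            tree = self._trees.setdefault((g.chrom, g.strand), IntervalTree())
            for t in catalog.gene_transcripts(gid):
                for e in t.exons:
                    tree[e.start : e.end] = gid

    def assign(self, t: LongReadTranscript) -> str | None:
        tree = self._trees.get((t.chrom, t.strand))
        if tree is None:
            return None
        overlap: dict[str, int] = {}
        for e in t.exons:
            for iv in tree.overlap(e.start, e.end):
                ov = min(e.end, iv.end) - max(e.start, iv.begin)
                overlap[iv.data] = overlap.get(iv.data, 0) + ov
        if not overlap:
            return None
        sites = {j.donor for j in t.junctions} | {j.acceptor for j in t.junctions}

        def shared_sites(gid: str) -> int:
            g = self.catalog.genes[gid]
            ref_sites = set()
            for chain in g.junction_chains:
                for j in chain:
                    ref_sites.add(j.donor)
                    ref_sites.add(j.acceptor)
            return len(sites & ref_sites)

        return min(
            overlap,
            key=lambda gid: (-overlap[gid], -shared_sites(gid), gid),
        )


def classify_transcript(
    t: LongReadTranscript, catalog: ReferenceCatalog
) -> TranscriptClass:
    """Classify a transcript against the reference by junction connectivity.

    Decision order for multi-exonic transcripts: any unannotated donor or
    acceptor site (per chrom/strand site sets) -> NNC; exact junction-chain
    match to a reference transcript -> FSM; otherwise NIC.  Mono-exonic
    transcripts are FSM when fully contained within a mono-exonic reference
    transcript of the same gene, else OTHER.  Transcripts assigned to no
    reference gene are OTHER (intergenic).
    """
    if t.gene_id is None or t.gene_id not in catalog.genes:
        return TranscriptClass(OTHER, reason="intergenic")
    gene = catalog.genes[t.gene_id]
    chain = t.junctions
    if not chain:  # mono-exonic
        for rt in catalog.gene_transcripts(t.gene_id):
            if len(rt.exons) == 1:
                r = rt.exons[0]
                e = t.exons[0]
                if r.start <= e.start and e.end <= r.end:
                    return TranscriptClass(FSM, matched_reference_transcript=rt.transcript_id)
        return TranscriptClass(OTHER, reason="mono-exonic without mono-exonic reference")
    novel = []
    for j in chain:
        if not catalog.is_known_donor(t.chrom, t.strand, j.donor):
            novel.append(("donor", j.donor))
        if not catalog.is_known_acceptor(t.chrom, t.strand, j.acceptor):
            novel.append(("acceptor", j.acceptor))
    if novel:
        return TranscriptClass(NNC, novel_sites=novel)
    if chain in gene.junction_chains:
        for rt in catalog.gene_transcripts(t.gene_id):
            if rt.junctions == chain:
                return TranscriptClass(FSM, matched_reference_transcript=rt.transcript_id)
    # chain may match a transcript of a different gene at the same locus
    for rt in catalog.transcripts.values():
        if (
            rt.chrom == t.chrom
            and rt.strand == t.strand
            and rt.junctions == chain
        ):
            return TranscriptClass(FSM, matched_reference_transcript=rt.transcript_id)
    return TranscriptClass(NIC)


@dataclass
class GeneExpressionSummary:
    gene_id: str
    isoforms: list[LongReadTranscript]  # sorted by cpm descending
    major_isoform: str
    minor_isoforms: list[str]
    principal_transcript: str | None
    major_matches_principal: bool
    total_gene_cpm: float


def summarize_gene_expression(
    gene_transcripts: list[LongReadTranscript],
    catalog: ReferenceCatalog,
    classes: dict[str, TranscriptClass],
) -> GeneExpressionSummary:
    """Major/minor calls and APPRIS concordance for one gene's transcripts.

    The major isoform is the CPM argmax; ties break toward larger fl_count,
    then smaller PB accession numeric suffix.  ``major_matches_principal`` is
    true iff the major is an FSM whose matched reference transcript is the
    gene's APPRIS principal.
    """
    if not gene_transcripts:
        raise ValueError("gene has no transcripts")
    ranked = sorted(
        gene_transcripts, key=lambda t: (-t.cpm, -t.fl_count, t.suffix_key)
    )
    gene_id = gene_transcripts[0].gene_id
    principal = None
    if gene_id in catalog.genes:
        p = catalog.principal_transcript(gene_id)
        principal = p.transcript_id if p else None
    major = ranked[0]
    cls = classes.get(major.pb_accession)
    matches = bool(
        cls
        and cls.category == FSM
        and principal is not None
        and cls.matched_reference_transcript == principal
    )
    return GeneExpressionSummary(
        gene_id=gene_id,
        isoforms=ranked,
        major_isoform=major.pb_accession,
        minor_isoforms=[t.pb_accession for t in ranked[1:]],
        principal_transcript=principal,
        major_matches_principal=matches,
        total_gene_cpm=sum(t.cpm for t in ranked),
    )


def summarize_all_genes(
    transcripts: list[LongReadTranscript],
    catalog: ReferenceCatalog,
    classes: dict[str, TranscriptClass],
) -> dict[str, GeneExpressionSummary]:
    by_gene: dict[str, list[LongReadTranscript]] = {}
    for t in transcripts:
        if t.gene_id is not None:
            by_gene.setdefault(t.gene_id, []).append(t)
    return {
        gid: summarize_gene_expression(ts, catalog, classes)
        for gid, ts in sorted(by_gene.items())
    }


def major_principal_concordance(
    summaries: dict[str, GeneExpressionSummary],
) -> tuple[int, float]:
    """(mismatch count, fraction) of multi-isoform genes whose major isoform
    is not the APPRIS principal.  Single-isoform genes are excluded from the
    denominator."""
    multi = [s for s in summaries.values() if len(s.isoforms) >= 2]
    if not multi:
        return 0, 0.0
    mism = sum(1 for s in multi if not s.major_matches_principal)
    return mism, mism / len(multi)


def coexpressed_isoform_genes(
    summaries: dict[str, GeneExpressionSummary],
    min_isoforms: int = 2,
    min_cpm: float = 3.0,
) -> list[str]:
    """Genes with >= min_isoforms isoforms each at cpm >= min_cpm."""
    out = []
    for gid, s in summaries.items():
        n = sum(1 for t in s.isoforms if t.cpm >= min_cpm)
        if n >= min_isoforms:
            out.append(gid)
    return sorted(out)


def rank_gene_set_by_abundance(
    summaries: dict[str, GeneExpressionSummary], gene_list: list[str]
) -> list[tuple[str, float]]:
    """Detected genes from a curated list, ranked by total gene CPM.

    Genes without any detected transcript are dropped; ties sort by gene id.
    """
    rows = [
        (gid, summaries[gid].total_gene_cpm)
        for gid in gene_list
        if gid in summaries
    ]
    return sorted(rows, key=lambda r: (-r[1], r[0]))


@dataclass
class LengthDeltaSummary:
    deltas: dict[str, int]  # pb_accession -> aa delta vs comparator
    median_shortening: float | None  # median |delta| over negative deltas
    mean_gain: float | None  # mean delta over positive deltas


def length_deltas_vs_reference(
    novel_proteins: dict[str, str],
    gene_of: dict[str, str],
    catalog: ReferenceCatalog,
    comparator: str = "principal",
    major_proteins: dict[str, str] | None = None,
) -> LengthDeltaSummary:
    """Amino-acid length delta of each novel protein vs its comparator.

    ``delta = len(novel) - len(comparator)``; the comparator is the gene's
    APPRIS principal protein (default) or the sample major isoform's protein
    (``comparator="major"`` with ``major_proteins`` gene -> protein).
    Shortenings (negative deltas) and gains (positive deltas) are summarized
    separately; genes without a comparator protein are skipped with a
    warning.
    """
    import warnings

    deltas: dict[str, int] = {}
    for acc, prot in novel_proteins.items():
        gid = gene_of.get(acc)
        comp = None
        if comparator == "major":
            comp = (major_proteins or {}).get(gid)
        elif gid in catalog.genes:
            p = catalog.principal_transcript(gid)
            comp = p.protein_sequence if p else None
        if not comp:
            warnings.warn(f"no comparator protein for gene {gid}; {acc} skipped")
            continue
        deltas[acc] = len(prot) - len(comp)
    neg = [-d for d in deltas.values() if d < 0]
    pos = [d for d in deltas.values() if d > 0]
    return LengthDeltaSummary(
        deltas=deltas,
        median_shortening=statistics.median(neg) if neg else None,
        mean_gain=statistics.fmean(pos) if pos else None,
    )


def round_percent(numerator: float, denominator: float) -> int:
    """Nearest-integer percentage, half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = numerator / denominator * 100.0
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# I/O


def load_long_read_models(
    gtf_path, counts_tsv_path, catalog: ReferenceCatalog | None = None
) -> list[LongReadTranscript]:
    """Load long-read transcript models (GTF exon chains) and FL counts.

    The counts TSV has columns ``pb_accession<TAB>fl_count``.  When a catalog
    is supplied, transcripts are assigned to genes by exonic overlap and CPM
    is attached.
    """
    import gffutils

    from .reference_model import _validate_gtf_lines

    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    counts: dict[str, int] = {}
    with open(counts_tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("pb_accession") or line.startswith("#"):
                continue
            acc, cnt = line.split("\t")[:2]
            counts[acc] = int(cnt)
    grouped: dict[str, list] = {}
    for f in db.features_of_type("exon"):
        grouped.setdefault(f.attributes["transcript_id"][0], []).append(f)
    transcripts = []
    for acc in sorted(grouped):
        feats = sorted(grouped[acc], key=lambda f: f.start)
        strand = feats[0].strand
        ex = [Exon(f.seqid, f.start - 1, f.end, strand) for f in feats]
        if strand == "-":
            ex = ex[::-1]
        transcripts.append(
            LongReadTranscript(pb_accession=acc, exons=ex, fl_count=counts.get(acc, 0))
        )
    if catalog is not None:
        assigner = GeneAssigner(catalog)
        for t in transcripts:
            t.gene_id = assigner.assign(t)
            if catalog.genome is not None:
                t.spliced_sequence = _spliced_seq(catalog.genome, t)
        attach_cpm(transcripts)
    return transcripts


def _spliced_seq(genome, t: LongReadTranscript) -> str:
    from .reference_model import _spliced

    return _spliced(genome, t.exons)


def write_classification_tsv(
    transcripts: list[LongReadTranscript],
    classes: dict[str, TranscriptClass],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("pb_accession\tgene\tcategory\tmatched_ref\tfl_count\tcpm\n")
        for t in transcripts:
            c = classes[t.pb_accession]
            fh.write(
                f"{t.pb_accession}\t{t.gene_id or ''}\t{c.category}\t"
                f"{c.matched_reference_transcript or ''}\t{t.fl_count}\t{t.cpm:.4f}\n"
            )


def write_bed12(transcripts: list[LongReadTranscript], path, name_of=None) -> None:
    """Write transcript models as a BED12 genome-browser track."""
    with open(path, "w") as fh:
        for t in transcripts:
            ex = sorted(t.exons, key=lambda e: e.start)
            chrom_start = ex[0].start
            chrom_end = ex[-1].end
            sizes = ",".join(str(e.length) for e in ex)
            starts = ",".join(str(e.start - chrom_start) for e in ex)
            name = name_of(t) if name_of else t.pb_accession
            fh.write(
                f"{t.chrom}\t{chrom_start}\t{chrom_end}\t{name}\t0\t{t.strand}\t"
                f"{chrom_start}\t{chrom_end}\t0\t{len(ex)}\t{sizes}\t{starts}\n"
            )
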