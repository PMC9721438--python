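"""Reference annotation model: genes, transcripts, splice-site indices.

Loads a GTF + genome FASTA (+ optional APPRIS principal-isoform table) into a
:class:`ReferenceCatalog`, the index every downstream stage queries: per-strand
donor/acceptor/junction sets, per-gene junction chains, annotated start/stop
codon positions, and per-gene mean annotated transcript length.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
1-based inclusive convention.  Donor/acceptor roles are strand-aware: a
junction is identified by ``(chrom, strand, lower, upper)`` where
``[lower, upper)`` is the intron, the donor is the intron boundary nearer the
transcript 5' end and the acceptor the boundary nearer the 3' end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pyfaidx
from Bio.Seq import Seq

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


@dataclass(frozen=True)
class Exon:
    """A genomic exon interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise AnnotationError(
                f"exon start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class Junction:
    """An intron, identified by (chrom, strand, lower, upper) half-open.

    ``donor``/``acceptor`` are derived, strand-aware role labels: on '+' the
    donor is ``lower`` (first intron base) and the acceptor ``upper``; on '-'
    the roles swap.  The intronic sequence has length ``upper - lower``.
    """

    chrom: str
    strand: str
    lower: int
    upper: int

    def __post_init__(self):
        if not self.lower < self.upper:
            raise AnnotationError(
                f"junction lower must be < upper, got [{self.lower}, {self.upper})"
            )

    @property
    def donor(self) -> int:
        return self.lower if self.strand == "+" else self.upper

    @property
    def acceptor(self) -> int:
        return self.upper if self.strand == "+" else self.lower


def junctions_of(exons: list[Exon]) -> tuple[Junction, ...]:
    """Junction chain of an exon list given in 5'->3' transcript order.

    A transcript with n exons has exactly n-1 junctions.
    """
    if not exons:
        return ()
    strand = exons[0].strand
    genomic = sorted(exons, key=lambda e: e.start)
    chain = tuple(
        Junction(exons[0].chrom, strand, a.end, b.start)
        for a, b in zip(genomic[:-1], genomic[1:])
    )
    return chain if strand == "+" else chain[::-1]


@dataclass
class ReferenceTranscript:
    transcript_id: str
    gene_id: str
    gene_name: str
    exons: list[Exon]  # 5'->3' transcript order
    cds_start: int | None = None  # genomic, 0-based; includes stop codon
    cds_end: int | None = None  # genomic, half-open
    protein_id: str | None = None
    protein_sequence: str | None = None
    is_principal: bool = False

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def length_nt(self) -> int:
        """Spliced (exonic) length in nucleotides."""
        return sum(e.length for e in self.exons)

    @property
    def junctions(self) -> tuple[Junction, ...]:
        return junctions_of(self.exons)

    @property
    def start_codon_pos(self) -> int | None:
        """Genomic position of the first base of the start codon."""
        if not self.is_coding:
            return None
        return self.cds_start if self.strand == "+" else self.cds_end - 1

    @property
    def stop_codon_pos(self) -> int | None:
        """Genomic position of the last base of the stop codon."""
        if not self.is_coding:
            return None
        return self.cds_end - 1 if self.strand == "+" else self.cds_start

    def cds_exons(self) -> list[Exon]:
        """Exon intervals clipped to [cds_start, cds_end), transcript order."""
        if not self.is_coding:
            return []
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s < t:
                out.append(Exon(e.chrom, s, t, e.strand))
        return out

    def cds_junctions(self) -> tuple[Junction, ...]:
        """Junctions internal to the coding region, transcript order."""
        return junctions_of(self.cds_exons())

    def spliced_sequence(self, genome) -> str:
        return _spliced(genome, self.exons)

    def cds_sequence(self, genome) -> str:
        return _spliced(genome, self.cds_exons())


def _spliced(genome, exons: list[Exon]) -> str:
    """Concatenate exon sequences in transcript orientation."""
    parts = []
    for e in exons:
        seq = str(genome[e.chrom][e.start : e.end]).upper()
        if e.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        parts.append(seq)
    return "".join(parts)


@dataclass
class GeneIndex:
    """Per-gene annotation summaries used by classification and filtering."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcript_ids: list[str] = field(default_factory=list)
    junction_chains: set[tuple[Junction, ...]] = field(default_factory=set)
    start_codon_positions: set[int] = field(default_factory=set)
    stop_codon_positions: set[int] = field(default_factory=set)
    cds_donor_sites: set[int] = field(default_factory=set)
    cds_acceptor_sites: set[int] = field(default_factory=set)
    mean_annotated_length: float = 0.0


@dataclass
class ReferenceCatalog:
    """Indexed view of a reference annotation."""

    transcripts: dict[str, ReferenceTranscript] = field(default_factory=dict)
    genes: dict[str, GeneIndex] = field(default_factory=dict)
    # per (chrom, strand): annotated splice-site and junction sets
    donor_sites: dict[tuple[str, str], set[int]] = field(default_factory=dict)
    acceptor_sites: dict[tuple[str, str], set[int]] = field(default_factory=dict)
    junction_set: dict[tuple[str, str], set[tuple[int, int]]] = field(
        default_factory=dict
    )
    genome: object | None = None

    def gene_transcripts(self, gene_id: str) -> list[ReferenceTranscript]:
        return [self.transcripts[t] for t in self.genes[gene_id].transcript_ids]

    def coding_transcripts(self, gene_id: str) -> list[ReferenceTranscript]:
        return [t for t in self.gene_transcripts(gene_id) if t.is_coding]

    def is_known_donor(self, chrom: str, strand: str, pos: int) -> bool:
        return pos in self.donor_sites.get((chrom, strand), ())

    def is_known_acceptor(self, chrom: str, strand: str, pos: int) -> bool:
        return pos in self.acceptor_sites.get((chrom, strand), ())

    def principal_transcript(self, gene_id: str) -> ReferenceTranscript | None:
        for t in self.gene_transcripts(gene_id):
            if t.is_principal:
                return t
        return None

    def _index_transcript(self, t: ReferenceTranscript) -> None:
        self.transcripts[t.transcript_id] = t
        g = self.genes.get(t.gene_id)
        if g is None:
            g = GeneIndex(t.gene_id, t.gene_name, t.chrom, t.strand)
            self.genes[t.gene_id] = g
        g.transcript_ids.append(t.transcript_id)
        key = (t.chrom, t.strand)
        chain = t.junctions
        g.junction_chains.add(chain)
        for j in chain:
            self.donor_sites.setdefault(key, set()).add(j.donor)
            self.acceptor_sites.setdefault(key, set()).add(j.acceptor)
            self.junction_set.setdefault(key, set()).add((j.lower, j.upper))
        if t.is_coding:
            g.start_codon_positions.add(t.start_codon_pos)
            g.stop_codon_positions.add(t.stop_codon_pos)
            for j in t.cds_junctions():
                g.cds_donor_sites.add(j.donor)
                g.cds_acceptor_sites.add(j.acceptor)

    def _finalize(self) -> None:
        for g in self.genes.values():
            lens = [self.transcripts[t].length_nt for t in g.transcript_ids]
            g.mean_annotated_length = sum(lens) / len(lens)


# APPRIS principal labels ordered best-first; used for tie-breaking.
_APPRIS_RANK = {f"PRINCIPAL:{i}": i for i in range(1, 6)}


def load_annotation(
    gtf_path,
    genome_fasta_path,
    appris_table_path=None,
    translate_cds: bool = True,
) -> ReferenceCatalog:
    """Load a GTF + genome (+ APPRIS table) into a :class:`ReferenceCatalog`.

    The GTF must carry ``gene_id``/``transcript_id`` attributes on ``exon``
    and ``CDS`` features (Ensembl/GENCODE dialect).  CDS intervals are taken
    to include the stop codon; a separate ``stop_codon`` feature, when
    present, is merged into the CDS.  Transcripts without CDS are retained
    and marked non-coding.

    Raises :class:`AnnotationError` naming the chromosome if an annotated
    chromosome is missing from the genome, or naming the line number for a
    malformed GTF line.
    """
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genome = pyfaidx.Fasta(str(genome_fasta_path))

    exons: dict[str, list] = {}
    meta: dict[str, dict] = {}
    cds: dict[str, list] = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        if f.seqid not in genome:
            raise AnnotationError(
                f"chromosome {f.seqid!r} referenced by transcript {tid} "
                f"is missing from the genome FASTA"
            )
        exons.setdefault(tid, []).append(f)
        meta.setdefault(
            tid,
            {
                "gene_id": f.attributes["gene_id"][0],
                "gene_name": f.attributes.get("gene_name", [None])[0]
                or f.attributes["gene_id"][0],
            },
        )
    for ftype in ("CDS", "stop_codon"):
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            feats = []
        for f in feats:
            tid = f.attributes["transcript_id"][0]
            cds.setdefault(tid, []).append(f)
            if "protein_id" in f.attributes:
                meta.setdefault(tid, {}).setdefault(
                    "protein_id", f.attributes["protein_id"][0]
                )

    catalog = ReferenceCatalog(genome=genome)
    for tid in sorted(exons):
        feats = sorted(exons[tid], key=lambda f: f.start)
        strand = feats[0].strand
        ex = [Exon(f.seqid, f.start - 1, f.end, strand) for f in feats]
        if strand == "-":
            ex = ex[::-1]
        t = ReferenceTranscript(
            transcript_id=tid,
            gene_id=meta[tid]["gene_id"],
            gene_name=meta[tid]["gene_name"],
            exons=ex,
            protein_id=meta[tid].get("protein_id"),
        )
        if tid in cds:
            t.cds_start = min(f.start for f in cds[tid]) - 1
            t.cds_end = max(f.end for f in cds[tid])
            if translate_cds:
                t.protein_sequence = translate_orf(t.cds_sequence(genome))
        catalog._index_transcript(t)
    catalog._finalize()

    if appris_table_path is not None:
        apply_appris_flags(catalog, appris_table_path)
    return catalog


def translate_orf(nt: str) -> str:
    """Translate an ORF nucleotide sequence, trimming a terminal stop codon.

    Translation stops at the first in-frame stop; trailing bases short of a
    codon are ignored.  Codons containing N are untranslatable and terminate
    the protein.
    """
    aas = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3].upper()
        if codon in STOP_CODONS:
            break
        if "N" in codon:
            break
        aas.append(str(Seq(codon).translate()))
    return "".join(aas)


def apply_appris_flags(catalog: ReferenceCatalog, appris_table_path) -> None:
    """Set ``is_principal`` from an APPRIS TSV (gene_id, transcript_id, label).

    Exactly zero or one transcript per gene ends up flagged; ties between
    multiple PRINCIPAL tags break by lowest principal rank then alphanumeric
    transcript id.  Table rows naming transcripts absent from the annotation
    are skipped with a warning.
    """
    per_gene: dict[str, list[tuple[int, str]]] = {}
    with open(appris_table_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            gene_id, tid, label = line.split("\t")[:3]
            if tid not in catalog.transcripts:
                warnings.warn(
                    f"APPRIS transcript {tid} absent from annotation; flag skipped"
                )
                continue
            if label.startswith("PRINCIPAL"):
                rank = _APPRIS_RANK.get(label, 99)
                per_gene.setdefault(gene_id, []).append((rank, tid))
    for gene_id, cands in per_gene.items():
        _, best = min(cands)
        for t in catalog.gene_transcripts(gene_id):
            t.is_principal = t.transcript_id == best


@dataclass
class ReferenceProteinEntry:
    """A distinct (gene, protein sequence) pair among reference transcripts."""

    accession: str
    gene: str
    sequence: str
    member_transcripts: list[str]


def group_reference_proteins(catalog: ReferenceCatalog) -> list[ReferenceProteinEntry]:
    """Group reference coding transcripts with identical protein sequences.

    One entry per distinct (gene, sequence) pair; the entry accession is the
    alphanumerically first member protein accession (the ``protein_id`` GTF
    attribute when present, else the transcript id).  Non-coding transcripts
    are skipped.
    """
    groups: dict[tuple[str, str], list[ReferenceTranscript]] = {}
    for gene_id in sorted(catalog.genes):
        for t in catalog.gene_transcripts(gene_id):
            if t.protein_sequence:
                groups.setdefault((gene_id, t.protein_sequence), []).append(t)
    entries = []
    for (gene_id, seq), members in groups.items():
        accs = sorted(m.protein_id or m.transcript_id for m in members)
        entries.append(
            ReferenceProteinEntry(
                accession=accs[0],
                gene=gene_id,
                sequence=seq,
                member_transcripts=sorted(m.transcript_id for m in members),
            )
        )
    entries.sort(key=lambda e: (e.gene, e.accession))
    return entries


def write_catalog_gtf(catalog: ReferenceCatalog, path) -> None:
    """Write the catalog back to GTF (1-based inclusive; CDS includes stop)."""
    with open(path, "w") as fh:
        for tid in catalog.transcripts:
            t = catalog.transcripts[tid]
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_name}";'
            )
            lo = min(e.start for e in t.exons)
            hi = max(e.end for e in t.exons)
            fh.write(
                f"{t.chrom}\tlrproteo\ttranscript\t{lo + 1}\t{hi}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for e in sorted(t.exons, key=lambda e: e.start):
                fh.write(
                    f"{e.chrom}\tlrproteo\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                pid = t.protein_id or t.transcript_id
                for e in sorted(t.cds_exons(), key=lambda e: e.start):
                    fh.write(
                        f"{e.chrom}\tlrproteo\tCDS\t{e.start + 1}\t{e.end}\t.\t"
                        f'{e.strand}\t0\t{attrs} protein_id "{pid}";\n'
                    )


def _validate_gtf_lines(gtf_path) -> None:
    with open(gtf_path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n = len(line.rstrip("\n").split("\t"))
            if n < 9:
                raise AnnotationError(
                    f"malformed GTF line {i} in {gtf_path}: expected 9 "
                    f"tab-separated fields, found {n}"
                )
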