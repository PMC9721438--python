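"""Peptide-level isoform evidence, nominations, and novel-peptide calls.

Externally identified peptides (sequence, q-value, PSM count) are mapped
onto the hybrid database under the tryptic digestion rule (cleave after K/R
except before P, up to 2 missed cleavages).  From the mappings this module
derives:

* per-gene evidence scenarios — single isoform in database / shared-only /
  one isoform confirmed by a unique peptide / multiple confirmed;
* abundance-based nominations of isoforms evidenced only by shared peptides
  when the associated transcript abundance reaches 25 CPM;
* novel peptides — identifications at the strict q-value tier (< 0.001)
  mapping to a sample entry but absent from the digests of both reference
  protein databases — with annotation of the supporting transcriptional
  event (novel exon, novel acceptor/donor, intron retention, frameshift);
* the gene-level RNA-protein abundance correlation (OLS on log10 CPM vs
  log10 PSM, pseudocount 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import parser as pyt_parser
from scipy import stats as sps

from .database_builder import GENCODE, PACBIO, HybridDatabase, ProteinDatabaseEntry
from .orf_calling import BestORF, genomic_footprint
from .reference_model import ReferenceCatalog
from .transcript_catalog import GeneExpressionSummary, LongReadTranscript

TRYPSIN_RULE = r"[KR](?!P)"
DEFAULT_Q_MAX = 0.01
STRICT_NOVEL_Q = 0.001
DEFAULT_MISSED_CLEAVAGES = 2
DEFAULT_MIN_PEPTIDE_LEN = 7
DEFAULT_MAX_PEPTIDE_LEN = 50

SINGLE_ISOFORM_IN_DB = "SINGLE_ISOFORM_IN_DB"
SHARED_ONLY = "SHARED_ONLY"
ONE_CONFIRMED = "ONE_CONFIRMED"
MULTI_CONFIRMED = "MULTI_CONFIRMED"

NOM_NONE = "NONE"
NOM_AMBIGUOUS = "NOMINATED_AMBIGUOUS"
NOM_ADDITIONAL = "NOMINATED_ADDITIONAL"

EVENTS = (
    "novel_exon",
    "novel_acceptor",
    "novel_donor",
    "intron_retention",
    "frameshift",
    "other",
)


@dataclass
class PeptideIdentification:
    sequence: str
    q_value: float
    psm_count: int = 1


@dataclass
class PeptideMapping:
    peptide: PeptideIdentification
    hit_entries: set[str] = field(default_factory=set)
    hit_genes: set[str] = field(default_factory=set)

    @property
    def is_unique_isoform(self) -> bool:
        return len(self.hit_entries) == 1 and len(self.hit_genes) == 1

    @property
    def is_multi_gene(self) -> bool:
        return len(self.hit_genes) > 1


@dataclass
class GeneEvidence:
    gene: str
    scenario: str
    confirmed_entries: list[str] = field(default_factory=list)
    nomination: str = NOM_NONE
    nominated_entries: list[str] = field(default_factory=list)
    coexpression_nominated: bool = False


@dataclass
class NovelPeptide:
    sequence: str
    hit_entries: list[str]
    q_value: float
    event: str = "other"


def filter_identifications(
    peptides: list[PeptideIdentification],
    q_max: float = DEFAULT_Q_MAX,
    strict: bool = False,
) -> list[PeptideIdentification]:
    """Retain identifications at q <= q_max (inclusive).

    The strict novel-candidate tier (``strict=True``) instead requires q
    strictly below ``q_max`` (q-values "below 0.001").
    """
    if strict:
        return [p for p in peptides if p.q_value < q_max]
    return [p for p in peptides if p.q_value <= q_max]


def digest(
    sequence: str,
    missed_cleavages: int = DEFAULT_MISSED_CLEAVAGES,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> set[str]:
    """Tryptic digest of one protein: cleave after K/R except before P."""
    peps = pyt_parser.cleave(
        sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=min_len
    )
    return {p for p in peps if len(p) <= max_len}


def digest_reference(
    sequences: list[str],
    missed_cleavages: int = DEFAULT_MISSED_CLEAVAGES,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
    il_equivalent: bool = False,
) -> set[str]:
    """Union digest of a reference protein database."""
    out: set[str] = set()
    for s in sequences:
        out |= digest(s, missed_cleavages, min_len, max_len)
    if il_equivalent:
        out = {p.replace("I", "L") for p in out}
    return out


class PeptideIndex:
    """Inverted index peptide -> database entry labels, digest-legal termini."""

    def __init__(
        self,
        entries: list[ProteinDatabaseEntry],
        missed_cleavages: int = DEFAULT_MISSED_CLEAVAGES,
        min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
        max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
    ):
        self.entries = {e.label: e for e in entries}
        self.index: dict[str, set[str]] = {}
        for e in entries:
            for pep in digest(e.sequence, missed_cleavages, min_len, max_len):
                self.index.setdefault(pep, set()).add(e.label)

    def lookup(self, peptide: str) -> set[str]:
        return set(self.index.get(peptide, ()))


def map_peptides(
    peptides: list[PeptideIdentification],
    db: HybridDatabase,
    index: PeptideIndex | None = None,
    substring_mode: bool = False,
) -> tuple[list[PeptideMapping], list[PeptideIdentification]]:
    """Map peptides onto database entries.

    A peptide hits an entry iff it occurs in the entry's tryptic digest
    (or, with ``substring_mode``, as a plain substring).  Returns (mappings
    with >= 1 hit, unmapped peptides); unmapped identifications are excluded
    from gene evidence.
    """
    if index is None and not substring_mode:
        index = PeptideIndex(db.entries)
    mappings, unmapped = [], []
    for p in peptides:
        if substring_mode:
            hits = {e.label for e in db.entries if p.sequence in e.sequence}
        else:
            hits = index.lookup(p.sequence)
        if not hits:
            unmapped.append(p)
            continue
        lookup = index.entries if index else {e.label: e for e in db.entries}
        genes = {g for g in (lookup[h].gene for h in hits) if g is not None}
        mappings.append(PeptideMapping(peptide=p, hit_entries=hits, hit_genes=genes))
    return mappings, unmapped


def classify_gene_scenarios(
    mappings: list[PeptideMapping], db: HybridDatabase
) -> dict[str, GeneEvidence]:
    """Per-gene evidence scenario from the peptide mappings.

    Only genes with at least one mapped peptide enter the result.  Peptides
    hitting entries of more than one gene ("razor" peptides) are excluded
    from isoform-level evidence.  Scenario: one database entry for the gene
    -> SINGLE_ISOFORM_IN_DB; else by the count of entries carrying a
    uniquely mapping peptide (0 -> SHARED_ONLY, 1 -> ONE_CONFIRMED, >= 2 ->
    MULTI_CONFIRMED).
    """
    by_gene_entries = db.by_gene()
    evidenced: dict[str, list[PeptideMapping]] = {}
    for m in mappings:
        if m.is_multi_gene:
            continue
        for g in m.hit_genes:
            evidenced.setdefault(g, []).append(m)
    out: dict[str, GeneEvidence] = {}
    for gene, ms in sorted(evidenced.items()):
        n_entries = len(by_gene_entries.get(gene, ()))
        confirmed = sorted(
            {next(iter(m.hit_entries)) for m in ms if m.is_unique_isoform}
        )
        if n_entries == 1:
            scenario = SINGLE_ISOFORM_IN_DB
        elif len(confirmed) >= 2:
            scenario = MULTI_CONFIRMED
        elif len(confirmed) == 1:
            scenario = ONE_CONFIRMED
        else:
            scenario = SHARED_ONLY
        out[gene] = GeneEvidence(gene=gene, scenario=scenario, confirmed_entries=confirmed)
    return out


def nominate_by_transcript_abundance(
    evidence: dict[str, GeneEvidence],
    db: HybridDatabase,
    cpm_min: float = 25.0,
) -> dict[str, GeneEvidence]:
    """Nominate isoforms lacking unique-peptide support by transcript CPM.

    SHARED_ONLY genes with at least one sample (PacBio) entry at cpm_sum >=
    ``cpm_min`` are nominated as ambiguous-resolved; ONE_CONFIRMED genes
    with an unconfirmed sample entry at >= ``cpm_min`` receive additional
    nominations.  Genes with only reference-sourced entries have no
    abundance and are never nominated.  A SHARED_ONLY gene with >= 2
    nominated entries is flagged as potential isoform co-expression.
    Updates and returns ``evidence`` in place.
    """
    by_gene = db.by_gene()
    for gene, ev in evidence.items():
        entries = by_gene.get(gene, [])
        pacbio = [e for e in entries if e.source == PACBIO]
        if ev.scenario == SHARED_ONLY:
            nom = [e.label for e in pacbio if (e.cpm_sum or 0.0) >= cpm_min]
            if nom:
                ev.nomination = NOM_AMBIGUOUS
                ev.nominated_entries = sorted(nom)
                ev.coexpression_nominated = len(nom) >= 2
        elif ev.scenario == ONE_CONFIRMED:
            nom = [
                e.label
                for e in pacbio
                if e.label not in ev.confirmed_entries and (e.cpm_sum or 0.0) >= cpm_min
            ]
            if nom:
                ev.nomination = NOM_ADDITIONAL
                ev.nominated_entries = sorted(nom)
    return evidence


def detect_novel_peptides(
    peptides: list[PeptideIdentification],
    mappings: list[PeptideMapping],
    reference_digests: list[set[str]],
    db: HybridDatabase,
    q_strict: float = STRICT_NOVEL_Q,
    il_equivalent: bool = False,
) -> list[NovelPeptide]:
    """Novel peptides at the strict q tier.

    A peptide is novel iff q < ``q_strict``, it maps to at least one sample
    (PacBio) entry, and its sequence is absent from every supplied reference
    digest.  With ``il_equivalent`` the absence check treats isoleucine and
    leucine as identical (conservative novelty calls keep them distinct by
    default).
    """
    strict = {p.sequence for p in filter_identifications(peptides, q_strict, strict=True)}
    mapped = {m.peptide.sequence: m for m in mappings}
    out = []
    for seq in sorted(strict):
        m = mapped.get(seq)
        if m is None:
            continue
        pac_hits = [
            h for h in sorted(m.hit_entries) if db.entry(h).source == PACBIO
        ]
        if not pac_hits:
            continue
        probe = seq.replace("I", "L") if il_equivalent else seq
        if any(
            (probe in d) if il_equivalent else (seq in d) for d in reference_digests
        ):
            continue
        out.append(
            NovelPeptide(sequence=seq, hit_entries=pac_hits, q_value=m.peptide.q_value)
        )
    return out


# ---------------------------------------------------------------------------
# Novel-event annotation


def annotate_novel_event(
    novel: NovelPeptide,
    entry: ProteinDatabaseEntry,
    transcript: LongReadTranscript,
    best_orf: BestORF,
    catalog: ReferenceCatalog,
) -> str:
    """Label the transcriptional event a novel peptide supports.

    The peptide is located on the entry's protein, projected to its genomic
    footprint through the transcript's exon chain, and compared with the
    reference annotation of the gene:

    * spans a transcript junction whose donor/acceptor is unannotated ->
      ``novel_donor`` / ``novel_acceptor``;
    * footprint in reference-intronic sequence: contained in a transcript
      exon bridging the full intron -> ``intron_retention``; in an exon
      overlapping no reference exon -> ``novel_exon``; in a one-sided exon
      extension -> ``novel_acceptor``/``novel_donor`` by the extended side;
    * footprint within annotated CDS but read in a different frame in every
      reference coding transcript -> ``frameshift``;
    * otherwise ``other``.
    """
    import warnings

    o = best_orf.orf
    aa_off = o.protein_sequence.find(novel.sequence)
    if aa_off < 0 or transcript.gene_id not in catalog.genes:
        warnings.warn(f"novel peptide {novel.sequence} footprint unmappable")
        return "other"
    t_start = o.start_nt + 3 * aa_off
    t_end = t_start + 3 * len(novel.sequence)
    exons = transcript.exons
    gene = catalog.genes[transcript.gene_id]
    ref_transcripts = catalog.gene_transcripts(transcript.gene_id)
    footprint = genomic_footprint(t_start, t_end, exons)

    # (1) peptide spans a junction carrying a novel splice site
    spanned = _spanned_junctions(t_start, t_end, transcript)
    for j in spanned:
        if not catalog.is_known_acceptor(transcript.chrom, transcript.strand, j.acceptor):
            return "novel_acceptor"
        if not catalog.is_known_donor(transcript.chrom, transcript.strand, j.donor):
            return "novel_donor"

    # (2) footprint bases inside reference-intronic sequence (footprint minus
    # the union of reference exons)
    ref_exon_ivs = sorted(
        {(e.start, e.end) for rt in ref_transcripts for e in rt.exons}
    )
    intronic = []
    for lo, hi in footprint:
        runs = [(lo, hi)]
        for ilo, ie in ref_exon_ivs:
            runs = [
                piece
                for a, b in runs
                for piece in ((a, min(b, ilo)), (max(a, ie), b))
                if piece[0] < piece[1]
            ]
        intronic.extend(runs)
    if intronic:
        # locate the transcript exon containing the (first) intronic run
        lo, hi = min(intronic)
        exon = next(e for e in exons if e.start <= lo and hi <= e.end)
        overlaps = [
            (ilo, ie)
            for ilo, ie in ref_exon_ivs
            if ilo < exon.end and exon.start < ie
        ]
        if not overlaps:
            return "novel_exon"
        covers_left = any(ilo <= exon.start for ilo, ie in overlaps if ilo < lo)
        covers_right = any(ie >= exon.end for ilo, ie in overlaps if ie > hi)
        if covers_left and covers_right:
            return "intron_retention"
        # one-sided extension: which transcript end of the exon is extended?
        extended_left = not covers_left
        if transcript.strand == "+":
            return "novel_acceptor" if extended_left else "novel_donor"
        return "novel_donor" if extended_left else "novel_acceptor"

    # (3) frame disagreement with every reference coding transcript
    phases = _our_phases(t_start, t_end, o.start_nt, exons)
    coding_refs = catalog.coding_transcripts(transcript.gene_id)
    if phases and coding_refs:
        in_cds = False
        agree = False
        for rt in coding_refs:
            ref_phase = _ref_phase_map(rt)
            common = [g for g in phases if g in ref_phase]
            if common:
                in_cds = True
                if all(ref_phase[g] == phases[g] for g in common):
                    agree = True
                    break
        if in_cds and not agree:
            return "frameshift"
    return "other"


def _spanned_junctions(t_start: int, t_end: int, transcript: LongReadTranscript):
    out = []
    cum = 0
    for e, j in zip(transcript.exons[:-1], transcript.junctions):
        cum += e.length
        if t_start < cum < t_end:
            out.append(j)
    return out


def _our_phases(t_start: int, t_end: int, orf_start: int, exons) -> dict[int, int]:
    """Genomic position -> codon phase of the predicted reading frame."""
    from .orf_calling import transcript_to_genomic

    phases = {}
    for t in range(t_start, t_end):
        g = transcript_to_genomic(t, exons)
        phases[g] = (t - orf_start) % 3
    return phases


def _ref_phase_map(rt) -> dict[int, int]:
    phases = {}
    off = 0
    for e in rt.cds_exons():
        positions = range(e.start, e.end) if e.strand == "+" else range(e.end - 1, e.start - 1, -1)
        for g in positions:
            phases[g] = off % 3
            off += 1
    return phases


def annotate_all_novel_events(
    novel_peptides: list[NovelPeptide],
    db: HybridDatabase,
    transcripts: dict[str, LongReadTranscript],
    best_orfs: dict[str, BestORF],
    catalog: ReferenceCatalog,
) -> None:
    """Attach an event label to each novel peptide in place (first hit entry)."""
    for np_ in novel_peptides:
        entry = db.entry(np_.hit_entries[0])
        rep = entry.representative or entry.member_accessions[0]
        np_.event = annotate_novel_event(
            np_, entry, transcripts[rep], best_orfs[rep], catalog
        )


# ---------------------------------------------------------------------------
# RNA-protein correlation


@dataclass
class CorrelationResult:
    r_squared: float
    slope: float
    intercept: float
    stderr: float
    n: int
    pairs: list[tuple[str, float, float]]  # gene, cpm, psm


def rna_protein_correlation(
    summaries: dict[str, GeneExpressionSummary],
    mappings: list[PeptideMapping],
    pseudocount: float = 1.0,
) -> CorrelationResult:
    """OLS of log10(gene PSM + 1) on log10(gene CPM + 1).

    Gene PSM totals sum the PSM counts of that gene's mapped peptides,
    excluding multi-gene peptides; only genes present in both datasets are
    paired.  Raises for fewer than 3 pairs.
    """
    import math

    psm: dict[str, int] = {}
    for m in mappings:
        if m.is_multi_gene:
            continue
        for g in m.hit_genes:
            psm[g] = psm.get(g, 0) + m.peptide.psm_count
    pairs = [
        (g, summaries[g].total_gene_cpm, float(psm[g]))
        for g in sorted(psm)
        if g in summaries
    ]
    if len(pairs) < 3:
        raise ValueError("insufficient pairs")
    x = [math.log10(c + pseudocount) for _, c, _ in pairs]
    y = [math.log10(p + pseudocount) for _, _, p in pairs]
    if len(set(y)) == 1 or len(set(x)) == 1:
        return CorrelationResult(0.0, 0.0, y[0], 0.0, len(pairs), pairs)
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r_squared=fit.rvalue**2,
        slope=fit.slope,
        intercept=fit.intercept,
        stderr=fit.stderr,
        n=len(pairs),
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# I/O


def load_peptide_table(path) -> list[PeptideIdentification]:
    """Read a peptide TSV (sequence, q_value, psm_count).

    Also accepts MetaMorpheus-style column headers (``Base Sequence``,
    ``QValue``, ``PSM Count``).
    """
    import csv

    aliases = {
        "sequence": "sequence",
        "base sequence": "sequence",
        "q_value": "q_value",
        "qvalue": "q_value",
        "psm_count": "psm_count",
        "psm count": "psm_count",
    }
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = {aliases.get(c.strip().lower()): c for c in reader.fieldnames}
        for row in reader:
            out.append(
                PeptideIdentification(
                    sequence=row[cols["sequence"]].strip(),
                    q_value=float(row[cols["q_value"]]),
                    psm_count=int(row.get(cols.get("psm_count"), 1) or 1),
                )
            )
    return out


def write_gene_evidence_tsv(evidence: dict[str, GeneEvidence], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tscenario\tconfirmed_entries\tnomination\tnominated_entries\n")
        for gene in sorted(evidence):
            ev = evidence[gene]
            fh.write(
                f"{gene}\t{ev.scenario}\t{';'.join(ev.confirmed_entries)}\t"
                f"{ev.nomination}\t{';'.join(ev.nominated_entries)}\n"
            )


def write_novel_peptides_tsv(novel: list[NovelPeptide], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tq_value\tevent\thit_entries\n")
        for np_ in novel:
            fh.write(
                f"{np_.sequence}\t{np_.q_value:.6g}\t{np_.event}\t"
                f"{';'.join(np_.hit_entries)}\n"
            )
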