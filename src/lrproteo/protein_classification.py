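"""SQANTI-Protein classification of predicted proteins (pFSM/pNIC/pNNC).

A predicted protein is compared to the reference protein models of its gene
through three sequence elements: the N-terminus (start codon position), the
CDS-internal splice chain, and the C-terminus (stop codon position).

* **pFSM** — all three elements known and the full CDS structure (start,
  ordered CDS junction chain, stop) equals that of a reference coding
  transcript;
* **pNIC** — every element drawn from the annotation but combined in a new
  way (e.g. a known start joined to another isoform's known C-terminal
  junctions);
* **pNNC** — at least one entirely novel element (unannotated start or stop
  position, or a CDS donor/acceptor absent from the gene's annotated CDS
  site sets);
* **pOTHER** — the transcript itself is OTHER, or the gene has no reference
  coding transcript.

The comparison is CDS-only: UTR-region novelty never affects the protein
class, because the classification is of the protein sequence relative to the
reference proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

from .orf_calling import BestORF, genomic_footprint, transcript_to_genomic
from .reference_model import Junction, ReferenceCatalog
from .transcript_catalog import OTHER, LongReadTranscript, TranscriptClass

PFSM = "pFSM"
PNIC = "pNIC"
PNNC = "pNNC"
POTHER = "pOTHER"

KNOWN = "known"
NOVEL_COMBINATION = "novel-combination"
NOVEL_ELEMENT = "novel-element"


@dataclass
class ProteinClass:
    category: str
    nterm_status: str = KNOWN
    cterm_status: str = KNOWN
    cds_splice_status: str = KNOWN
    matched_reference_protein: str | None = None
    novel_features: list[tuple[str, int]] | None = None
    reason: str | None = None


def cds_junction_chain(
    orf: BestORF, transcript: LongReadTranscript
) -> tuple[Junction, ...]:
    """The transcript's junctions internal to the predicted CDS."""
    o = orf.orf
    chain = transcript.junctions
    if not chain:
        return ()
    out = []
    cum = 0
    for e, j in zip(transcript.exons[:-1], chain):
        cum += e.length
        if o.start_nt < cum <= o.stop_nt - 1:
            out.append(j)
    return tuple(out)


def classify_protein(
    best_orf: BestORF,
    transcript: LongReadTranscript,
    transcript_class: TranscriptClass,
    catalog: ReferenceCatalog,
) -> ProteinClass:
    """Classify one predicted protein against its gene's reference proteins."""
    if transcript_class.category == OTHER:
        return ProteinClass(POTHER, reason="transcript classified OTHER")
    gene = catalog.genes.get(transcript.gene_id)
    coding_refs = (
        catalog.coding_transcripts(transcript.gene_id) if gene is not None else []
    )
    if not coding_refs:
        return ProteinClass(POTHER, reason="gene has no reference coding transcript")

    o = best_orf.orf
    start_g = transcript_to_genomic(o.start_nt, transcript.exons)
    stop_g = None
    if o.has_stop_codon:
        stop_g = transcript_to_genomic(o.stop_nt - 1, transcript.exons)
    chain = cds_junction_chain(best_orf, transcript)

    novel_features: list[tuple[str, int]] = []
    nterm = KNOWN if start_g in gene.start_codon_positions else NOVEL_ELEMENT
    if nterm is NOVEL_ELEMENT:
        novel_features.append(("start", start_g))
    cterm = (
        KNOWN
        if stop_g is not None and stop_g in gene.stop_codon_positions
        else NOVEL_ELEMENT
    )
    if cterm is NOVEL_ELEMENT:
        novel_features.append(("stop", -1 if stop_g is None else stop_g))

    splice = KNOWN
    for j in chain:
        if j.donor not in gene.cds_donor_sites:
            splice = NOVEL_ELEMENT
            novel_features.append(("cds_donor", j.donor))
        if j.acceptor not in gene.cds_acceptor_sites:
            splice = NOVEL_ELEMENT
            novel_features.append(("cds_acceptor", j.acceptor))

    matched = None
    if nterm is KNOWN and cterm is KNOWN and splice is KNOWN:
        for rt in coding_refs:
            if (
                rt.start_codon_pos == start_g
                and rt.stop_codon_pos == stop_g
                and rt.cds_junctions() == chain
            ):
                matched = rt.protein_id or rt.transcript_id
                break
        if matched is None and splice is KNOWN:
            # sites annotated but chain combination unseen among references
            if chain not in {rt.cds_junctions() for rt in coding_refs}:
                splice = NOVEL_COMBINATION

    if NOVEL_ELEMENT in (nterm, cterm, splice):
        category = PNNC
    elif matched is not None:
        category = PFSM
    else:
        category = PNIC
    return ProteinClass(
        category=category,
        nterm_status=nterm,
        cterm_status=cterm,
        cds_splice_status=splice,
        matched_reference_protein=matched,
        novel_features=novel_features or None,
    )


def classify_all_proteins(
    best_orfs: dict[str, BestORF],
    transcripts: list[LongReadTranscript],
    transcript_classes: dict[str, TranscriptClass],
    catalog: ReferenceCatalog,
) -> dict[str, ProteinClass]:
    by_acc = {t.pb_accession: t for t in transcripts}
    out = {}
    for acc, b in best_orfs.items():
        out[acc] = classify_protein(
            b, by_acc[acc], transcript_classes[acc], catalog
        )
    return out


def write_protein_classification_tsv(
    classes: dict[str, ProteinClass], gene_of: dict[str, str], path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pb_accession\tgene\tcategory\tnterm\tcterm\tcds_splice\t"
            "matched_reference_protein\n"
        )
        for acc in sorted(classes):
            c = classes[acc]
            fh.write(
                f"{acc}\t{gene_of.get(acc, '')}\t{c.category}\t{c.nterm_status}\t"
                f"{c.cterm_status}\t{c.cds_splice_status}\t"
                f"{c.matched_reference_protein or ''}\n"
            )
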