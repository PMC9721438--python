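"""ORF enumeration and best-ORF selection on long-read transcripts.

Candidate open reading frames are AUG-initiated, sense-strand, and at least
50 nt long counting start through stop codon inclusive; a candidate without
an in-frame stop runs to the transcript end and is flagged (such truncation
suspects are removed later, at database filtering, so the removal count is
observable).  Among a transcript's candidates, the most biologically
plausible ORF is selected by a strict lexicographic rule:

1. start codon at an annotated reference start position;
2. fewest upstream AUGs skipped to reach the start;
3. highest coding-potential score;
4. longest ORF;
5. smallest start position.

The coding-potential scorer is a deterministic logistic stand-in over ORF
coverage, capped ORF length, and a Fickett-style codon position-bias score;
an external score table keyed by (transcript, start) can be dropped in via
``scores`` to replace it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .reference_model import STOP_CODONS, Exon, translate_orf

MIN_ORF_NT = 50

# Logistic stand-in coefficients: intercept, ORF coverage, capped length
# (codons/100, capped at 1), composition (Fickett-style position bias).
CODING_POTENTIAL_COEFFS = (-4.0, 4.0, 3.0, 2.0)


@dataclass
class CandidateORF:
    pb_accession: str
    start_nt: int  # transcript coordinate of the A of AUG, 0-based
    stop_nt: int  # first base after the stop codon, or transcript end
    has_stop_codon: bool
    protein_sequence: str
    coding_potential: float = 0.0
    start_matches_reference: bool = False
    upstream_augs_skipped: int = 0
    stop_genomic: int | None = None
    junctions_after_stop: int | None = None

    @property
    def orf_nt_length(self) -> int:
        return self.stop_nt - self.start_nt


@dataclass
class BestORF:
    orf: CandidateORF
    selection_tier: str


def enumerate_candidate_orfs(
    pb_accession: str, spliced_sequence: str, min_nt: int = MIN_ORF_NT
) -> list[CandidateORF]:
    """All AUG-initiated sense-strand candidates of length >= min_nt.

    Each candidate runs from an AUG to the first in-frame stop codon
    (inclusive) or, lacking one, to the transcript end.  Nested ORFs sharing
    a stop but starting at different AUGs are distinct candidates.  A codon
    containing N is untranslatable and truncates the candidate before it
    (treated as stop-less).
    """
    seq = spliced_sequence.upper()
    n = len(seq)
    out = []
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        stop_nt = None
        has_stop = False
        for i in range(start, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                stop_nt = i
                break
            if codon in STOP_CODONS:
                stop_nt = i + 3
                has_stop = True
                break
        if stop_nt is None:
            stop_nt = n
        if stop_nt - start < min_nt:
            continue
        out.append(
            CandidateORF(
                pb_accession=pb_accession,
                start_nt=start,
                stop_nt=stop_nt,
                has_stop_codon=has_stop,
                protein_sequence=translate_orf(seq[start:stop_nt]),
                upstream_augs_skipped=seq.count("ATG", 0, start),
            )
        )
    return out


def fickett_position_bias(orf_seq: str) -> float:
    """A Fickett-style codon position-bias score in [0, 1).

    For each base, counts its occurrences at the three codon positions and
    measures the asymmetry (max - min) / (total + 1); the score is the mean
    over the four bases.  Coding sequence tends to use codon positions
    asymmetrically; uniform usage scores near 0.
    """
    counts = {b: [0, 0, 0] for b in "ACGT"}
    for i, b in enumerate(orf_seq.upper()):
        if b in counts:
            counts[b][i % 3] += 1
    scores = []
    for b in "ACGT":
        c = counts[b]
        scores.append((max(c) - min(c)) / (sum(c) + 1))
    return sum(scores) / 4.0


def score_coding_potential(orf: CandidateORF, spliced_sequence: str) -> float:
    """Deterministic logistic coding-potential score in [0, 1].

    sigmoid(b0 + b1 * coverage + b2 * min(codons/100, 1) + b3 * bias) with
    the coefficients in :data:`CODING_POTENTIAL_COEFFS`; coverage is
    orf_nt_length / transcript length and bias the Fickett-style position
    score of the ORF sequence.  Monotone non-decreasing in ORF coverage for
    fixed composition.
    """
    b0, b1, b2, b3 = CODING_POTENTIAL_COEFFS
    n = len(spliced_sequence)
    coverage = orf.orf_nt_length / n if n else 0.0
    codons = min((orf.orf_nt_length // 3) / 100.0, 1.0)
    bias = fickett_position_bias(spliced_sequence[orf.start_nt : orf.stop_nt])
    return _sigmoid(b0 + b1 * coverage + b2 * codons + b3 * bias)


def score_candidates(
    candidates: list[CandidateORF],
    spliced_sequence: str,
    scores: dict[tuple[str, int], float] | None = None,
) -> None:
    """Attach coding-potential scores to candidates in place.

    ``scores`` maps (pb_accession, start_nt) to an externally computed score
    (e.g. CPAT output); candidates absent from the table fall back to the
    logistic stand-in.
    """
    for c in candidates:
        if scores is not None and (c.pb_accession, c.start_nt) in scores:
            c.coding_potential = scores[(c.pb_accession, c.start_nt)]
        else:
            c.coding_potential = score_coding_potential(c, spliced_sequence)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def mark_reference_starts(
    candidates: list[CandidateORF],
    exons: list[Exon],
    annotated_starts: set[int],
) -> None:
    """Flag candidates whose start codon genomic position is annotated."""
    for c in candidates:
        g = transcript_to_genomic(c.start_nt, exons)
        c.start_matches_reference = g in annotated_starts


_TIERS = (
    ("reference-start", lambda c: not c.start_matches_reference),
    ("fewest-skipped", lambda c: c.upstream_augs_skipped),
    ("coding-potential", lambda c: -c.coding_potential),
    ("length", lambda c: -c.orf_nt_length),
    ("position", lambda c: c.start_nt),
)


def select_best_orf(candidates: list[CandidateORF]) -> BestORF | None:
    """Select the most plausible candidate by the lexicographic rule.

    Returns None for an empty candidate list (transcript marked non-coding
    downstream).  The result is a total order: permuting input order never
    changes the selection.  ``selection_tier`` names the first criterion
    that separated the winner from the runner-up ("only" for a single
    candidate).
    """
    if not candidates:
        return None

    def key(c):
        return tuple(f(c) for _, f in _TIERS)

    ranked = sorted(candidates, key=key)
    best = ranked[0]
    if len(ranked) == 1:
        return BestORF(best, "only")
    second = ranked[1]
    for name, f in _TIERS:
        if f(best) != f(second):
            return BestORF(best, name)
    return BestORF(best, "position")


def transcript_to_genomic(pos: int, exons: list[Exon]) -> int:
    """Map a transcript coordinate to a genomic position via the exon chain.

    ``exons`` are in 5'->3' transcript order; on '-' strand transcript
    coordinates run right-to-left along the genome.
    """
    if pos < 0:
        raise ValueError("negative transcript coordinate")
    off = pos
    for e in exons:
        if off < e.length:
            if e.strand == "+":
                return e.start + off
            return e.end - 1 - off
        off -= e.length
    raise ValueError(f"transcript coordinate {pos} beyond spliced length")


def genomic_footprint(start: int, end: int, exons: list[Exon]) -> list[tuple[int, int]]:
    """Genomic half-open intervals covered by transcript range [start, end)."""
    out = []
    off = 0
    for e in exons:
        lo = max(start, off)
        hi = min(end, off + e.length)
        if lo < hi:
            if e.strand == "+":
                out.append((e.start + (lo - off), e.start + (hi - off)))
            else:
                out.append((e.end - (hi - off), e.end - (lo - off)))
        off += e.length
    return out


def locate_stop_and_junctions(
    orf: CandidateORF, exons: list[Exon]
) -> tuple[int | None, int | None]:
    """Genomic position of the stop codon's last base, and the count of
    junctions strictly 3' (transcript orientation) of it.

    For a stop-less ORF both values are None (the entry is flagged and
    removed by the truncation filter anyway).
    """
    if not orf.has_stop_codon:
        orf.stop_genomic = None
        orf.junctions_after_stop = None
        return None, None
    last_base_t = orf.stop_nt - 1
    stop_g = transcript_to_genomic(last_base_t, exons)
    # junction i sits after cumulative exon length of exons[:i+1]
    cum = 0
    after = 0
    for e in exons[:-1]:
        cum += e.length
        if cum > last_base_t:
            after += 1
    orf.stop_genomic = stop_g
    orf.junctions_after_stop = after
    return stop_g, after


def call_best_orfs(
    transcripts,
    catalog,
    min_nt: int = MIN_ORF_NT,
    scores: dict[tuple[str, int], float] | None = None,
) -> dict[str, BestORF]:
    """Enumerate, score, and select the best ORF for each transcript.

    Transcripts without sequence or without any candidate are omitted from
    the result (non-coding).
    """
    best: dict[str, BestORF] = {}
    for t in transcripts:
        if not t.spliced_sequence:
            continue
        cands = enumerate_candidate_orfs(t.pb_accession, t.spliced_sequence, min_nt)
        if not cands:
            continue
        score_candidates(cands, t.spliced_sequence, scores)
        starts = set()
        if t.gene_id is not None and t.gene_id in catalog.genes:
            starts = catalog.genes[t.gene_id].start_codon_positions
        mark_reference_starts(cands, t.exons, starts)
        b = select_best_orf(cands)
        locate_stop_and_junctions(b.orf, t.exons)
        best[t.pb_accession] = b
    return best


def write_orf_table(best_orfs: dict[str, BestORF], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pb_accession\tstart_nt\tstop_nt\thas_stop\tcoding_potential\t"
            "tier\tjunctions_after_stop\tprotein_length\n"
        )
        for acc in sorted(best_orfs):
            b = best_orfs[acc]
            o = b.orf
            fh.write(
                f"{acc}\t{o.start_nt}\t{o.stop_nt}\t{int(o.has_stop_codon)}\t"
                f"{o.coding_potential:.4f}\t{b.selection_tier}\t"
                f"{'' if o.junctions_after_stop is None else o.junctions_after_stop}\t"
                f"{len(o.protein_sequence)}\n"
            )
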