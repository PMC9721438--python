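"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emits every file the pipeline consumes — toy genome FASTA,
reference annotation GTF with APPRIS table and reference/contaminant/UniProt-
style protein FASTAs, long-read transcript GTF with full-length counts, and
a peptide identification table — together with the ground truth of every
label the analysis infers: transcript novelty class, protein class, NMD and
truncation flags, hybrid-database gene source, per-gene evidence scenario
and nomination, and injected novel peptides with their event type.

Construction guarantees, not post-hoc checks, make the truth labels exact:

* Transcribed gene bodies are built over a T-free alphabet {A, C, G}, so no
  stop codon or AUG can occur anywhere in any reading frame except where
  planted.  Each transcript therefore carries exactly one candidate ORF,
  from the planted start AUG.
* Exon and intron lengths are multiples of 3 and the single start codon
  sits a fixed 9-nt 5' UTR into exon 1, so every frame-preserving edit
  (exon skip, 27-nt acceptor/donor shift, intron retention, novel exon)
  keeps the downstream frame and the terminal stop codon.
* Frame-shifting edits (28-nt shifts) divert translation onto auxiliary
  TAA codons planted out-of-frame in the last exon (late shifts -> retained
  frameshift isoforms) or in exon 2 (early shifts -> NMD suspects with
  > 2 junctions after the stop).  Out-of-frame TAA planting is invisible to
  the in-frame reading (no codon window over a TAA planted at phase 1 or 2
  can form a stop or an AUG).
* Novelty events are applied at sites far (>= 27 nt) from any annotated
  boundary, so planted classes never straddle a classification boundary.

All randomness flows from one seeded NumPy generator; a fixed seed yields
byte-identical output bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .database_builder import format_pacbio_label
from .peptide_evidence import digest

SPACER_NT = 500

FSM = "FSM"
NIC = "NIC"
NNC = "NNC"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the defaults are the study conditions.

    Rates are per-gene Bernoulli probabilities; lengths in nucleotides.
    ``novelty_rates`` controls the per-event chance that a gene carries a
    novel isoform of that type; acceptor/donor shifts come in frame-
    preserving (27 nt) and frame-shifting (28 nt) variants so frameshift
    annotation has positive truth cases.
    """

    seed: int = 0
    n_genes: int = 30
    exon_count_range: tuple[int, int] = (5, 7)
    exon_length_range: tuple[int, int] = (240, 420)  # rounded to multiples of 3
    intron_length_range: tuple[int, int] = (300, 600)
    long_gene_exon_count: int = 8
    long_gene_exon_length_range: tuple[int, int] = (600, 750)
    utr5_nt: int = 9
    utr3_nt: int = 15
    minus_strand_fraction: float = 0.4
    p_second_reference_isoform: float = 0.8
    p_duplicate_protein_reference: float = 0.2
    p_gene_absent: float = 0.08
    p_gene_long: float = 0.08  # mean annotated length above the 4 kbp window
    p_gene_low_abundance: float = 0.08  # detected but < 3 CPM aggregate
    novelty_rates: dict = field(
        default_factory=lambda: {
            "exon_skip": 0.35,
            "novel_acceptor_shift": 0.30,
            "novel_donor_shift": 0.25,
            "intron_retention": 0.25,
            "novel_exon": 0.25,
            "novel_combination": 0.15,
        }
    )
    frameshift_rate: float = 0.20
    nmd_rate: float = 0.15
    truncation_rate: float = 0.15
    inframe_shift_nt: int = 27
    frameshift_shift_nt: int = 28
    novel_exon_nt: int = 60
    abundance_log_mean: float = 2.0  # natural-log CPM
    abundance_log_sd: float = 1.3
    library_size: int = 1_000_000
    p_major_not_principal: float = 0.30
    p_gene_evidenced: float = 0.90
    scenario_weights: dict = field(
        default_factory=lambda: {
            "SHARED_ONLY": 0.40,
            "ONE_CONFIRMED": 0.35,
            "MULTI_CONFIRMED": 0.25,
        }
    )
    peptide_q_true: tuple[float, float] = (2e-3, 9e-3)
    peptide_q_novel: tuple[float, float] = (1e-5, 8e-4)
    peptide_q_false: tuple[float, float] = (0.02, 0.30)
    n_false_peptides: int = 8
    n_unmapped_peptides: int = 5
    psm_log_slope: float = 0.8
    psm_log_intercept: float = 0.3
    psm_log_noise_sd: float = 0.25
    n_contaminants: int = 5

    def validate(self) -> None:
        for k, v in self.novelty_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"novelty rate {k}={v} outside [0, 1]")
        if self.exon_count_range[0] < 5:
            raise ValueError("need >= 5 exons for NMD truth cases")
        if self.exon_length_range[0] < 90:
            raise ValueError("exons shorter than 90 nt cannot host the plants")
        if self.intron_length_range[0] < 3 * self.novel_exon_nt:
            raise ValueError("introns too short for novel-exon insertion")

    @classmethod
    def smoke(cls, seed: int = 0) -> "SimulationConfig":
        """Small preset (<= 50 genes) that runs the pipeline in seconds."""
        return cls(seed=seed, n_genes=30)


# ---------------------------------------------------------------------------
# Internal blueprints


@dataclass
class VariantPlan:
    """One planned transcript: exon intervals in gene-body coordinates."""

    pb_accession: str
    gene: "GenePlan"
    exons_body: list[tuple[int, int]]
    edit: str  # FSM_full / FSM_skip / exon_skip / ... / truncation / nmd
    true_class: str
    true_protein_class: str
    fsm_match: str | None = None
    novel_body_interval: tuple[int, int] | None = None
    event: str | None = None  # planted event label for novel peptides
    cpm_target: float = 0.0
    fl_count: int = 0
    cpm: float = 0.0
    # filled during finalization
    protein: str = ""
    has_stop: bool = True
    junctions_after_stop: int = 0
    removal: str | None = None  # truncation / NMD / None

    def spliced(self) -> str:
        return "".join(self.gene.body[s:e] for s, e in self.exons_body)

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons_body)


@dataclass
class ReferencePlan:
    transcript_id: str
    protein_id: str
    exons_body: list[tuple[int, int]]
    is_principal: bool = False
    protein: str = ""


@dataclass
class GenePlan:
    index: int
    gene_id: str
    strand: str
    body: str = ""
    exons_body: list[tuple[int, int]] = field(default_factory=list)
    genome_start: int = 0
    references: list[ReferencePlan] = field(default_factory=list)
    variants: list[VariantPlan] = field(default_factory=list)
    absent: bool = False
    long_gene: bool = False
    low_abundance: bool = False
    cds_start_spliced: int = 0  # on the full exon chain
    stop_off_spliced: int = 0  # first base of terminal stop, full chain

    @property
    def body_len(self) -> int:
        return len(self.body)

    def body_to_genomic(self, b: int) -> int:
        """Map a gene-body coordinate (transcript orientation) to genome."""
        if self.strand == "+":
            return self.genome_start + b
        return self.genome_start + (self.body_len - b)

    def body_interval_to_genomic(self, s: int, e: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.genome_start + s, self.genome_start + e
        return self.genome_start + self.body_len - e, self.genome_start + self.body_len - s


# ---------------------------------------------------------------------------
# Sequence construction helpers


def _tfree(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACG"))[rng.integers(0, 3, n)])


def _mult3(rng: np.random.Generator, lo: int, hi: int) -> int:
    return 3 * int(rng.integers(lo // 3, hi // 3 + 1))


def _translate(nt: str) -> str:
    nt = nt[: len(nt) // 3 * 3]
    return str(Seq(nt).translate(to_stop=True))


def _first_inframe_stop(seq: str, start: int) -> int | None:
    """Spliced offset of the first in-frame stop codon at/after ``start``."""
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in ("TAA", "TAG", "TGA"):
            return i
    return None


def _build_gene(cfg: SimulationConfig, rng: np.random.Generator, idx: int) -> GenePlan:
    gene = GenePlan(
        index=idx,
        gene_id=f"SYNG{idx + 1:04d}",
        strand="-" if rng.random() < cfg.minus_strand_fraction else "+",
    )
    gene.long_gene = rng.random() < cfg.p_gene_long
    if gene.long_gene:
        n_ex = cfg.long_gene_exon_count
        elo, ehi = cfg.long_gene_exon_length_range
    else:
        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        elo, ehi = cfg.exon_length_range
    exon_lens = [_mult3(rng, elo, ehi) for _ in range(n_ex)]
    intron_lens = [
        _mult3(rng, *cfg.intron_length_range) for _ in range(n_ex - 1)
    ]
    # gene body in transcript orientation: exon/intron alternation, T-free
    parts, pos, exons = [], 0, []
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        parts.append(_tfree(rng, el))
        pos += el
        if i < n_ex - 1:
            parts.append(_tfree(rng, intron_lens[i]))
            pos += intron_lens[i]
    body = list("".join(parts))
    gene.exons_body = exons

    # spliced-offset plants on the full exon chain
    L = sum(exon_lens)
    u5 = cfg.utr5_nt
    stop_off = L - cfg.utr3_nt - 3
    gene.cds_start_spliced = u5
    gene.stop_off_spliced = stop_off

    def splice_to_body(s: int) -> int:
        off = s
        for bs, be in exons:
            if off < be - bs:
                return bs + off
            off -= be - bs
        raise ValueError("spliced offset beyond transcript")

    def plant(spliced_pos: int, codon: str) -> None:
        for k, ch in enumerate(codon):
            body[splice_to_body(spliced_pos + k)] = ch

    plant(u5, "ATG")
    plant(stop_off, "TAA")
    # auxiliary out-of-frame stops: late (last exon) and early (exon 2);
    # phase is relative to the CDS codon grid ((pos - u5) % 3)
    plant(stop_off - 41, "TAA")  # phase 1
    plant(stop_off - 37, "TAA")  # phase 2
    early = exon_lens[0] + 31 - ((exon_lens[0] + 31 - u5) % 3) + 1  # phase 1
    plant(early, "TAA")
    plant(early + 4, "TAA")  # phase 2
    gene.body = "".join(body)
    return gene


def _variant_exons(gene: GenePlan, edit: str, cfg: SimulationConfig):
    """Exon list (body coords), novel body interval, and labels for an edit."""
    ex = list(gene.exons_body)
    n = len(ex)
    if edit == "exon_skip":
        drop = 1 if n == 5 else 3
        return [e for i, e in enumerate(ex) if i != drop], None
    if edit == "novel_combination":
        return [e for i, e in enumerate(ex) if i not in (1, 3)], None
    if edit == "novel_acceptor_shift":
        s, e = ex[2]
        ex[2] = (s - cfg.inframe_shift_nt, e)
        return ex, (s - cfg.inframe_shift_nt, s)
    if edit == "novel_donor_shift":
        s, e = ex[2]
        ex[2] = (s, e + cfg.inframe_shift_nt)
        return ex, (e, e + cfg.inframe_shift_nt)
    if edit == "intron_retention":
        merged = (ex[2][0], ex[3][1])
        out = ex[:2] + [merged] + ex[4:]
        return out, (ex[2][1], ex[3][0])
    if edit == "novel_exon":
        ilo, ihi = ex[1][1], ex[2][0]
        ns = ilo + 120
        out = ex[:2] + [(ns, ns + cfg.novel_exon_nt)] + ex[2:]
        return out, (ns, ns + cfg.novel_exon_nt)
    if edit == "frameshift":
        s, e = ex[-1]
        ex[-1] = (s - cfg.frameshift_shift_nt, e)
        return ex, (s, e)  # novel frame region: the original last exon
    if edit == "nmd":
        s, e = ex[1]
        ex[1] = (s - cfg.frameshift_shift_nt, e)
        return ex, None
    if edit == "truncation":
        return ex[:-2], None
    raise ValueError(edit)


_EDIT_CLASSES = {
    "exon_skip": (NIC, "pNIC"),
    "novel_combination": (NIC, "pNIC"),
    "intron_retention": (NIC, "pNIC"),
    "truncation": (NIC, "pNNC"),
    "novel_acceptor_shift": (NNC, "pNNC"),
    "novel_donor_shift": (NNC, "pNNC"),
    "novel_exon": (NNC, "pNNC"),
    "frameshift": (NNC, "pNNC"),
    "nmd": (NNC, "pNNC"),
}

_EDIT_EVENTS = {
    "novel_acceptor_shift": "novel_acceptor",
    "novel_donor_shift": "novel_donor",
    "intron_retention": "intron_retention",
    "novel_exon": "novel_exon",
    "frameshift": "frameshift",
}


def _finalize_variant(v: VariantPlan, cfg: SimulationConfig) -> None:
    """Derive protein, stop location, and filter truth from the construction."""
    seq = v.spliced()
    start = v.gene.cds_start_spliced  # exon 1 is never edited
    stop = _first_inframe_stop(seq, start)
    if stop is None:
        v.has_stop = False
        v.protein = _translate(seq[start:])
        v.junctions_after_stop = -1
        v.removal = "truncation"
        return
    v.has_stop = True
    v.protein = _translate(seq[start:])
    # junctions strictly 3' of the stop codon's last base
    last = stop + 2
    cum, after = 0, 0
    for s, e in v.exons_body[:-1]:
        cum += e - s
        if cum > last:
            after += 1
    v.junctions_after_stop = after
    if v.true_protein_class == "pNNC" and after > 2:
        v.removal = "NMD"


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass
class GroundTruth:
    transcript_class: dict[str, str] = field(default_factory=dict)
    protein_class: dict[str, str] = field(default_factory=dict)
    removal: dict[str, str | None] = field(default_factory=dict)
    junctions_after_stop: dict[str, int] = field(default_factory=dict)
    fsm_match: dict[str, str] = field(default_factory=dict)
    cpm: dict[str, float] = field(default_factory=dict)
    gene_source: dict[str, str] = field(default_factory=dict)
    gene_scenario: dict[str, str] = field(default_factory=dict)
    gene_nomination: dict[str, str] = field(default_factory=dict)
    nominated_entries: dict[str, list[str]] = field(default_factory=dict)
    novel_peptides: dict[str, tuple[str, str]] = field(default_factory=dict)
    major_not_principal_fraction: float = 0.0
    multi_isoform_genes: int = 0
    gene_cpm_total: dict[str, float] = field(default_factory=dict)
    gene_psm_total: dict[str, int] = field(default_factory=dict)
    psm_model: dict = field(default_factory=dict)
    entry_labels: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    genes: list[GenePlan]
    chrom: str
    genome_seq: str
    truth: GroundTruth
    peptides: list[tuple[str, float, int]]  # sequence, q_value, psm_count
    contaminants: list[tuple[str, str]]
    reference_entries: dict[str, list[tuple[str, str]]]  # gene -> (acc, seq)


# ---------------------------------------------------------------------------
# Stage 1: reference + genome


def generate_reference(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Build gene structures, reference isoforms, and the toy genome."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    genes = []
    genome_parts = []
    pos = 0
    for idx in range(cfg.n_genes):
        spacer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, SPACER_NT)])
        genome_parts.append(spacer)
        pos += SPACER_NT
        g = _build_gene(cfg, rng, idx)
        g.genome_start = pos
        seg = g.body if g.strand == "+" else str(Seq(g.body).reverse_complement())
        genome_parts.append(seg)
        pos += g.body_len

        refs = [
            ReferencePlan(
                transcript_id=f"{g.gene_id}-201",
                protein_id=f"{g.gene_id}-P201",
                exons_body=list(g.exons_body),
                is_principal=True,
            )
        ]
        if rng.random() < cfg.p_second_reference_isoform:
            refs.append(
                ReferencePlan(
                    transcript_id=f"{g.gene_id}-202",
                    protein_id=f"{g.gene_id}-P202",
                    exons_body=[e for i, e in enumerate(g.exons_body) if i != 2],
                )
            )
        if rng.random() < cfg.p_duplicate_protein_reference:
            ex = list(g.exons_body)
            s, e = ex[-1]
            ex[-1] = (s, e - 9)  # trim 3' UTR only: same junctions, same protein
            refs.append(
                ReferencePlan(
                    transcript_id=f"{g.gene_id}-203",
                    protein_id=f"{g.gene_id}-P203",
                    exons_body=ex,
                )
            )
        for r in refs:
            spliced = "".join(g.body[s:e] for s, e in r.exons_body)
            r.protein = _translate(spliced[g.cds_start_spliced :])
        g.references = refs
        genes.append(g)
    genome_parts.append("".join(np.array(list("ACGT"))[rng.integers(0, 4, SPACER_NT)]))
    return genes, "".join(genome_parts)


# ---------------------------------------------------------------------------
# Stage 2: long-read transcript models with planted novelty


def simulate_long_reads(
    cfg: SimulationConfig, genes: list[GenePlan], rng: np.random.Generator
) -> None:
    """Plan sample transcripts, plant novelty events, and draw abundances."""
    for g in genes:
        g.absent = rng.random() < cfg.p_gene_absent
        if g.absent:
            continue
        g.low_abundance = (not g.long_gene) and rng.random() < cfg.p_gene_low_abundance
        counter = 0

        def acc() -> str:
            nonlocal counter
            counter += 1
            return f"PB.{g.index + 1}.{counter}"

        variants = []
        # FSM of the principal isoform is always sampled
        variants.append(
            VariantPlan(
                pb_accession=acc(),
                gene=g,
                exons_body=list(g.references[0].exons_body),
                edit="FSM_full",
                true_class=FSM,
                true_protein_class="pFSM",
                fsm_match=g.references[0].transcript_id,
            )
        )
        second = next(
            (r for r in g.references if r.transcript_id.endswith("-202")), None
        )
        if second is not None and rng.random() < 0.8:
            variants.append(
                VariantPlan(
                    pb_accession=acc(),
                    gene=g,
                    exons_body=list(second.exons_body),
                    edit="FSM_skip",
                    true_class=FSM,
                    true_protein_class="pFSM",
                    fsm_match=second.transcript_id,
                )
            )
        dup = next((r for r in g.references if r.transcript_id.endswith("-203")), None)
        if dup is not None and rng.random() < 0.7:
            # same junction chain and protein as the principal: classified as
            # an FSM of the first chain-identical reference and later grouped
            # with the principal's FSM copy by identical ORF sequence
            variants.append(
                VariantPlan(
                    pb_accession=acc(),
                    gene=g,
                    exons_body=list(dup.exons_body),
                    edit="FSM_dup",
                    true_class=FSM,
                    true_protein_class="pFSM",
                    fsm_match=g.references[0].transcript_id,
                )
            )
        if not g.low_abundance:
            edits = [k for k, p in cfg.novelty_rates.items() if rng.random() < p]
            if rng.random() < cfg.frameshift_rate:
                edits.append("frameshift")
            if rng.random() < cfg.nmd_rate:
                edits.append("nmd")
            if rng.random() < cfg.truncation_rate:
                edits.append("truncation")
            for edit in edits:
                exons, novel_iv = _variant_exons(g, edit, cfg)
                tclass, pclass = _EDIT_CLASSES[edit]
                variants.append(
                    VariantPlan(
                        pb_accession=acc(),
                        gene=g,
                        exons_body=exons,
                        edit=edit,
                        true_class=tclass,
                        true_protein_class=pclass,
                        novel_body_interval=novel_iv,
                        event=_EDIT_EVENTS.get(edit),
                    )
                )
        for v in variants:
            _finalize_variant(v, cfg)

        # abundances: log-normal CPM targets; low-abundance genes stay < 3 CPM
        for v in variants:
            if g.low_abundance:
                v.cpm_target = float(rng.uniform(1.2, 1.4))
            else:
                v.cpm_target = float(
                    np.clip(
                        rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd),
                        1.5,
                        3000.0,
                    )
                )
        if len(variants) >= 2 and not g.low_abundance:
            top = max(v.cpm_target for v in variants)
            principal_tid = g.references[0].transcript_id
            others = [v for v in variants if v.fsm_match != principal_tid]
            if others and rng.random() < cfg.p_major_not_principal:
                boost = others[int(rng.integers(len(others)))]
            else:
                boost = variants[0]
            boost.cpm_target = top * 1.5 + 10.0
        g.variants = variants

    # integer counts scaled to the library size; CPM recomputed from counts
    all_vars = [v for g in genes for v in g.variants]
    total_target = sum(v.cpm_target for v in all_vars)
    scale = cfg.library_size / total_target
    for v in all_vars:
        v.fl_count = max(2, round(v.cpm_target * scale))
    total = sum(v.fl_count for v in all_vars)
    for v in all_vars:
        v.cpm = v.fl_count / total * 1e6


# ---------------------------------------------------------------------------
# Stage 3: hybrid-database replica (construction-side) + peptide emissions


def _grouped_sample_entries(g: GenePlan) -> list[dict]:
    """Replicate grouping of retained sample ORFs by protein sequence."""
    retained = [v for v in g.variants if v.removal is None]
    groups: dict[str, list[VariantPlan]] = {}
    for v in retained:
        groups.setdefault(v.protein, []).append(v)
    out = []
    for seq, members in sorted(groups.items(), key=lambda kv: kv[1][0].pb_accession):
        rep = max(members, key=lambda v: (v.cpm, [-int(x) for x in v.pb_accession.split(".")[1:]]))
        cpm_sum = sum(m.cpm for m in sorted(members, key=lambda m: m.pb_accession))
        out.append(
            {
                "label": format_pacbio_label(
                    g.gene_id, rep.pb_accession, rep.true_protein_class, cpm_sum
                ),
                "sequence": seq,
                "cpm_sum": cpm_sum,
                "rep": rep,
                "members": members,
            }
        )
    return out


def _reference_entries(g: GenePlan) -> list[tuple[str, str]]:
    """Grouped reference proteins: (accession, sequence) per distinct protein."""
    groups: dict[str, list[str]] = {}
    for r in g.references:
        groups.setdefault(r.protein, []).append(r.protein_id)
    return sorted((min(accs), seq) for seq, accs in groups.items())


def _novel_spliced_interval(v: VariantPlan) -> tuple[int, int] | None:
    """Map the variant's novel body interval to its spliced coordinates."""
    if v.novel_body_interval is None:
        return None
    lo, hi = v.novel_body_interval
    off = 0
    out = None
    for s, e in v.exons_body:
        a, b = max(lo, s), min(hi, e)
        if a < b:
            lo_s = off + (a - s)
            if out is None:
                out = [lo_s, lo_s + (b - a)]
            else:
                out[1] = lo_s + (b - a)
        off += e - s
    return None if out is None else (out[0], out[1])


def simulate_peptide_identifications(
    cfg: SimulationConfig, genes: list[GenePlan], rng: np.random.Generator
) -> tuple[GroundTruth, list, list, dict]:
    """Emit the peptide table and derive all gene/peptide-level truth."""
    truth = GroundTruth()
    for g in genes:
        for v in g.variants:
            truth.transcript_class[v.pb_accession] = v.true_class
            truth.protein_class[v.pb_accession] = v.true_protein_class
            truth.removal[v.pb_accession] = v.removal
            truth.junctions_after_stop[v.pb_accession] = v.junctions_after_stop
            truth.cpm[v.pb_accession] = v.cpm
            if v.fsm_match:
                truth.fsm_match[v.pb_accession] = v.fsm_match

    # major/principal concordance over multi-isoform genes
    multi = [g for g in genes if len(g.variants) >= 2]
    mismatch = 0
    for g in multi:
        major = max(
            g.variants,
            key=lambda v: (v.cpm, v.fl_count, [-int(x) for x in v.pb_accession.split(".")[1:]]),
        )
        if major.fsm_match != g.references[0].transcript_id:
            mismatch += 1
    truth.multi_isoform_genes = len(multi)
    truth.major_not_principal_fraction = mismatch / len(multi) if multi else 0.0

    # hybrid gene sources (the length window is [1000, 4000] by construction)
    sample_entries: dict[str, list[dict]] = {}
    reference_entries: dict[str, list[tuple[str, str]]] = {}
    for g in genes:
        reference_entries[g.gene_id] = _reference_entries(g)
        mean_len = sum(
            sum(e - s for s, e in r.exons_body) for r in g.references
        ) / len(g.references)
        total_cpm = sum(v.cpm for v in g.variants)
        hi_conf = (
            not g.absent and total_cpm >= 3.0 and 1000 <= mean_len <= 4000
        )
        truth.gene_source[g.gene_id] = "PACBIO" if hi_conf else "GENCODE"
        truth.gene_cpm_total[g.gene_id] = total_cpm
        if hi_conf:
            sample_entries[g.gene_id] = _grouped_sample_entries(g)

    # global peptide -> entry-label index over the replica database
    digests: dict[str, set[str]] = {}
    entry_gene: dict[str, str] = {}
    entry_seq: dict[str, str] = {}
    for g in genes:
        if truth.gene_source[g.gene_id] == "PACBIO":
            entries = [(e["label"], e["sequence"]) for e in sample_entries[g.gene_id]]
        else:
            entries = reference_entries[g.gene_id]
        truth.entry_labels[g.gene_id] = [lab for lab, _ in entries]
        for lab, seq in entries:
            digests[lab] = digest(seq)
            entry_gene[lab] = g.gene_id
            entry_seq[lab] = seq
    contaminants = [
        (f"CONTAM_{i + 1:03d}", _random_protein(rng, 120)) for i in range(cfg.n_contaminants)
    ]
    for lab, seq in contaminants:
        digests[lab] = digest(seq)
        entry_gene[lab] = None

    pep_to_entries: dict[str, set[str]] = {}
    for lab, d in digests.items():
        for p in d:
            pep_to_entries.setdefault(p, set()).add(lab)

    # reference digest union (GENCODE-style + UniProt-style hold the same
    # protein space, so one union covers both novelty checks)
    ref_union: set[str] = set()
    for g in genes:
        for _, seq in reference_entries[g.gene_id]:
            ref_union |= digest(seq)

    def hit_genes(pep: str) -> set[str]:
        return {entry_gene[l] for l in pep_to_entries.get(pep, ()) if entry_gene[l]}

    emitted: list[tuple[str, float, int, str | None]] = []  # seq, q, psm, gene
    emitted_seqs: set[str] = set()

    def emit(pep: str, q: float, gene: str | None) -> None:
        if pep in emitted_seqs:
            return
        emitted_seqs.add(pep)
        emitted.append([pep, q, 1, gene])

    def q_true() -> float:
        return float(rng.uniform(*cfg.peptide_q_true))

    # per-gene scenario emission
    scen_names = list(cfg.scenario_weights)
    scen_p = np.array([cfg.scenario_weights[s] for s in scen_names], dtype=float)
    scen_p /= scen_p.sum()
    for g in genes:
        labels = truth.entry_labels[g.gene_id]
        if not labels or rng.random() >= cfg.p_gene_evidenced:
            continue
        uniq = {
            lab: sorted(p for p in digests[lab] if pep_to_entries[p] == {lab})
            for lab in labels
        }
        shared = sorted(
            p
            for p, es in pep_to_entries.items()
            if len(es & set(labels)) >= 2 and hit_genes(p) == {g.gene_id}
        )
        if len(labels) == 1:
            cands = uniq[labels[0]] or sorted(
                p for p in digests[labels[0]] if hit_genes(p) == {g.gene_id}
            )
            for p in _pick(rng, cands, 2):
                emit(p, q_true(), g.gene_id)
            continue
        target = scen_names[int(rng.choice(len(scen_names), p=scen_p))]
        if target == "SHARED_ONLY":
            for p in _pick(rng, shared, 2):
                emit(p, q_true(), g.gene_id)
        elif target == "ONE_CONFIRMED":
            with_u = [l for l in labels if uniq[l]]
            if with_u:
                lab = with_u[int(rng.integers(len(with_u)))]
                emit(_pick(rng, uniq[lab], 1)[0], q_true(), g.gene_id)
            for p in _pick(rng, shared, 1):
                emit(p, q_true(), g.gene_id)
        else:  # MULTI_CONFIRMED
            with_u = [l for l in labels if uniq[l]]
            for lab in with_u[:2]:
                emit(_pick(rng, uniq[lab], 1)[0], q_true(), g.gene_id)
            for p in _pick(rng, shared, 1):
                emit(p, q_true(), g.gene_id)

    # injected novel peptides from event-carrying retained sample entries
    for g in genes:
        if truth.gene_source[g.gene_id] != "PACBIO":
            continue
        for e in sample_entries[g.gene_id]:
            v = e["rep"]
            if v.event is None or len(e["members"]) > 1:
                continue
            iv = _novel_spliced_interval(v)
            if iv is None:
                continue
            cands = []
            for p in sorted(digests[e["label"]]):
                if (
                    p in ref_union
                    or p in emitted_seqs
                    or pep_to_entries[p] != {e["label"]}
                ):
                    continue
                aa = v.protein.find(p)
                if aa < 0:
                    continue
                nt_lo = v.gene.cds_start_spliced + 3 * aa
                nt_hi = nt_lo + 3 * len(p)
                if v.event == "novel_exon":
                    ok = iv[0] <= nt_lo and nt_hi <= iv[1]
                elif v.event == "frameshift":
                    # fully inside the original (reference-exonic) part of the
                    # extended last exon, i.e. at or after the frame-shifted
                    # region's spliced start and not spanning the novel junction
                    ok = nt_lo >= iv[0]
                else:
                    ok = nt_lo < iv[1] and iv[0] < nt_hi
                if ok:
                    cands.append(p)
            if cands:
                p = cands[int(rng.integers(len(cands)))]
                q = float(rng.uniform(*cfg.peptide_q_novel))
                emit(p, q, g.gene_id)
                truth.novel_peptides[p] = (e["label"], v.event)

    # decoy-like emissions: above-threshold false hits and unmapped peptides
    for _ in range(cfg.n_false_peptides):
        lab = sorted(digests)[int(rng.integers(len(digests)))]
        d = sorted(digests[lab])
        if d:
            emit(d[int(rng.integers(len(d)))], float(rng.uniform(*cfg.peptide_q_false)), None)
    for _ in range(cfg.n_unmapped_peptides):
        emit(_random_protein(rng, 12), q_true(), None)

    # scenario/nomination truth recomputed from what was actually emitted
    by_gene_peps: dict[str, list[str]] = {}
    for pep, q, _, _gene in emitted:
        if q > 0.01:
            continue
        hg = hit_genes(pep)
        if len(hg) != 1:
            continue
        by_gene_peps.setdefault(next(iter(hg)), []).append(pep)
    for gene_id, peps in sorted(by_gene_peps.items()):
        labels = truth.entry_labels[gene_id]
        confirmed = sorted(
            {
                next(iter(pep_to_entries[p]))
                for p in peps
                if len(pep_to_entries[p]) == 1
            }
        )
        if len(labels) == 1:
            scen = "SINGLE_ISOFORM_IN_DB"
        elif len(confirmed) >= 2:
            scen = "MULTI_CONFIRMED"
        elif len(confirmed) == 1:
            scen = "ONE_CONFIRMED"
        else:
            scen = "SHARED_ONLY"
        truth.gene_scenario[gene_id] = scen
        nomination, nominated = "NONE", []
        if truth.gene_source[gene_id] == "PACBIO":
            ents = sample_entries[gene_id]
            if scen == "SHARED_ONLY":
                nominated = sorted(e["label"] for e in ents if e["cpm_sum"] >= 25.0)
                if nominated:
                    nomination = "NOMINATED_AMBIGUOUS"
            elif scen == "ONE_CONFIRMED":
                nominated = sorted(
                    e["label"]
                    for e in ents
                    if e["label"] not in confirmed and e["cpm_sum"] >= 25.0
                )
                if nominated:
                    nomination = "NOMINATED_ADDITIONAL"
        truth.gene_nomination[gene_id] = nomination
        truth.nominated_entries[gene_id] = nominated

    # PSM counts: log-linear in gene CPM with Gaussian noise
    truth.psm_model = {
        "slope": cfg.psm_log_slope,
        "intercept": cfg.psm_log_intercept,
        "noise_sd": cfg.psm_log_noise_sd,
    }
    gene_rows: dict[str, list] = {}
    for row in emitted:
        pep, q, _, _ = row
        hg = hit_genes(pep)
        if q <= 0.01 and len(hg) == 1:
            gene_rows.setdefault(next(iter(hg)), []).append(row)
    for gene_id, rows in sorted(gene_rows.items()):
        cpm_total = truth.gene_cpm_total.get(gene_id, 0.0)
        log_psm = (
            cfg.psm_log_intercept
            + cfg.psm_log_slope * math.log10(cpm_total + 1.0)
            + rng.normal(0.0, cfg.psm_log_noise_sd)
        )
        total_psm = max(len(rows), round(10**log_psm))
        base, extra = divmod(total_psm, len(rows))
        for i, row in enumerate(rows):
            row[2] = base + (1 if i < extra else 0)
        truth.gene_psm_total[gene_id] = total_psm

    return truth, [tuple(r[:3]) for r in emitted], contaminants, reference_entries


def _pick(rng: np.random.Generator, items: list, k: int) -> list:
    if not items:
        return []
    k = min(k, len(items))
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in sorted(idx)]


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_AA20))[rng.integers(0, 20, n)])


# ---------------------------------------------------------------------------
# Stage 4: file emission


def end_to_end_fixture(cfg: SimulationConfig, outdir) -> SyntheticBundle:
    """Generate the full input bundle and write it under ``outdir``.

    Layout: genome.fa, reference.gtf, appris.tsv, reference_proteins.fa,
    uniprot_like.fa, contaminants.fa, longreads.gtf, counts.tsv,
    peptides.tsv, plus truth_*.tsv/json tables.
    """
    import os

    rng = np.random.default_rng(cfg.seed)
    genes, genome_seq = generate_reference(cfg, rng)
    simulate_long_reads(cfg, genes, rng)
    truth, peptides, contaminants, reference_entries = simulate_peptide_identifications(
        cfg, genes, rng
    )
    bundle = SyntheticBundle(
        config=cfg,
        genes=genes,
        chrom="chr1",
        genome_seq=genome_seq,
        truth=truth,
        peptides=peptides,
        contaminants=contaminants,
        reference_entries=reference_entries,
    )
    os.makedirs(outdir, exist_ok=True)
    write_bundle(bundle, outdir)
    return bundle


def write_bundle(b: SyntheticBundle, outdir) -> None:
    import os

    join = lambda name: os.path.join(str(outdir), name)

    with open(join("genome.fa"), "w") as fh:
        fh.write(f">{b.chrom}\n")
        for i in range(0, len(b.genome_seq), 60):
            fh.write(b.genome_seq[i : i + 60] + "\n")
    for stale in ("genome.fa.fai",):
        p = join(stale)
        if os.path.exists(p):
            os.remove(p)

    with open(join("reference.gtf"), "w") as fh:
        for g in b.genes:
            for r in g.references:
                _write_gtf_transcript(fh, b.chrom, g, r.exons_body, r.transcript_id, r.protein_id)
    with open(join("appris.tsv"), "w") as fh:
        fh.write("gene_id\ttranscript_id\tappris_label\n")
        for g in b.genes:
            fh.write(f"{g.gene_id}\t{g.references[0].transcript_id}\tPRINCIPAL:1\n")

    with open(join("reference_proteins.fa"), "w") as fh:
        for g in b.genes:
            for r in g.references:
                fh.write(f">{r.protein_id} gene={g.gene_id}\n{r.protein}\n")
    with open(join("uniprot_like.fa"), "w") as fh:
        for g in b.genes:
            for i, (acc, seq) in enumerate(b.reference_entries[g.gene_id]):
                fh.write(f">sp|P{g.index + 1:05d}{i}|{g.gene_id}_HUMAN\n{seq}\n")
    with open(join("contaminants.fa"), "w") as fh:
        for name, seq in b.contaminants:
            fh.write(f">{name}\n{seq}\n")

    with open(join("longreads.gtf"), "w") as fh:
        for g in b.genes:
            for v in g.variants:
                _write_gtf_transcript(fh, b.chrom, g, v.exons_body, v.pb_accession, None)
    with open(join("counts.tsv"), "w") as fh:
        fh.write("pb_accession\tfl_count\n")
        for g in b.genes:
            for v in g.variants:
                fh.write(f"{v.pb_accession}\t{v.fl_count}\n")

    with open(join("peptides.tsv"), "w") as fh:
        fh.write("sequence\tq_value\tpsm_count\n")
        for seq, q, psm in b.peptides:
            fh.write(f"{seq}\t{q:.8f}\t{psm}\n")

    t = b.truth
    with open(join("truth_transcripts.tsv"), "w") as fh:
        fh.write(
            "pb_accession\tgene\tclass\tprotein_class\tremoval\t"
            "junctions_after_stop\tcpm\tfsm_match\n"
        )
        for g in b.genes:
            for v in g.variants:
                fh.write(
                    f"{v.pb_accession}\t{g.gene_id}\t{v.true_class}\t"
                    f"{v.true_protein_class}\t{v.removal or ''}\t"
                    f"{v.junctions_after_stop}\t{v.cpm:.6f}\t{v.fsm_match or ''}\n"
                )
    with open(join("truth_genes.tsv"), "w") as fh:
        fh.write("gene\tsource\tscenario\tnomination\tnominated_entries\tcpm_total\tpsm_total\n")
        for g in b.genes:
            gid = g.gene_id
            fh.write(
                f"{gid}\t{t.gene_source[gid]}\t{t.gene_scenario.get(gid, '')}\t"
                f"{t.gene_nomination.get(gid, '')}\t"
                f"{';'.join(t.nominated_entries.get(gid, []))}\t"
                f"{t.gene_cpm_total.get(gid, 0.0):.6f}\t{t.gene_psm_total.get(gid, 0)}\n"
            )
    with open(join("truth_novel_peptides.tsv"), "w") as fh:
        fh.write("sequence\tentry\tevent\n")
        for seq in sorted(t.novel_peptides):
            lab, ev = t.novel_peptides[seq]
            fh.write(f"{seq}\t{lab}\t{ev}\n")
    with open(join("truth_summary.json"), "w") as fh:
        json.dump(
            {
                "major_not_principal_fraction": t.major_not_principal_fraction,
                "multi_isoform_genes": t.multi_isoform_genes,
                "psm_model": t.psm_model,
                "n_novel_peptides": len(t.novel_peptides),
            },
            fh,
            indent=2,
        )


def _write_gtf_transcript(fh, chrom, g: GenePlan, exons_body, tid, protein_id):
    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; gene_name "{g.gene_id}";'
    ivs = sorted(g.body_interval_to_genomic(s, e) for s, e in exons_body)
    lo, hi = ivs[0][0], ivs[-1][1]
    fh.write(f"{chrom}\tsynth\ttranscript\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n")
    for s, e in ivs:
        fh.write(f"{chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
    if protein_id is not None:
        cds = _cds_body_intervals(g, exons_body)
        for s, e in sorted(g.body_interval_to_genomic(a, c) for a, c in cds):
            fh.write(
                f"{chrom}\tsynth\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                f'{attrs} protein_id "{protein_id}";\n'
            )


def _cds_body_intervals(g: GenePlan, exons_body) -> list[tuple[int, int]]:
    """Body intervals of the CDS (start codon through terminal stop)."""
    spliced = "".join(g.body[s:e] for s, e in exons_body)
    stop = _first_inframe_stop(spliced, g.cds_start_spliced)
    cds_lo_s = g.cds_start_spliced
    cds_hi_s = (stop + 3) if stop is not None else len(spliced)
    out = []
    off = 0
    for s, e in exons_body:
        a = max(cds_lo_s, off)
        bnd = min(cds_hi_s, off + (e - s))
        if a < bnd:
            out.append((s + (a - off), s + (bnd - off)))
        off += e - s
    return out


# ---------------------------------------------------------------------------
# Lightweight expression-pair simulator for the correlation analysis


def simulate_rna_protein_pairs(
    n: int,
    slope: float = 0.8,
    intercept: float = 0.3,
    noise_sd: float = 0.25,
    seed: int = 0,
):
    """(cpm, psm) pairs drawn from the log-linear abundance model.

    log10(psm + 1) = intercept + slope * log10(cpm + 1) + N(0, noise_sd);
    CPM spans three decades uniformly in log space.
    """
    rng = np.random.default_rng(seed)
    cpm = 10 ** rng.uniform(0.0, 3.0, n)
    log_psm = intercept + slope * np.log10(cpm + 1.0) + rng.normal(0.0, noise_sd, n)
    psm = np.maximum(np.round(10**log_psm) - 1, 0)
    return cpm, psm
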