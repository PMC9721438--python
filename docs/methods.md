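# Methods

This note documents the models, rules, and numerical choices behind
`lrproteo`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and annotation model

All intervals are 0-based half-open internally; GTF I/O converts to and
from the 1-based inclusive convention. A junction is the intron interval
`(chrom, strand, lower, upper)`; donor and acceptor are derived, strand-
aware role labels (on `-` the donor is the rightmost boundary), so the
intron between donor and acceptor always has length `upper - lower`. In
the GTF dialect written and read here, CDS features include the stop
codon; a separate `stop_codon` feature, when present, is merged into the
CDS, so GENCODE-style files with exclusive CDS are also handled.

The per-gene mean annotated transcript length — used by the hybrid-database
rule — is the arithmetic mean of spliced (exonic) lengths over **all** of
the gene's annotated transcripts, coding and non-coding alike. This is the
most literal reading of "average reference transcript length"; restricting
to coding transcripts would be an equally defensible choice, and the window
boundaries below are what make the decision consequential. APPRIS ties
(multiple PRINCIPAL tags) break by lowest principal rank, then alphanumeric
transcript id, so exactly zero or one transcript per gene is principal.

## Transcript classification

Multi-exonic transcripts are classified in a fixed decision order: any
donor or acceptor absent from the per-(chrom, strand) annotated site sets
makes the transcript NNC (the offending sites are reported, making every
call auditable); otherwise an exact ordered junction-chain match to a
reference transcript makes it FSM; otherwise NIC. Mono-exonic transcripts
are FSM when fully contained in a mono-exonic reference transcript of the
same gene and OTHER otherwise; OTHER also absorbs intergenic transcripts.
OTHER-class transcripts never enter the protein database. The finer
SQANTI categories (ISM, genic, antisense, ...) are deliberately out of
scope.

Gene assignment, needed when the long-read GTF carries no gene ids, picks
the same-strand reference gene with the largest exonic overlap, breaking
ties toward more shared splice sites. CPM uses as denominator the total
full-length reads assigned to the supplied transcript models, making the
quantity self-contained; CPM over all loaded models sums to 10^6 by
construction, and the >= 1 CPM retention filter is applied afterwards.

Major-isoform ties (equal CPM) break toward larger FL count, then smaller
PB accession numeric suffix — determinism over biological meaning, since a
true tie carries no signal. Reported percentages round to the nearest
integer, half away from zero.

## ORF calling

Candidates are AUG-initiated, sense-strand, and at least 50 nt counting
start through stop codon inclusive; a candidate without an in-frame stop
runs to the transcript end and is flagged rather than dropped, so the
downstream truncation filter's removal count is observable. Codons
containing N end translation (no fabricated residues). Nested ORFs sharing
a stop are distinct candidates.

Selection is a strict lexicographic order: (1) start codon at an annotated
start position of the gene, (2) fewest upstream AUGs skipped, (3) higher
coding potential, (4) longer ORF, (5) smaller start coordinate. The order
encodes the intent of preferring annotated starts and is a total order, so
the selection is permutation-invariant; the reported `selection_tier` names
the rule that decided.

The coding-potential scorer is a deliberate stand-in, not a reimplementation
of a trained model: `sigmoid(-4 + 4*coverage + 3*min(codons/100, 1) +
2*bias)`, where coverage is ORF length over transcript length and bias is a
Fickett-style codon position asymmetry in [0, 1). The coefficients are
fixed constants chosen to be monotone in coverage and saturating in length;
they matter only at tier (3), i.e. when neither start-site provenance nor
skipped-AUG count separates candidates. An external score table keyed by
(transcript, start) can replace it entirely, which is the intended route
when a trained coding-potential tool is available.

## Protein classification and filtering

A predicted protein is compared with the gene's reference protein models
on three elements: N-terminus (start codon genomic position against the
gene's annotated start set), C-terminus (stop codon position against the
annotated stop set, derived from reference CDS ends), and the CDS-internal
splice chain (each donor/acceptor against the gene's annotated CDS site
sets). Any novel element gives pNNC; an exact match of start + CDS chain +
stop to a reference coding transcript gives pFSM; anything else — all
elements known but newly combined — gives pNIC. The evaluation is CDS-only:
UTR-region novelty does not change the protein class, since the
classification is of the protein relative to reference proteins. The
decision table is this package's concrete reconstruction of the
SQANTI-Protein scheme; the whole-transcript alternative would differ only
by letting UTR junctions demote pFSM calls.

Filtering applies, in order, with one recorded reason per isoform:
stop-less ORFs (truncation suspects); classes outside {pFSM, pNIC, pNNC};
and NMD suspects — pNNC isoforms with **more than two** junctions strictly
3' of the stop codon. The NMD rule is scoped to pNNC only (pFSM/pNIC are
exempt), matching the stated staging of the filter; the retained + removed
sets partition the input exactly.

Grouping merges retained isoforms of a gene with identical protein
sequences; the group's CPM is the sum of member CPMs and its representative
is the highest-CPM member (ties to the smaller accession suffix). Hybrid
assembly takes sample entries for genes with >= 3 CPM aggregate abundance
and mean annotated length in [1000, 4000] nt (both boundaries inclusive;
"at least three" is explicit, "between 1 and 4 kbp" is taken inclusively),
reference entries for every other annotated gene including those absent
from the long-read data, and appends contaminants verbatim. Labels must be
unique; CPM in labels prints with one decimal.

## Peptide evidence

Peptide-to-protein matching requires digest-legal termini — fully tryptic
(cleave after K/R except before P), at most 2 missed cleavages, peptide
length 7-50 aa — rather than free substring matching, because that is how
the peptides were produced and searched; a substring mode exists for
exploration. Isoleucine and leucine are distinct by default with an
I/L-equivalence switch for novelty checks (the default is the conservative
direction: fewer novel calls). Peptides hitting entries of more than one
gene are excluded from isoform-level evidence and from the per-gene PSM
sums.

Evidence scenarios per evidenced gene: one database entry ->
SINGLE_ISOFORM_IN_DB; otherwise by the number of entries carrying a
uniquely mapping peptide (0 SHARED_ONLY, 1 ONE_CONFIRMED, >= 2
MULTI_CONFIRMED). Nominations add transcript abundance as evidence:
SHARED_ONLY genes nominate every sample entry at >= 25 CPM (two or more
flags potential isoform co-expression); ONE_CONFIRMED genes nominate
unconfirmed sample entries at >= 25 CPM. Reference-sourced genes carry no
abundance and are never nominated.

Novel peptides require all three of: q strictly below 0.001, a mapping to
at least one sample entry, and exact absence from the tryptic digests of
both reference databases. Event annotation projects the peptide's codons
through the exon chain to genomic intervals and tests, in order: a spanned
junction with an unannotated site (novel acceptor/donor); footprint bases
in reference-intronic sequence — classified by the containing transcript
exon as full-intron bridge (intron retention), no reference-exon overlap
(novel exon), or one-sided extension (novel acceptor/donor by side); frame
disagreement with every reference coding transcript over the footprint
(frameshift); else other.

The RNA-protein correlation regresses log10(PSM + 1) on log10(CPM + 1) per
gene by ordinary least squares. Both distributions are heavy-tailed, hence
the log-log space; the pseudocount of 1 keeps zero counts finite and is the
conventional minimal choice.

## Synthetic data: what it emulates and what it does not

The generator builds gene bodies over a T-free {A, C, G} alphabet so that
no stop codon or AUG exists anywhere in any frame except where planted:
one start AUG after a 9-nt 5' UTR, a terminal in-frame TAA before a 15-nt
3' UTR, and auxiliary TAAs planted out-of-frame (phases 1 and 2) in the
last exon and in exon 2. Out-of-frame TAA planting is invisible to the
in-frame reading (no codon window across a phase-1/2 TAA can form a stop
or an AUG), so every transcript carries exactly one candidate ORF and the
true protein of every edited isoform is known in closed form. Exon and
intron lengths are multiples of 3, which keeps every frame-preserving edit
(exon skip, double skip, intron retention, 60-nt novel exon, 27-nt
acceptor/donor shifts) in frame through the terminal stop. Frame-shifting
28-nt shifts divert translation onto the auxiliary stops: a late shift
(last intron) yields a retained frameshift isoform with 0 junctions after
the stop; an early shift (first intron) stops in exon 2 with >= 3 junctions
after the stop, i.e. a planted NMD suspect; dropping the last two exons
yields a stop-less truncation suspect. Default per-gene event rates
(0.15-0.35), gene counts (30 in the smoke preset), 5-7 exons of 240-420 nt,
transcript CPMs log-normal (ln-mean 2.0, ln-sd 1.3) scaled to a 10^6-read
library, a 30% planted rate of major-isoform/principal discordance, and a
log-linear PSM model (slope 0.8, noise sd 0.25 in log10 space, a moderate
RNA-protein correlation) were chosen once as a realistic miniature of a
long-read proteogenomics experiment and are fixed.

Peptide emission draws shared and isoform-unique peptides from the tryptic
digests of the replica database the generator constructs for itself, with
per-gene target scenarios; novel peptides are injected only from entries
carrying a planted event, constrained to footprints that genuinely overlap
the novel region (and, for frameshift truth, to lie inside the reframed
exonic region without spanning the novel junction). All truth labels are
consequences of the construction, not of running the analysis under test.

What passing these tests shows: the classification, selection, filtering,
assembly, and evidence logic implements its stated rules exactly, on both
strands, across every planted event type, at the stated boundaries. What
it does not show: robustness to real long-read artifacts (truncated or
intrapriming reads, mono-exonic noise, fuzzy junction alignment), to real
sequence composition (the T-free alphabet yields proteins over a reduced
residue set with atypical tryptic site density), to search-engine score
calibration, or to reference annotations with overlapping genes. Those
belong to upstream QC tools and to the external search engine, both out of
scope here.

## Determinism and degenerate inputs

All generator randomness flows from one seeded NumPy generator; a fixed
seed reproduces bundles byte for byte. The pipeline itself is
deterministic: every tie-break is total (accession suffixes, lexicographic
minima), so reruns on identical inputs give identical reports. Degenerate
inputs have defined behavior: zero total reads is a hard error ("empty
dataset"); a transcript overlapping no gene is OTHER; a gene without
reference coding transcripts is pOTHER; empty long-read input degenerates
the hybrid database to grouped reference plus contaminants; fewer than 3
RNA-protein pairs is an error; a constant PSM axis returns R^2 = 0.

## Known limitations

Single-AUG, sense-strand ORFs only (no non-AUG starts, selenocysteine, or
frameshift recoding); no protein-level FDR or parsimony inference — the
evidence tiers operate directly on peptides; the coding-potential stand-in
is not a trained model; mean annotated length uses all transcripts (see
above); GFF3, fusion transcripts, and liftover are unsupported. The
published HUVEC predicted-protein tallies contain internal inconsistencies
(component sums that disagree with printed totals by single digits); the
bundled bookkeeping therefore reproduces only the self-consistent
identities, and the database total is reported both with and without
contaminants since the printed total excludes them.
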