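"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives a result from first principles (exhaustive scans and
set enumeration) without sharing code with the library paths it checks.
"""

from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orf_scan(seq: str, min_nt: int = 50):
    """Every AUG-initiated ORF, by testing every position independently.

    Returns (start, stop, has_stop) triples; stop is one past the stop codon
    or the sequence end (or the first N-containing codon) for stop-less ORFs.
    """
    seq = seq.upper()
    out = []
    for start in range(len(seq)):
        if seq[start : start + 3] != "ATG":
            continue
        stop = None
        has_stop = False
        i = start
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if "N" in codon:
                stop = i
                break
            if codon in STOPS:
                stop = i + 3
                has_stop = True
                break
            i += 3
        if stop is None:
            stop = len(seq)
        if stop - start >= min_nt:
            out.append((start, stop, has_stop))
    return out


def brute_force_digest(seq: str, missed_cleavages=2, min_len=7, max_len=50):
    """Tryptic peptides by enumerating every cleavage-site window.

    Cleavage sites are after K/R not followed by P; a peptide is any span
    between consecutive sites with at most ``missed_cleavages`` internal
    sites.
    """
    sites = [0]
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            sites.append(i + 1)
    if sites[-1] != len(seq):
        sites.append(len(seq))
    peps = set()
    for a in range(len(sites) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(sites))):
            p = seq[sites[a] : sites[b]]
            if min_len <= len(p) <= max_len:
                peps.add(p)
    return peps


def brute_force_transcript_class(
    query_junctions,
    chrom,
    strand,
    reference_transcripts,
):
    """FSM/NIC/NNC by exhaustive enumeration over reference transcripts.

    ``query_junctions`` is the ordered (donor, acceptor) chain;
    ``reference_transcripts`` is a list of (chain, chrom, strand) triples for
    the whole annotation.  Mono-exonic and gene-assignment cases are out of
    scope here (multi-exonic only).
    """
    donors, acceptors, chains = set(), set(), set()
    for chain, c, s in reference_transcripts:
        if (c, s) != (chrom, strand):
            continue
        chains.add(tuple(chain))
        for d, a in chain:
            donors.add(d)
            acceptors.add(a)
    for d, a in query_junctions:
        if d not in donors or a not in acceptors:
            return "NNC"
    if tuple(query_junctions) in chains:
        return "FSM"
    return "NIC"


def naive_peptide_scan(peptide: str, entries, missed_cleavages=2):
    """Entry labels containing the peptide at digest-legal termini.

    Checks every substring occurrence and validates that both termini are
    legal tryptic boundaries with at most ``missed_cleavages`` internal
    sites.
    """

    def legal(seq, lo, hi):
        if lo > 0:
            prev = seq[lo - 1]
            if not (prev in "KR" and seq[lo] != "P"):
                return False
        if hi < len(seq):
            last = seq[hi - 1]
            if not (last in "KR" and seq[hi] != "P"):
                return False
        internal = sum(
            1
            for i in range(lo, hi - 1)
            if seq[i] in "KR" and seq[i + 1] != "P"
        )
        return internal <= missed_cleavages

    hits = set()
    for label, seq in entries:
        start = seq.find(peptide)
        while start >= 0:
            if legal(seq, start, start + len(peptide)):
                hits.add(label)
                break
            start = seq.find(peptide, start + 1)
    return hits
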