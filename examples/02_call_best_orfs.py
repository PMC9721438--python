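"""Enumerate candidate ORFs and select the most plausible one.

Candidates are AUG-initiated, >= 50 nt (start through stop codon).  The
selection prefers, in order: annotated start positions, fewer skipped
upstream AUGs, higher coding potential, longer ORFs.
"""

from lrproteo.orf_calling import (
    enumerate_candidate_orfs,
    mark_reference_starts,
    score_candidates,
    select_best_orf,
)
from lrproteo.reference_model import Exon

# one transcript: 12-nt 5' UTR, an annotated start at genomic 112, and a
# decoy downstream AUG
seq = "CCACCACCACCA" + "ATG" + "GCAGAACTG" * 8 + "ATG" + "GCC" * 18 + "TAA"
exons = [Exon("chr1", 100, 100 + len(seq), "+")]

cands = enumerate_candidate_orfs("PB.1.1", seq)
score_candidates(cands, seq)
mark_reference_starts(cands, exons, annotated_starts={112})
best = select_best_orf(cands)

print(f"{len(cands)} candidate ORFs")
for c in cands:
    print(
        f"  start={c.start_nt:3d} len={c.orf_nt_length:3d} nt "
        f"ref_start={c.start_matches_reference} skipped={c.upstream_augs_skipped} "
        f"coding_potential={c.coding_potential:.3f}"
    )
print(
    f"selected: start={best.orf.start_nt} ({len(best.orf.protein_sequence)} aa), "
    f"decided by the '{best.selection_tier}' rule"
)
# the annotated start wins over the longer downstream ORF because start-site
# provenance outranks length in the selection order.
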