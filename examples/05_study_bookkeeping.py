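"""Reproduce the HUVEC study's bookkeeping arithmetic from component counts.

The dataset-level counts published for the HUVEC Iso-Seq + MS experiment
are bundled in ``lrproteo.datasets``; this recomputes the derived totals,
shares, and rounded percentages from them.
"""

from lrproteo import datasets

b = datasets.huvec_bookkeeping()
c = datasets.HUVEC_COUNTS

print(f"transcripts: {c['transcripts_total']} = {c['transcripts_fsm']} FSM "
      f"+ {c['transcripts_nic']} NIC + {c['transcripts_nnc']} NNC "
      f"(check: {b['transcripts_total_check']})")
print(f"FSM share: {b['fsm_percent']}%  novel: {b['novel_percent']}% "
      f"(NIC {b['nic_percent_of_novel']}% / NNC {b['nnc_percent_of_novel']}% of novel)")
print(f"multi-isoform genes: {b['multi_isoform_gene_percent']}% of detected; "
      f"major != APPRIS principal: {b['major_not_principal_percent']}%")
print(f"minimum FL count reaching 1 CPM at {c['total_long_reads']} reads: "
      f"{b['min_count_for_1cpm']}")
print(f"hybrid DB: {b['db_total_genes']} genes, {b['db_total_entries']} entries "
      f"(+{c['db_contaminant_entries']} contaminants = "
      f"{b['db_total_entries_with_contaminants']})")
print(f"evidenced genes: {b['evidenced_genes']} "
      f"({b['shared_only_percent']}% shared-only); "
      f"nominated ambiguous: {b['nominated_ambiguous_percent']}% of shared-only")
print(f"SRSF5 Table 1 CPM sum: {b['srsf5_total_cpm']}")
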