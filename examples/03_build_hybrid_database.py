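"""Build the hybrid protein search database from a synthetic study.

Predicted proteins are filtered (stop-less truncations, non-pFSM/pNIC/pNNC
classes, pNNC NMD suspects with > 2 junctions after the stop), grouped by
identical sequence with summed CPM, and combined with reference proteins:
sample entries for high-confidence genes (>= 3 CPM, 1-4 kbp mean annotated
length), reference entries elsewhere, contaminants appended.
"""

import tempfile

from lrproteo.pipeline import run_pipeline
from lrproteo.synthetic_data import SimulationConfig, end_to_end_fixture

d = tempfile.mkdtemp()
end_to_end_fixture(SimulationConfig(seed=3, n_genes=15), d)
res = run_pipeline(
    reference_gtf=f"{d}/reference.gtf", genome_fasta=f"{d}/genome.fa",
    longread_gtf=f"{d}/longreads.gtf", counts_tsv=f"{d}/counts.tsv",
    peptides_tsv=f"{d}/peptides.tsv", appris_tsv=f"{d}/appris.tsv",
    contaminants_fasta=f"{d}/contaminants.fa", outdir=f"{d}/out",
)

print("removal ledger:", res.report.removal_ledger)
print("genes by source:", res.report.db_genes_by_source)
print("entries by source:", res.report.db_entries_by_source)
pacbio = [e for e in res.db.entries if e.source == "PACBIO"]
print("example sample entry label:", pacbio[0].label)
# the label format <Gene>|<PB accession>|<protein class>|<CPM> carries the
# representative transcript, its SQANTI-Protein class, and the summed
# transcript abundance of all transcripts yielding this protein sequence.
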