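import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lrproteo.pipeline import run_pipeline
from lrproteo.reference_model import Exon, ReferenceCatalog, ReferenceTranscript
from lrproteo.synthetic_data import SimulationConfig, end_to_end_fixture


def make_catalog(transcripts) -> ReferenceCatalog:
    """Index hand-built reference transcripts into a catalog (no genome)."""
    cat = ReferenceCatalog()
    for t in transcripts:
        cat._index_transcript(t)
    cat._finalize()
    return cat


def ref_transcript(tid, gene, exon_coords, strand="+", chrom="chrT", cds=None, **kw):
    exons = [Exon(chrom, s, e, strand) for s, e in exon_coords]
    if strand == "-":
        exons = exons[::-1]
    t = ReferenceTranscript(
        transcript_id=tid, gene_id=gene, gene_name=gene, exons=exons, **kw
    )
    if cds is not None:
        t.cds_start, t.cds_end = cds
    return t


@pytest.fixture(scope="session")
def toy_catalog():
    """Two-gene catalog: GA on '+' (two isoforms), GB on '-' (one isoform)."""
    t1 = ref_transcript(
        "GA-201", "GA", [(100, 200), (300, 400), (500, 600), (700, 800)],
        cds=(130, 770), protein_id="GA-P201", is_principal=True,
    )
    t2 = ref_transcript(
        "GA-202", "GA", [(100, 200), (500, 600), (700, 800)],
        cds=(130, 770), protein_id="GA-P202",
    )
    t3 = ref_transcript(
        "GB-201", "GB", [(2000, 2100), (2300, 2400), (2600, 2700)],
        strand="-", cds=(2030, 2670), protein_id="GB-P201", is_principal=True,
    )
    return make_catalog([t1, t2, t3])


@pytest.fixture(scope="session")
def smoke_bundle(tmp_path_factory):
    d = tmp_path_factory.mktemp("smoke")
    bundle = end_to_end_fixture(SimulationConfig.smoke(seed=1), d)
    return bundle, d


@pytest.fixture(scope="session")
def smoke_run(smoke_bundle):
    bundle, d = smoke_bundle
    result = run_pipeline(
        reference_gtf=d / "reference.gtf",
        genome_fasta=d / "genome.fa",
        longread_gtf=d / "longreads.gtf",
        counts_tsv=d / "counts.tsv",
        peptides_tsv=d / "peptides.tsv",
        appris_tsv=d / "appris.tsv",
        contaminants_fasta=d / "contaminants.fa",
        second_reference_fasta=d / "uniprot_like.fa",
        outdir=d / "out",
    )
    return bundle, result
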