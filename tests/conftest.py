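import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from codsplice import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    SimulationConfig,
    TranscriptModel,
    detect_all,
    generate_cohort,
    generate_reference,
)


def make_transcript(coords, strand="+", tid="t1", gid="g1", chrom="chr1"):
    return TranscriptModel(
        tid, gid, [GenomicInterval(chrom, s, e, strand) for s, e in coords], strand
    )


def make_gene(isoform_coords, strand="+", gid="g1", **kw):
    isoforms = [
        make_transcript(coords, strand=strand, tid=f"{gid}.t{i + 1}", gid=gid)
        for i, coords in enumerate(isoform_coords)
    ]
    return GeneModel(gene_id=gid, symbol=kw.get("symbol", gid), biotype="protein_coding", isoforms=isoforms)


@pytest.fixture(scope="session")
def default_sim():
    """The default seeded study cohort, shared across tests: reference,
    observed records, planted truth and the detection callset."""
    config = SimulationConfig(seed=1)
    annotation = generate_reference(config)
    observed, truth = generate_cohort(annotation, config)
    callset = detect_all(observed, annotation)
    return config, annotation, observed, truth, callset
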