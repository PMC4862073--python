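import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hoxatlas.model import GeneModel, GenomeAnnotation, Scaffold, TranscriptModel
from hoxatlas.synthetic_data import default_mirna_templates


@pytest.fixture(scope="session")
def templates():
    return default_mirna_templates(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160510)


def make_toy_annotation(
    gene_positions, scaffold_len=100_000, scaffold_id="s1", strands=None,
    biotypes=None, sequence=None,
):
    """Single-scaffold annotation from (start, end) tuples, single-exon genes."""
    ann = GenomeAnnotation(
        scaffolds={
            scaffold_id: Scaffold(id=scaffold_id, length=scaffold_len, sequence=sequence)
        }
    )
    for i, (s, e) in enumerate(gene_positions):
        gid = f"g{i}"
        strand = strands[i] if strands else "+"
        ann.add_gene(
            GeneModel(
                gene_id=gid, scaffold_id=scaffold_id, start=s, end=e, strand=strand,
                transcripts=[
                    TranscriptModel(
                        transcript_id=f"{gid}.t1", exons=[(s, e)],
                        cds=[(s, e)],
                    )
                ],
                biotype=biotypes[i] if biotypes else "protein_coding",
            )
        )
    return ann
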