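import numpy as np
import pytest

from smgcpan.smgc_io import GeneRecord, GenomeMetadata, SmgcRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, lo: int = 30, hi: int = 80) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def make_gene(gene_id, genome_id, cluster_id, seq, start=1, strand="+"):
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome_id,
        cluster_id=cluster_id,
        start=start,
        end=start + 3 * len(seq) - 1,
        strand=strand,
        protein_seq=seq,
    )


def make_cluster(cluster_id, genome_id, seqs, smgc_class="nrps"):
    genes = []
    pos = 1
    for i, seq in enumerate(seqs):
        genes.append(
            make_gene(f"{cluster_id}.g{i + 1}", genome_id, cluster_id, seq, start=pos)
        )
        pos += 3 * len(seq) + 50
    return SmgcRecord(
        cluster_id=cluster_id,
        genome_id=genome_id,
        smgc_class=smgc_class,
        length_bp=pos + 100,
        genes=tuple(genes),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_metadata():
    return [
        GenomeMetadata("g1", "NDR", 8_700_000, 7775),
        GenomeMetadata("g2", "NDR", 8_600_000, 7700),
        GenomeMetadata("g3", "SDR", 7_900_000, 7093),
        GenomeMetadata("g4", "SDR", 7_950_000, 7100),
    ]
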