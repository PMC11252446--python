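import pytest

from y1hnet.model import GeneRecord, PromoterRegion, TFRecord
from y1hnet.network import build_network
from y1hnet.simulate import WorldParams, generate_world, make_planted_study


@pytest.fixture(scope="session")
def small_world():
    """A compact noisy world for fast end-to-end tests."""
    return generate_world(
        WorldParams(n_tfs=60, n_genes=40, n_tf_pairs=10, seed=42)
    )


@pytest.fixture(scope="session")
def noiseless_world():
    return generate_world(
        WorldParams(
            n_tfs=60,
            n_genes=40,
            n_tf_pairs=10,
            colony_dropout_prob=0.0,
            colony_false_active_prob=0.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def planted_study():
    return make_planted_study(seed=0)


def make_promoter(pid, gene_id, start=1000, end=3000, strand="+", chrom="chr1"):
    tss = end if strand == "+" else start
    return PromoterRegion(pid, gene_id, chrom, start, end, strand, tss)


@pytest.fixture
def toy_network():
    """T1 binds two promoters of gene A and one of gene B; T2 binds gene B."""
    promoters = {
        "A.P1": make_promoter("A.P1", "A", 1000, 3000),
        "A.P2": make_promoter("A.P2", "A", 11000, 13000),
        "B.P1": make_promoter("B.P1", "B", 21000, 23000),
    }
    calls = [
        ("T1", "A.P1", "eY1H"),
        ("T1", "A.P2", "eY1H"),
        ("T1", "B.P1", "eY1H"),
        ("T2", "B.P1", "eY1H"),
    ]
    tf_ann = {
        "T1": TFRecord("T1", "SymT1", "bZIP", "activator"),
        "T2": TFRecord("T2", "SymT2", "NHR", "repressor"),
    }
    gene_ann = {
        "A": GeneRecord("A", "SymA", "oncogene", "poor"),
        "B": GeneRecord("B", "SymB", "tsg", "good"),
    }
    return build_network(calls, promoters, tf_ann, gene_ann)
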