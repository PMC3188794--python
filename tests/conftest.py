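import numpy as np
import pytest

import ribotai as rt


@pytest.fixture(scope="session")
def weights():
    """Codon weight table from the bundled tRNA pool."""
    return rt.default_weights()


@pytest.fixture(scope="session")
def default_lib(weights):
    """The default synthetic library (150 uniform-synonymous GFP-like variants
    with planted measurement effects), fixed seed."""
    return rt.default_library(weights, seed=11)


@pytest.fixture(scope="session")
def random_genes(weights):
    """200 random-codon genes of varying length (well above the scan window)."""
    rng = np.random.default_rng(2024)
    codons = list(rt.SENSE_CODONS)
    return [
        rt.CodingSequence(
            id=f"g{i:03d}",
            codons=tuple(rng.choice(codons, size=int(rng.integers(120, 400)))),
        )
        for i in range(200)
    ]


def make_gene(gene_id, codon, length):
    """Gene of one repeated codon."""
    return rt.CodingSequence(id=gene_id, codons=(codon,) * length)


@pytest.fixture(scope="session")
def uniform_weight_table():
    """All 61 codons at weight 0.5 except one reference codon at 1."""
    w = {c: 0.5 for c in rt.SENSE_CODONS}
    w["AAA"] = 1.0
    return rt.CodonWeightTable(w=w, source="synthetic uniform")
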