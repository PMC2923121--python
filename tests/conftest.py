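import numpy as np
import pytest

from alusv.gene_model import ExonInterval, GeneModel
from alusv import synthetic as syn


@pytest.fixture(scope="session")
def toy_model() -> GeneModel:
    """3 exons of 10 bp at g 101-110, 121-130, 141-150 (introns of 10 bp);
    CDS from g 105 (exon 1) to g 146 (exon 3): 4 bp 5'UTR, 4 bp 3'UTR."""
    return GeneModel(
        "TOY1",
        "toyref",
        [ExonInterval(1, 101, 110), ExonInterval(2, 121, 130),
         ExonInterval(3, 141, 150)],
        translation_start_g=105,
        stop_end_g=146,
    )


@pytest.fixture(scope="session")
def default_locus() -> syn.Locus:
    return syn.build_locus(syn.default_locus_spec(0))


@pytest.fixture(scope="session")
def ldlr_fixture():
    from alusv.ldlr import build_ldlr_like_fixture

    return build_ldlr_like_fixture(0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
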