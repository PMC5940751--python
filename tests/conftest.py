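import numpy as np
import pytest

from mrlink.sumstats import HaplotypePanel, SumStatsTable, VariantAssociation


def make_variant(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.02, p=1e-9,
                 eaf=0.3, chrom="1", pos=1000, **kw):
    return VariantAssociation(rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea,
                              other_allele=oa, beta=beta, se=se, pvalue=p,
                              eaf=eaf, **kw)


def make_table(records, provenance="test"):
    return SumStatsTable.from_records(records, provenance=provenance)


@pytest.fixture
def tiny_panel():
    """10 haplotypes over 3 variants: v1/v2 fully coupled, v3 independent."""
    v1 = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    v2 = v1.copy()
    v3 = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
    return HaplotypePanel(rsids=["v1", "v2", "v3"],
                          matrix=np.vstack([v1, v2, v3]),
                          pos=np.array([100, 200, 300]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
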