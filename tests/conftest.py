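import pytest

from mrmediation.gwas_io import SummaryStatRecord
from mrmediation.harmonization import HarmonizedInstrument


def make_record(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.01,
                chrom="1", pos=1_000_000, eaf=0.3, pval=1e-10, n=100_000.0):
    return SummaryStatRecord(rsid=rsid, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, chrom=chrom, pos=pos,
                             eaf=eaf, pval=pval, n=n)


def make_instrument(rsid="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02, **kw):
    return HarmonizedInstrument(
        rsid=rsid, effect_allele="A", other_allele="G",
        beta_exposure=bx, se_exposure=sx,
        beta_outcome=by, se_outcome=sy, **kw)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def instrument_factory():
    return make_instrument


@pytest.fixture
def five_instruments():
    """Five harmonized SNPs with varied effects, no special structure."""
    data = [(0.10, 0.02, 0.01), (0.22, 0.05, 0.012), (0.31, 0.06, 0.02),
            (0.15, 0.04, 0.015), (0.27, 0.09, 0.018)]
    return [make_instrument(rsid=f"rs{i}", bx=bx, by=by, sy=sy)
            for i, (bx, by, sy) in enumerate(data, start=1)]
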