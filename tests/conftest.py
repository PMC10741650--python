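import numpy as np
import pytest

from mrmediate.sumstats import (
    HarmonizedInstrument,
    InstrumentSet,
    VariantAssociation,
)


def make_assoc(vid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
               beta=0.1, se=0.01, p=1e-12, n=100_000):
    return VariantAssociation(vid, chrom, pos, ea, oa, eaf, beta, se, p, n)


def make_instruments(bx, se_x, by, se_y, mediators=None, mediator_ses=None,
                     mediator_names=()):
    """Build an InstrumentSet straight from effect arrays."""
    instruments = []
    for j in range(len(bx)):
        med_b = tuple(col[j] for col in mediators) if mediators else None
        med_s = tuple(col[j] for col in mediator_ses) if mediator_ses else None
        instruments.append(
            HarmonizedInstrument(
                variant_id=f"rs{j}",
                beta_exposure=float(bx[j]),
                se_exposure=float(se_x[j]),
                beta_outcome=float(by[j]),
                se_outcome=float(se_y[j]),
                eaf=0.3,
                f_stat=(float(bx[j]) / float(se_x[j])) ** 2,
                beta_mediators=med_b,
                se_mediators=med_s,
            )
        )
    return InstrumentSet("exposure", "outcome", tuple(mediator_names), instruments)


@pytest.fixture
def two_instruments():
    """The worked IVW/Q example: weights 100 and 400, ratios 0.3 and 0.1."""
    return make_instruments(
        bx=[0.1, 0.2], se_x=[0.01, 0.01], by=[0.03, 0.02], se_y=[0.01, 0.01]
    )


@pytest.fixture
def random_instruments():
    rng = np.random.default_rng(42)
    n = 10
    bx = rng.normal(0.05, 0.02, n)
    bx[np.abs(bx) < 0.01] = 0.02
    se_x = rng.uniform(0.003, 0.01, n)
    by = rng.normal(0.01, 0.01, n)
    se_y = rng.uniform(0.005, 0.02, n)
    return make_instruments(bx, se_x, by, se_y)
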