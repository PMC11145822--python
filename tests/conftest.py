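import numpy as np
import pytest

from mrlipid import (
    HarmonizedInstrument,
    InstrumentSet,
    SummaryRecord,
    paper_like_config,
    simulate_dataset,
)


def make_iset(
    bx,
    by,
    sy,
    sx=None,
    n_exp=300_000,
    n_out=337_199,
    name="exposure",
) -> InstrumentSet:
    """Build an InstrumentSet directly from effect arrays (test helper)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    instruments = [
        HarmonizedInstrument(
            snp_id=f"rs{i:04d}",
            effect_allele="A",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
            n_exp=n_exp,
            n_out=n_out,
            chrom="1",
            pos=1_000_000 + i * 1_000_000,
        )
        for i in range(bx.size)
    ]
    return InstrumentSet(exposure_name=name, instruments=instruments)


@pytest.fixture(scope="session")
def paper_study():
    """The three-lipid synthetic study at seed 0 (shared across tests)."""
    return simulate_dataset(paper_like_config(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
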