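import numpy as np
import pytest

from mosaicstr.config import RunConfig
from mosaicstr.simulate import SimulationConfig, simulate_cohort
from mosaicstr.stutter import StutterModel
from mosaicstr.types import ObservedRead, STRLocus


@pytest.fixture
def cag_locus():
    return STRLocus(chrom="1", start=1000, end=1024, motif="CAG",
                    ref_allele_seq="CAG" * 8, left_flank_3bp="TTA",
                    right_flank_3bp="GGC")


@pytest.fixture
def default_model():
    return StutterModel(u=0.01, d=0.01, rho=0.9, unit=1)


@pytest.fixture
def config():
    return RunConfig()


def make_read(sequence, e=0.001, read_id="r1", cell_id="c1", mapq=60, **kw):
    return ObservedRead(read_id=read_id, cell_id=cell_id, sequence=sequence,
                        base_error_rates=np.full(len(sequence), e),
                        mapping_quality=mapq, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared by the slower tests."""
    cfg = SimulationConfig(n_loci=40, n_cells=6, n_mosaic=8, seed=11)
    return simulate_cohort(cfg)
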