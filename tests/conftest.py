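import numpy as np
import pytest

from armflip.io_formats import HairpinLocus, SampleRecord
from armflip.synthetic_data import SimConfig, generate_hairpins, make_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Reduced 1 accession x 2 tissues x 2 time points x 3 replicates design."""
    return SimConfig(
        n_hairpins=12,
        n_switch_loci=3,
        nb_mean=150.0,
        nb_dispersion=0.05,
        accessions=("C08",),
        time_points_h=(0.0, 24.0),
        n_lncrnas=8,
        n_interacting_pairs=2,
        seed=42,
    )


@pytest.fixture
def small_loci(small_cfg, rng):
    return generate_hairpins(small_cfg, rng)


@pytest.fixture
def small_samples(small_cfg):
    return make_design(small_cfg)


@pytest.fixture
def toy_locus():
    # 21 nt 5p arm, 16 nt loop, 21 nt 3p arm
    arm5 = "ACGUACGUACGUACGUACGUA"
    loop = "CCCCGGGGAAAAUUUU"
    arm3 = "UGGAUGGAUGGAUGGAUGGAU"
    seq = arm5 + loop + arm3
    return HairpinLocus(
        hairpin_id="hp-toy",
        sequence=seq,
        arm5p=(0, 21),
        arm3p=(37, 58),
        mature5p_id="hp-toy-5p",
        mature3p_id="hp-toy-3p",
    )
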