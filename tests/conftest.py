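import numpy as np
import pytest

from promab import synthetic_data as sd


@pytest.fixture(scope="session")
def panel():
    """Default synthetic antibody panel: 4 promiscuous + 6 non-promiscuous."""
    return sd.generate_antibody_set(sd.SequenceGenConfig(seed=0))


@pytest.fixture(scope="session")
def hairpin_start():
    return sd.build_ideal_backbone("hairpin", 16)


@pytest.fixture(scope="session")
def small_hairpin_ensemble(hairpin_start):
    cfg = sd.EnsembleGenConfig(n_conformers=50, backbone_noise=4.0, seed=11)
    return sd.generate_ensemble(hairpin_start, cfg)
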