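import numpy as np
import pytest

from satselseq.demux import Decoder, GenerationBarcodeSet
from satselseq.library import build_library_panel, default_reference
from satselseq.simulate import CampaignConfig, FitnessMap, run_campaign


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def panel(ref):
    return build_library_panel(ref)


@pytest.fixture(scope="session")
def barcodes():
    return GenerationBarcodeSet()


@pytest.fixture(scope="session")
def decoder(ref, panel, barcodes):
    return Decoder(ref, panel, barcodes)


@pytest.fixture(scope="session")
def noiseless_campaign(ref, panel):
    """Small noiseless campaign over two libraries with known selection."""
    fitness = FitnessMap.from_aa({"L": 5.0, "Y": 2.0}, stop=0.0)
    config = CampaignConfig(
        libraries=panel[:2], ref=ref, fitness=fitness,
        initial_depth=2_000, bottleneck=2_000, generations=3,
        reads_per_sample=1_000, error_rate=0.0, seed=7,
    )
    return run_campaign(config)
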