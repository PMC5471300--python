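import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sampled():
    """Small planted-topology alignment shared by fit-quality tests:
    L=16 chain, strong couplings, 800 Gibbs samples."""
    from coevo.synth import generate_topology, plant_potts, sample_sequences

    rng = np.random.default_rng(91)
    topo = generate_topology(16, 8, rng)
    model = plant_potts(topo, 1.5, rng)
    aln = sample_sequences(model, 800, rng, burn_in=500, thinning=5)
    return topo, model, aln
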