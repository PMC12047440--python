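import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lambda_genome():
    """Deterministic lambda-scale synthetic genome with 12 planted target sites."""
    from rnpq.simulate import synthetic_lambda_genome

    return synthetic_lambda_genome()


@pytest.fixture(scope="session")
def lambda_track(lambda_genome):
    from rnpq.curtains import GenomeTrack

    return GenomeTrack(lambda_genome)


@pytest.fixture(scope="session")
def small_track():
    """5-kb random genome for oracle-equivalence checks."""
    from rnpq.curtains import GenomeTrack

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return GenomeTrack(seq, at_window_bp=200, at_step_bp=100)


@pytest.fixture(scope="session")
def spot_scene():
    """Mid-SNR synthetic cell image with mixed compartments, no colocalization."""
    from rnpq.simulate import gen_spot_images

    return gen_spot_images(
        n_cells=4, image_shape=(16, 96, 96), n_spots_per_cell=10,
        colocalized_fraction=0.0, nuclear_fraction=0.3, seed=11,
        spot_intensity={"rna": 100.0, "protein": 100.0, "dna": 300.0})
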