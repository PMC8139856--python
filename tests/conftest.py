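import numpy as np
import pytest

from atlasmap.homology_graph import hits_from_frame
from atlasmap.refinement import map_atlases
from atlasmap.synthetic_data import SimConfig, generate_species_pair


@pytest.fixture(scope="session")
def small_pair():
    """A small synthetic species pair exercising every homology feature."""
    cfg = SimConfig(
        n_celltypes=4,
        cells_per_type=60,
        n_ortholog_groups=300,
        program_size=20,
        divergence=0.2,
        frac_one_to_many=0.2,
        frac_many_to_many=0.05,
        frac_species_specific=0.2,
        n_substitutions=3,
        n_decoy_paralogs=3,
        seed=1,
    )
    return generate_species_pair(cfg)


@pytest.fixture(scope="session")
def small_result(small_pair):
    """Full pipeline run on the small pair (shared across tests)."""
    a1, a2, b12, b21, _, _ = small_pair
    return map_atlases(
        a1,
        a2,
        hits_12=hits_from_frame(b12),
        hits_21=hits_from_frame(b21),
        num_iters=3,
        seed=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
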