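import sys
from pathlib import Path

import pytest

import mtstruct as m

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def two_pop_dataset():
    """Two moderately diverged populations, 8 + 9 individuals."""
    cfg = m.SimConfig(n_populations=2, n_per_population=[8, 9], region_length=300,
                      founder_divergence=5, within_theta=2, seed=11)
    dataset, truth = m.simulate_divergence_populations(cfg)
    return dataset, truth


@pytest.fixture
def grouped_dataset():
    """Four populations in two truth groups, unbalanced sizes."""
    cfg = m.SimConfig(n_populations=4, n_per_population=[5, 7, 6, 4],
                      region_length=250, founder_divergence=6, within_theta=2,
                      truth_groups=[[0, 1], [2, 3]], seed=23)
    dataset, truth = m.simulate_divergence_populations(cfg)
    return dataset, truth


@pytest.fixture
def kowalewko_metadata():
    return m.load_kowalewko_assignments()
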