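import numpy as np
import pytest

from icbreedsim.founders import (
    GeneticMap,
    GenomeSpec,
    designate_qtl,
    simulate_founder_haplotypes,
)
from icbreedsim.traits import (
    TraitArchitecture,
    sample_correlated_effects,
    scale_architecture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced genome for fast unit tests (the study-scale defaults are
    exercised in the acceptance suite)."""
    return GenomeSpec(crop="toy_crop", physical_length_bp=1e8, n_sites=300, n_qtl=100)


@pytest.fixture(scope="session")
def small_founders(small_spec):
    return simulate_founder_haplotypes(small_spec, seed=7, n_founders=30)


@pytest.fixture(scope="session")
def small_arch(small_founders):
    qtl = designate_qtl(small_founders, small_founders.spec.n_qtl, seed=8)
    eff_mc, eff_ic = sample_correlated_effects(qtl.size, R=0.5, seed=9)
    raw = TraitArchitecture(qtl, eff_mc, eff_ic, target_correlation=0.5)
    return scale_architecture(raw, small_founders)


@pytest.fixture(scope="session")
def unit_map():
    """Ten evenly spaced loci on a 1-Morgan chromosome."""
    return GeneticMap(np.linspace(0.05, 0.95, 10), 1.0)
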