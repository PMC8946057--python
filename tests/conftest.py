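import numpy as np
import pytest

from cinscore.genome import GenomeBuild, SampleProfile, Segment, default_build
from cinscore.simulate import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def build():
    return default_build()


@pytest.fixture(scope="session")
def small_build(build):
    """Default autosomes shrunk 1:1000 so per-base oracles are affordable."""
    return build.scaled(1e-3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw of the generator at default study conditions."""
    return simulate_cohort(GeneratorConfig(seed=7))


def flat_profile(build, ploidy=2.0, cn=None, sample_id="S1"):
    """A fully covered profile with one segment per chromosome."""
    cn = ploidy if cn is None else cn
    segs = [Segment(name, 0, length, cn) for name, length in build.chromosomes]
    return SampleProfile(sample_id=sample_id, segments=segs, ploidy=ploidy)
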