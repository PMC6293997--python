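import numpy as np
import pytest

from minicircles import (
    PipelineConfig,
    SeedIndex,
    SimulationConfig,
    make_host_genome,
    make_minicircle,
)


@pytest.fixture(scope="session")
def pcfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim_cfg() -> SimulationConfig:
    return SimulationConfig(seed=42, n_host_chrom=2, host_chrom_length=60_000)


@pytest.fixture(scope="session")
def small_refs(small_sim_cfg):
    """Two 60 kb chromosomes + virus, with the AT-window catalog."""
    return make_host_genome(small_sim_cfg)


@pytest.fixture(scope="session")
def small_index(small_refs, planted_template, pcfg):
    # built after template planting: junction homology is imprinted into the
    # host reference, and the index must see the final sequences
    refs, _ = small_refs
    return SeedIndex(refs, pcfg)


@pytest.fixture(scope="session")
def planted_template(small_refs, small_sim_cfg):
    """One sampled hybrid minicircle on the small genome."""
    refs, windows = small_refs
    rng = np.random.default_rng(11)
    return make_minicircle(
        refs.virus,
        refs,
        small_sim_cfg,
        rng,
        template_id="hybA",
        copy_number=30.0,
        window=windows[0],
    )
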