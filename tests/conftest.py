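import pytest

import embryolin as e


@pytest.fixture(scope="session")
def late_sim():
    """Default late-blastocyst dataset (300 cells, 3 studies, seed 0)."""
    cfg = e.late_blastocyst_config(0)
    m, ann, truth = e.simulate_dataset(cfg)
    return cfg, m, ann, truth


@pytest.fixture(scope="session")
def default_sim():
    """Full zygote-to-blastocyst time course (300 cells, seed 0)."""
    cfg = e.default_config(0)
    m, ann, truth = e.simulate_dataset(cfg)
    return cfg, m, ann, truth


@pytest.fixture(scope="session")
def hvg_sim():
    """Variable-gene fixture: 100 planted dispersed genes among 2000."""
    cfg = e.hvg_config(0)
    m, ann, truth = e.simulate_dataset(cfg)
    return cfg, m, ann, truth


@pytest.fixture(scope="session")
def noise_free_profiles():
    """Stage profiles computed on the noise-free limit of the default config."""
    from embryolin.simulate import noise_free
    from embryolin.staging import stage_profiles

    cfg = noise_free(e.default_config(0))
    m, ann, truth = e.simulate_dataset(cfg)
    return stage_profiles(m, ann), truth


@pytest.fixture(scope="session")
def module_sim():
    """Three planted 60-gene blocks (within-correlation 0.8, 200 cells)."""
    cfg = e.plant_module_blocks(e.module_config(200, 0), [60, 60, 60], 0.8)
    m, ann, truth = e.simulate_dataset(cfg)
    return cfg, e.log_transform(m), ann, truth


@pytest.fixture(scope="session")
def e5_sim():
    """E5 mixture with 45 planted early-ICM cells among 300."""
    cfg = e.e5_config(0)
    m, ann, truth = e.simulate_dataset(cfg)
    return cfg, m, ann, truth
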