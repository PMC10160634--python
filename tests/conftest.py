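import pytest

from chlorokin.pipeline import analyze_run, simulate_run, small_test_config
from chlorokin.protocol import build_protocol
from chlorokin.synthgen import (
    KineticParams,
    NoiseConfig,
    make_layout,
    render_stack,
)


@pytest.fixture(scope="session")
def default_protocol():
    return build_protocol()


@pytest.fixture(scope="session")
def tiny_layout():
    """2 variants × 3 cells on a 2×3 grid, 3 seedlings per cell."""
    return make_layout(
        variants=["wt", "mut"],
        rng_seed=7,
        grid_rows=2,
        areas_per_row=3,
        replicate_cells_per_variant=3,
        seeds_per_area=4,
        seedlings_per_cell=3,
    )


@pytest.fixture(scope="session")
def tiny_kinetics():
    return {"wt": KineticParams(), "mut": KineticParams(exp_onset=150.0)}


@pytest.fixture(scope="session")
def noiseless_sim(tiny_layout, default_protocol, tiny_kinetics):
    """Noiseless 64×64 rendered stack with ground truth."""
    stack, truth = render_stack(
        tiny_layout,
        default_protocol,
        tiny_kinetics,
        noise=NoiseConfig.zero(),
        rng_seed=7,
        image_shape=(64, 64),
    )
    return stack, truth


@pytest.fixture(scope="session")
def noisy_sim(tiny_layout, default_protocol, tiny_kinetics):
    stack, truth = render_stack(
        tiny_layout,
        default_protocol,
        tiny_kinetics,
        noise=NoiseConfig(),
        rng_seed=7,
        image_shape=(64, 64),
    )
    return stack, truth


@pytest.fixture(scope="session")
def analyzed_run():
    """Full simulate+analyze at reduced scale, onset shifted +30 min."""
    cfg = small_test_config(rng_seed=11, exp_onset_shift=30.0)
    sim = simulate_run(cfg, spectra_timepoints=())
    return sim, analyze_run(sim.stack, sim.layout, cfg)
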