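import numpy as np
import pytest

from mesomap import (
    ImagingStack,
    SynthConfig,
    UnitSpec,
    gaussian_motif,
    generate_session,
    indicator_kernel,
)


@pytest.fixture(scope="session")
def small_session():
    """A 16x16, 30 Hz, 60 s session with one planted unit (seeded)."""
    motif = gaussian_motif(16, 16, [(8.0, 8.0)], sigma_px=3.0, label="u0",
                           kernel=indicator_kernel(30.0))
    cfg = SynthConfig(n_frames=1800, frame_rate_hz=30.0, height=16, width=16,
                      units=[UnitSpec(motif=motif, firing_rate_hz=2.0, coupling=0.05)],
                      noise_sd=0.01, hemo_amplitude=0.02, seed=7)
    green, blue, trains, truth = generate_session(cfg)
    return {"config": cfg, "green": green, "blue": blue, "train": trains[0],
            "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def constant_stack():
    return ImagingStack(np.full((100, 4, 4), 100.0), frame_rate_hz=10.0)
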