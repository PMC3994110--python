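from __future__ import annotations

import numpy as np
import pytest

from srnaome import pipeline, sio, synthetic_data as sd


def run_synthetic_pipeline(
    seed: int,
    error_rate: float = 0.0,
    background_multiplier: float = 1.0,
    config: pipeline.PipelineConfig | None = None,
):
    """Generate a synthetic study and run the full pipeline on it."""
    ref = sd.make_reference(seed=seed)
    noise = sd.NoiseConfig(
        error_rate=error_rate, background_multiplier=background_multiplier
    )
    srna, degradome = sd.simulate_reads(ref, noise, seed=seed)
    inputs = pipeline.PipelineInputs(
        reads=srna,
        genome=ref.genome,
        transcripts=ref.transcripts,
        species_matures=ref.species_matures,
        plant_matures=ref.plant_matures,
        repeat_library=ref.repeat_library,
        degradome_reads=degradome,
    )
    cfg = config or pipeline.PipelineConfig(seed=seed)
    return ref, pipeline.run(cfg, inputs)


@pytest.fixture(scope="session")
def reference1():
    return sd.make_reference(seed=1)


@pytest.fixture(scope="session")
def clean_run1():
    """Zero-noise synthetic study, seed 1, with its pipeline result."""
    return run_synthetic_pipeline(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140421)


def make_read(seq: str, q: int = 35, read_id: str = "r") -> sio.ReadRecord:
    return sio.ReadRecord(read_id, seq, [q] * len(seq))
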