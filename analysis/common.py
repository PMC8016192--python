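"""Shared configuration of the analysis scripts.

All drivers run the same desk-scale emulation of the comparative
ensemble: 1/20 of the full frame counts (200 original records per
system), seed 1, the default overlapping anchor mixtures, and a
simulated assay link of 76% inhibition per unit bound-state occupancy
with 3% assay noise.
"""

from pathlib import Path

from allostate.experiment import ExperimentConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1
FRAME_SCALE = 0.05


def desk_config(**overrides) -> ExperimentConfig:
    params = dict(seed=SEED, frame_scale=FRAME_SCALE)
    params.update(overrides)
    return ExperimentConfig(**params)


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
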