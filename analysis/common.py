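"""Shared constants for the analysis scripts: one seed, one scenario."""

from pathlib import Path

from linscr.simulate import SimulationConfig

SEED = 2018
RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

# default study scenario: ~100-km sinuous dendritic network, 20 latrines,
# 8 occasions, hazard half-normal detection, replicate-PCR genotyping with
# the field error rates
CFG = SimulationConfig(lambda0_male=0.45, bk_beta=0.5, prop_male=0.45)
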