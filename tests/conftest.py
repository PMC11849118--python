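"""Shared fixtures: simulated study conditions run through the full pipeline.

The variant-like condition has mean focal-area counts free-A = 5.5,
free-B = 0.9, complexes = 4.5 (45% of A and ~83% of B complexed), the
WT-like condition free-A = 9.5, free-B = 0.85, complexes = 3.0 (24% of
A and ~78% of B complexed). Both use the default acquisition settings
(25,000 frames at 769 Hz). The fixtures are session-scoped because each
condition runs the complete simulate -> unmix -> correlate -> fit ->
summarize pipeline on 30 scans.
"""

import pytest

import fccs

N_SCANS = 30


@pytest.fixture(scope="session")
def variant_condition():
    config = fccs.SimulationConfig()  # defaults are the variant-like condition
    return fccs.simulate_and_analyze(config, N_SCANS, master_seed=2025, label="variant")


@pytest.fixture(scope="session")
def wt_condition():
    config = fccs.SimulationConfig(mean_free_a=9.5, mean_free_b=0.85, mean_complex=3.0)
    return fccs.simulate_and_analyze(config, N_SCANS, master_seed=4051, label="wt")
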