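"""Single-species sanity check: the FCS amplitude and dwell-time laws.

Simulates scans of one diffusing species (no complexes), correlates the
detection trace and fits the 2D diffusion model. The fitted amplitude
should approach 1/N_eff (N_eff the mean molecule count in the effective
focal area pi*w^2) and the dwell time w^2/(4D).
"""

import numpy as np

import fccs
from fccs.correlate import correlate
from fccs.fitfcs import fit_correlation

N_EFF = 10.0     # mean molecules in the focal area
D = 0.5          # um^2/s

config = fccs.SimulationConfig(
    mean_free_a=N_EFF, mean_free_b=0.0, mean_complex=0.0, diff_a=D, n_frames=25000
)
g0s, taus = [], []
for trace_a, _ in fccs.simulate_condition_traces(config, n_scans=8, master_seed=11):
    fit = fit_correlation(correlate(trace_a, trace_a), baseline_mode="free")
    g0s.append(fit.g0)
    taus.append(fit.tau_d)

expected_tau = config.beam_waist**2 / (4 * D)
print(f"fitted G0 (median of 8 scans): {np.median(g0s):.4f}   expected 1/N = {1/N_EFF:.4f}")
print(f"fitted tau_D (median, ms):     {1e3*np.median(taus):.2f}   expected w^2/4D = {1e3*expected_tau:.2f}")
print("G0 counts molecules in the spot; tau_D is the mean crossing time of the spot.")
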