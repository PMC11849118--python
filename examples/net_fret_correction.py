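"""Three-filter net-FRET correction on a synthetic scene.

Builds a donor-only control to measure the bleed-through slope alpha,
then corrects a scene with an injected sensitized-emission (FRET)
signal and quantifies the mean nFRET over the cell ROI.
"""

from fccs.fret import (
    CorrectionFactors,
    FretSceneParams,
    estimate_bleedthrough,
    net_fret,
    roi_mean,
    synth_fret_scene,
)

donor_only, truth = synth_fret_scene(
    FretSceneParams(shape=(256, 256), acceptor_level=0.0, fret_level=0.0), seed=1
)
acceptor_only, _ = synth_fret_scene(
    FretSceneParams(shape=(256, 256), donor_level=0.0, fret_level=0.0), seed=2
)
alpha = estimate_bleedthrough(donor_only, "donor")
beta = estimate_bleedthrough(acceptor_only, "acceptor")
print(f"estimated alpha = {alpha:.4f} (true {truth['factors'].alpha}), "
      f"beta = {beta:.4f} (true {truth['factors'].beta})")

scene_params = FretSceneParams(shape=(256, 256), fret_level=40.0)
scene, scene_truth = synth_fret_scene(scene_params, seed=3)
nfret = net_fret(scene, CorrectionFactors(alpha, beta))
mean_cell = roi_mean(nfret, scene_truth["cell_mask"])
print(f"mean nFRET over the cell ROI = {mean_cell:.1f} (injected {scene_params.fret_level})")
print("After removing donor bleed-through and acceptor cross-excitation, the")
print("corrected image recovers the injected sensitized-emission signal.")
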