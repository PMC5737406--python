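"""The complete pipeline on one synthetic study, scored against ground truth.

Runs extraction, initialisation (neighbour alignment, 3D similarity to the
later reference, oblique slice extraction), global intensity correction, the
staged joint motion + intensity registration, and TVL2 deconvolution; then
reports per-slice pose recovery and the five evaluation variants.
"""

import warnings

from filmrecon.pipeline import (
    PipelineConfig,
    pose_recovery_errors,
    run_evaluation,
    run_reconstruction,
)
from filmrecon.synth import FilmRenderSpec, PhantomSpec, make_phantom, make_reference, render_films

seed = 0
volume, brain, skull = make_phantom(PhantomSpec(seed=seed))
sheets, sidecar, gt = render_films(volume, brain, skull, FilmRenderSpec(seed=seed))
reference = make_reference(volume, brain, skull, atrophy_factor=0.95)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_reconstruction(sheets, sidecar, reference, PipelineConfig(seed=seed))
    report = run_evaluation(result.variants, gt.sharp_stack, gt.brain_mask)

err = pose_recovery_errors(gt, result.neighbour_poses, result.final_poses)
print("pose recovery against the rendered ground truth "
      "(modulo the global rigid frame):")
print(f"  mean |translation| = {err['translation_px'].mean():.3f} px")
print(f"  mean |rotation|    = {err['rotation_deg'].mean():.3f} deg")
print(f"  mean |scale - 1|   = {100 * err['scale_rel'].mean():.2f} %")

print("\nvariant quality over the ground-truth brain mask:")
for name, row in report.rows.items():
    print(f"  {name:22s} NCC={row['ncc']:.3f}  SSIM={row['ssim']:.3f}  "
          f"PSNR={row['psnr']:.2f} dB  edge motion={row['edge_motion']:.2f} vox")
print("\nmotion + intensity correction should dominate the naive variants, and "
      "the TVL2 variant should show the smallest brain-edge displacement.")
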