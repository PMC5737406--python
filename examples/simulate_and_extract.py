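"""Render synthetic MR films and extract the printed slices into a naive stack.

Builds the head phantom, prints its thick slices onto a film canvas with known
per-slice distortions, then runs the landmark-driven extraction and reports
how far the naive stack is from the sharp ground truth.
"""

import numpy as np

from filmrecon import extract_slices
from filmrecon.synth import FilmRenderSpec, PhantomSpec, make_phantom, render_films

volume, brain, skull = make_phantom(PhantomSpec(seed=0))
sheets, sidecar, gt = render_films(volume, brain, skull, FilmRenderSpec(seed=0))

stack = extract_slices(sheets, sidecar)
print(f"films rendered: {len(sheets)} sheet(s) of {sheets[0].pixels.shape} pixels")
print(f"extracted stack: {stack.n_slices} slices of {stack.data.shape[1:]} px, "
      f"provisional spacing {stack.spacing} mm")

rmse = np.sqrt(np.mean((stack.data - gt.sharp_stack.data) ** 2))
rots = [np.rad2deg(np.arctan2(m[1, 0], m[0, 0])) for m, _ in gt.poses]
print(f"RMS intensity error vs sharp truth: {rmse:.3f} (per-slice motion, blur and "
      "noise still present)")
print(f"true per-slice rotations span {min(rots):.1f} to {max(rots):.1f} degrees — "
      "this is what the joint registration must undo")
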