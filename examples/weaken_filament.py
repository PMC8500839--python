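"""Weaken the filament signal of a phantom micrograph.

Builds a straight-filament image with a bound particle and noise, then
subtracts the weighted average along the filament axis within a rectangle
mask slightly wider than the filament.  The filament disappears, the
particle and everything outside the mask stay.
"""

import numpy as np

from axonarray.micrograph import rasterize_mask, weaken_filament_signal
from axonarray.synthetic import SyntheticImageConfig, make_filament_image

cfg = SyntheticImageConfig(
    image_shape_px=(128, 256),
    filament_point_px=(128.0, 64.0),
    filament_width_px=10.0,
    filament_amplitude=2.0,
    particle_positions_px=((150.0, 64.0),),
    particle_amplitude=1.0,
    noise_sd=0.05,
    seed=3,
)
img, mask, truth = make_filament_image(cfg)
out = weaken_filament_signal(img, mask)
w = rasterize_mask(mask, img.pixels.shape)

inside = w > 0
print(f"mask width {mask.width_px:.0f} px (filament {cfg.filament_width_px:.0f} px)")
print(f"in-mask mean intensity:  before {img.pixels[inside].mean():+.3f}, "
      f"after {out.pixels[inside].mean():+.3f}")
print(f"outside-mask pixels identical: {np.array_equal(out.pixels[~inside], img.pixels[~inside])}")
py, px = int(truth.y_px[0]), int(truth.x_px[0])
print(f"particle peak at ({px},{py}): before {img.pixels[py, px]:.2f}, "
      f"after {out.pixels[py, px]:.2f}")
print("(the continuous filament averages out; the localized particle survives)")
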