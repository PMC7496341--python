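"""Reconstruct one scan with FBP, MAR 1 and MAR 2 and compare streaks.

The thresholds are calibrated once at the mid-range condition and frozen.
Prints the residual streak energy of each method against the metal-free
reference image (RMS outside the metal, 1/cm).
"""

import numpy as np
from scipy import ndimage

from marbench import PRESETS, build_phantom, fbp
from marbench.projector import counts_to_log_sinogram, detect_counts
from marbench.study import ImagingPipeline, iron_pixel_mask

pipe = ImagingPipeline(PRESETS["desk"], lump_seed=0)
print(f"frozen thresholds: MAR1 log-attenuation {pipe.thresholds.log_threshold:.2f}, "
      f"MAR2 {pipe.thresholds.hu_threshold:.0f} HU")

phantom = build_phantom(inset_angle=1.2, lump_field=pipe.lump_field)
rng = np.random.default_rng(2)
sino = pipe.log_sinogram(phantom, dose=pipe.settings.cal_dose, rng=rng)
images = pipe.reconstruct_all(sino, ["fbp", "mar1", "mar2"])

# metal-free reference with the same acquisition settings
mats = {m: v for m, v in pipe.material_sinograms(phantom).items() if m != "iron"}
ref_sino = counts_to_log_sinogram(detect_counts(
    mats, pipe.spectrum, pipe.tables, pipe.geometry,
    I0=pipe.settings.cal_dose, s0=pipe.settings.s0, seed=None,
))
reference = fbp(ref_sino, out_size=pipe.settings.image_size).pixels

metal = iron_pixel_mask(phantom, pipe.settings.image_size, pipe.settings.fov)
outside = ~ndimage.binary_dilation(metal, iterations=2)
for name, img in images.items():
    rms = np.sqrt(np.mean((img - reference)[outside] ** 2))
    print(f"  {name:5s} streak energy {rms:.4f} /cm")
print("lower is better: both MAR variants suppress streaks at the "
      "calibration dose, image-domain segmentation (MAR 2) most.")
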