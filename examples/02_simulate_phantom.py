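"""Generate a virtual-cell force volume and round-trip it through the container.

The phantom is a dome-shaped cell with tensile stress fibers (+20 kPa) over
a compressive background (-5 kPa); the virtual instrument indents every
pixel until the 3 nN trigger and adds Gaussian force noise.
"""

import tempfile
from pathlib import Path

from prestressmap import (AcquisitionConfig, make_phantom, read_force_volume,
                          simulate_spectrum_image, write_force_volume)

ph = make_phantom(seed=0)   # 32 x 32, 0.5 um pitch by default
img, gt = simulate_spectrum_image(ph, AcquisitionConfig(noise_rms=0.03e-9, seed=0))

n_px = len(img.curves)
n_full = sum(c.flag is None for c in img.curves.values())
lens = [c.n_samples for c in img.curves.values()]
print(f"{img.nx} x {img.ny} force volume, pitch {img.pixel_pitch*1e6:.1f} um")
print(f"curves: {n_px} ({n_full} trigger-terminated), "
      f"{min(lens)}-{max(lens)} samples each (10 nm depth steps)")
print(f"dome height {img.topography.max()*1e6:.1f} um; "
      f"fiber pixels {gt.fiber_mask.sum()} with sigma = "
      f"{gt.sigma[gt.fiber_mask][0]/1e3:.0f} kPa, background "
      f"{gt.sigma[~gt.fiber_mask & (gt.sigma != 0)][0]/1e3:.0f} kPa")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cell.h5"
    write_force_volume(img, path, format="hdf5")
    back = read_force_volume(path, format="hdf5")
    print(f"container round trip identical: {back == img}")
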