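"""Measure the blur scale and contrast of a synthetic edge.

A Gaussian-blurred step edge with known blur scale omega0 and contrast
c0 is rendered, then analyzed with the multiscale FDAG bank.  The scale
map should select omega0 on the edge centerline and the scale-compensated
edge strength should recover c0.
"""

import math

import numpy as np

from fdagseg import (
    BankConfig,
    EdgeModelParams,
    anisotropic_edge_strength,
    scaled_edge_image,
)
from fdagseg.kernels import directions_from_count

omega0, c0, b0 = 1.3, 0.6, 0.2
params = EdgeModelParams(omega0=omega0, theta0=0.0, c0=c0, b0=b0)
image = scaled_edge_image((64, 64), params)

config = BankConfig(
    scales=tuple(round(0.8 + 0.1 * i, 1) for i in range(11)),
    directions=directions_from_count(8),
    control_scale=1.2,
)
result = anisotropic_edge_strength(image, config, rescale=False)

center_col = 32
on_centerline = result.Enms[:, center_col] > 0
selected_scale = result.Smap[on_centerline, center_col].mean()
peak_response = result.E[on_centerline, center_col].mean()
recovered_contrast = result.Ie[on_centerline, center_col].mean()

print(f"true edge blur scale omega0 = {omega0}, contrast c0 = {c0}")
print(f"selected scale on centerline      : {selected_scale:.2f}")
print(f"peak response (expected c0/sqrt(omega0) = "
      f"{c0 / math.sqrt(omega0):.4f}) : {peak_response:.4f}")
print(f"scale-compensated edge strength   : {recovered_contrast:.4f}")
print()
print("The selected scale matches the edge blur scale and multiplying the")
print("peak by sqrt(scale) recovers the step contrast, so the edge-strength")
print("map reflects contrast independently of how blurred an edge is.")
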