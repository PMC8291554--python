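"""Dual-channel cell counting on a PVN-like phantom.

Renders a two-channel phantom with known class counts (834 CRH-like
somata in red, 430 of them carrying a c-Fos-like nucleus in green, plus
25 green-only cells), runs the DoG/watershed detector independently per
channel, links the per-plane segments into 3D records, and pairs the two
channels by mutual nearest neighbors.
"""

from visor.detection import colocalize, detect_cells
from visor.phantom import pvn_preset, render_phantom

spec = pvn_preset(seed=0)
vols, truth = render_phantom(spec)
print(f"phantom volume {vols['red'].shape} (z, y, x) at "
      f"{spec.spacing_um} um spacing, {len(truth.cells)} ground-truth cells")

rec_red = detect_cells(vols["red"], spec.spacing_um, channel="red")
rec_green = detect_cells(vols["green"], spec.spacing_um, channel="green")
n_red, n_green, n_double = colocalize(rec_red, rec_green, radius_um=6.0)

print(f"red (CRH-like) somata   : {n_red} detected, truth 834")
print(f"green (c-Fos-like) cells: {n_green} detected, truth 455")
print(f"double positive          : {n_double} paired,  truth 430")
print(f"=> {100 * n_double / n_red:.0f}% of CRH-like cells activated "
      "(the phantom was built from a stimulated-animal count profile)")
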