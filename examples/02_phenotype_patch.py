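"""Round-trip a rendered immunofluorescence patch through the classifier.

Cells with known CD8/PD-L1 states are rendered as Gaussian blobs, the
channels min–max normalised, and each cell called positive when its mean
intensity over an 11-pixel circular neighbourhood reaches 32/256 = 0.125.
"""

import numpy as np
import pandas as pd

import immunocontext as ic

rng = np.random.default_rng(0)
grid = np.arange(15.0, 85.0, 22.0)
xs, ys = np.meshgrid(grid, grid)
pts = np.column_stack([xs.ravel(), ys.ravel()])[:10]
cells = pd.DataFrame({
    "x_um": pts[:, 0],
    "y_um": pts[:, 1],
    "cd8": rng.random(10) < 0.5,
    "pdl1": rng.random(10) < 0.3,
})

rasters = ic.render_if_patch(cells, ["CD8", "PDL1"], (100.0, 100.0), rng=rng)
channels = {ch: ic.normalize_channel(r) for ch, r in rasters.items()}
centres = pts / 0.5  # μm → px at 0.5 μm/px
flags = ic.classify_markers(centres, channels)

for ch in ("CD8", "PDL1"):
    truth = cells[ch.lower()].to_numpy()
    called = flags[ch].to_numpy()
    print(f"{ch}: {int((called == truth).sum())}/10 flags recovered")
# at default rendering noise the threshold classifier recovers the
# ground-truth marker states of well-separated nuclei essentially always
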