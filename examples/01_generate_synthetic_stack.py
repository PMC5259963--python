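"""Generate the calibrated intact-eye synthetic stack and write it to disk.

Builds the ground-truth label volume (cornea | TM band | sclera, with the
Schlemm's-canal and aqueous-vein voids), renders it through the two-photon
imaging model, and saves multi-page TIFFs plus JSON metadata sidecars.
"""

from pathlib import Path

import numpy as np

import limbuskit as lk

out = Path("scratch/example_scene")
out.mkdir(parents=True, exist_ok=True)

config = lk.default_intact_config()
labels = lk.build_labels(config)
stack = lk.render_intensities(labels, config)

config.to_json(out / "config.json")
lk.write_labels(labels, out / "labels.tif")
lk.write_stack(stack, out / "stack.tif")

print(f"stack shape {stack.shape}, depths {stack.depths[0]:.0f}–"
      f"{stack.depths[-1]:.0f} μm at {stack.axial_step:.0f} μm steps")
for lab, name in sorted(labels.legend.items()):
    frac = np.mean(labels.labels == lab)
    print(f"  {name:<11s} {100 * frac:5.1f} % of voxels")
print(f"written to {out}/")
# The TM band holds both beam and pore voxels; their per-slice ratio is the
# ground-truth porosity that the analysis pipeline has to recover.
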