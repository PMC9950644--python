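"""Build the per-tree feature table and correlate features with conductance.

Per tree: mean canopy reflectance in four bands, seven vegetation indices
from those means, and eight GLCM texture statistics per band computed over
canopy pixels only.  Pearson correlations against measured stomatal
conductance show which features carry the water-stress signal.
"""

import pandas as pd

from canopysc import features as feat
from canopysc import segmentation as seg
from canopysc import synthetic as syn

scenes = syn.generate_scene_batch(15, seed=21)  # 60 trees
masks = [seg.hsv_segment(s.rgb).mask for s in scenes]
sc = pd.concat([s.sc_table() for s in scenes], ignore_index=True)

table = feat.build_feature_table(scenes, masks, sc)
print(f"feature table: {table.shape[0]} trees x {table.shape[1]} columns")

corr = feat.correlation_table(table).set_index("feature")["r"]
show = ["b560", "b650", "b725", "b808", "ndvi", "ndre", "rvi",
        "b808_con", "b808_cor", "b808_var", "b560_cor"]
print("\nPearson r with Sc:")
for c in show:
    print(f"  {c:10s} {corr[c]:+.3f}")
print(
    "\nNIR reflectance and 808 nm contrast fall with conductance (stress"
    "\nraises both), 808 nm correlation tracks it positively, and the"
    "\n560 nm texture carries almost nothing — the 808 nm band is where"
    "\nthe texture signal lives."
)
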