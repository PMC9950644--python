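"""Compare canopy segmentation methods against the ground-truth mask.

HSV gating (hue/saturation/value ranges) is scored against Otsu thresholding
of each visible-light vegetation index, with intersection-over-reference
accuracy (ACC), Matthews correlation (MCC) and IOU.
"""

import numpy as np

from canopysc import segmentation as seg
from canopysc import synthetic as syn

scene = syn.generate_scene(syn.SceneConfig(seed=3))

rows = []
m = seg.hsv_segment(scene.rgb)
rows.append(("HSV", seg.score_mask(m, scene.truth_mask)))
for vi in seg.VISIBLE_VI_NAMES:
    m = seg.otsu_vi_segment(scene.rgb, vi)
    rows.append((f"Otsu/{vi}", seg.score_mask(m, scene.truth_mask)))

print(f"{'method':12s} {'IOU':>7s} {'ACC%':>7s} {'MCC':>7s}")
for name, s in sorted(rows, key=lambda r: -r[1].mcc):
    print(f"{name:12s} {s.iou:7.4f} {s.acc:7.2f} {s.mcc:7.4f}")
print(
    "\nHSV gating rejects dark canopy-cast shadow (low V) and ochre litter"
    "\n(hue below the green gate) that greenness-only thresholds admit, so"
    "\nits MCC leads; indices weakly tied to greenness (BRRI, EXR) trail."
)
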