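"""Corner counts across the curvature-scale-space smoothing width.

Detects margin corners on one serrate leaf at several Gaussian widths
(delta).  Counts shrink as delta grows: fine serration detail is
smoothed away first, so dense-toothed leaves want a small delta and
sparse-toothed leaves a larger one.
"""

from leaftooth import CSSParams, detect_corners, extract_contour, segment
from leaftooth.synthetic import SyntheticLeafSpec, generate_leaf

spec = SyntheticLeafSpec(n_teeth=20, tooth_amplitude=32.0, seed=7)
image, truth = generate_leaf(spec)

contour = extract_contour(segment(image))
print(f"leaf with {truth.n_teeth} teeth "
      f"(expected corners: {2 * truth.n_teeth} = apices + sinuses)\n")
print("delta   corners detected")
for delta in (2, 4, 5, 6, 7):
    corners = detect_corners(contour, CSSParams(delta=delta))
    print(f"{delta:>5}   {len(corners)}")
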