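"""Render a synthetic HER2-stained TMA spot and score it end to end.

Generates a 400-µm spot whose cells carry membrane staining over 70% of
their perimeter, runs tissue detection, ROI margin, stain separation,
membrane segmentation and the connectivity statistic, and prints the
result.  Connectivity near 0 means only short membrane fragments (score
0/1+); near 1 means long connected membrane chains (score 3+).
"""

from memconnect import SpotSimParams, analyze_spot, generate_spot_image

params = SpotSimParams(
    n_cells=80,
    spot_diameter_um=400.0,
    membrane_completeness=0.7,
    seed=42,
)
image, truth = generate_spot_image(params)
result = analyze_spot(image)

cr = result.connectivity_result
print(f"status:            {result.status}")
print(f"ROI area:          {result.roi.area_um2:.0f} um^2 (adequate: {result.roi.adequate})")
print(f"membrane fragments:{cr.n_fragments:4d}  (total skeleton {cr.total_skeleton_px} px)")
print(f"connectivity:      {cr.connectivity:.4f}")
print(f"HER2 score:        {cr.her2_score}")
print()
print("With 70% membrane completeness most membrane lies in long linked")
print("chains, so the connectivity lands above the 0.56 cut-point -> 3+.")
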