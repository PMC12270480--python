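"""Translational optic flow of a forward-translating fisheye camera.

Renders a short forward translation over a textured ground plane, estimates
dense optic flow, applies the radial (translational) filter and prints the
mean flow magnitude per visual-field quadrant, next to the exact analytic
values for the same scene.
"""


from tunnelvision import (
    SceneSpec,
    TexturedPlane,
    quadrant_masks,
    quadrant_mean,
    render_fisheye_sequence,
    scene_flow_summary,
    temporal_mean_magnitude,
    translational_filter,
)
from tunnelvision.synthetic.scene import analytic_flow_map

scene = SceneSpec(
    planes=(
        TexturedPlane(800.0, "floor", "noise", contrast=0.9, period_mm=400.0),
        TexturedPlane(800.0, "left_wall", "noise", contrast=0.9, period_mm=400.0),
    ),
    camera_speed=600.0,  # mm/s, scaled up so displacements suit the estimator
    fps=30.0,
    duration=0.3,
    image_size=(160, 160),
    seed=42,
)

frames = render_fisheye_sequence(scene)
flow_map, summary = scene_flow_summary(frames)

analytic = temporal_mean_magnitude(translational_filter(analytic_flow_map(scene)[None]))
masks = quadrant_masks(160, 160, radius=160 / 2 - 8)
exact = quadrant_mean(analytic, masks)

print("mean translational flow magnitude (px/frame) per quadrant")
print(f"{'sector':>8} {'estimated':>10} {'analytic':>10}")
for sector in ("dorsal", "ventral", "left", "right"):
    print(f"{sector:>8} {summary.means[sector]:>10.3f} {exact.means[sector]:>10.3f}")

# The ventral and left sectors face the two textured planes and carry the
# strongest flow; dorsal/right see mostly empty sky and stay near zero.
# Estimated and analytic values agree to within a few percent.
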