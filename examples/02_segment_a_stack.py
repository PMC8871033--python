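"""Extract the flow domain from a grayscale stack by reaction-diffusion
region growth.

The indicator field R grows from automatically found seeds at a rate gated
by the local gray level (dR/dt = max{0, C1(I-1)+1} * lap R, with R > C2
accelerated to 1), the 0.5 contour of R is traced per slice, and the
contours are fused into a 3-D voxel mask.  Against the phantom's ground
truth we can score the recovery.
"""

from septalflow import (make_two_chamber_phantom, render_image_stack,
                        segment_stack)

spec = make_two_chamber_phantom(defect_open=True)
stack = render_image_stack(spec, blur_sigma=1.0, noise_sigma=0.05, seed=7)

mask = segment_stack(stack, c1=1.0, c2=0.7)

gt = spec.ground_truth_mask.fluid
seg = mask.fluid
jaccard = (gt & seg).sum() / (gt | seg).sum()
print(f"ground truth: {gt.sum()} fluid voxels; segmented: {seg.sum()}")
print(f"Jaccard overlap: {jaccard:.3f}")
# A Jaccard above 0.9 means the recovered lumen differs from the true one
# by well under half a voxel of surface placement on average — enough to
# hand the mask straight to the flow solver.
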