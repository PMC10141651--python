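"""The four occlusion geometries of the self-supervised pretext task."""

import numpy as np
from scipy import ndimage

from fusionseg import PhantomSpec, generate_case, make_mask, apply_masks, similarity_loss
from fusionseg.nn import Tensor

for strategy in ("block20", "block50", "grid", "random"):
    mask, spec = make_mask(strategy, 224, seed=5)
    n_comp = ndimage.label(mask)[1]
    print(
        f"{strategy:8s} masks {int(mask.sum()):4d} px in {n_comp:3d} component(s), "
        f"window origin {spec.window_origin}"
    )

# per-modality occlusion: each modality gets its own window position, so the
# unmasked modalities still carry the occluded information
case = generate_case(PhantomSpec(image_side=64, seed=2))
masked, specs, masks = apply_masks(case, "block20", seed=1)
print("\nper-modality origins:", [s.window_origin for s in specs])
outside = ~np.any(masks, axis=0)
untouched = all((m[outside] == c[outside]).all() for m, c in zip(masked.images, case.images))
print("pixels outside every mask untouched:", untouched)

# the similarity loss the masked branch is trained against
a = Tensor(np.abs(np.random.default_rng(0).standard_normal((1, 8, 4, 4))).astype(np.float32))
b = Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32))
b.data[0, :4] = a.data[0, :4]  # half-overlapping features
print(
    f"\nsimilarity loss: identical {similarity_loss(a, a).item():.4f}, "
    f"partial {similarity_loss(a, b).item():.4f} "
    "(0 = occlusion-invariant features, 1 = unrelated)"
)
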