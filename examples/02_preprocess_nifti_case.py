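"""Round-trip a case through NIfTI and the slice-preprocessing pipeline."""

import tempfile
import warnings
from pathlib import Path

import numpy as np

from fusionseg import PhantomSpec, case_to_slices, generate_volume, load_case
from fusionseg.phantom import write_case_nifti
from fusionseg.preprocess import slice_window

# the centered slice window: a 155-deep BraTS volume keeps indices 5..148
win = slice_window(155)
print(f"depth 155 -> keep {len(win)} slices, indices {win[0]}..{win[-1]}")

with tempfile.TemporaryDirectory() as tmp:
    case_dir = Path(tmp) / "phantom000"
    volumes, labels = generate_volume(PhantomSpec(image_side=64, seed=3), depth=10)
    write_case_nifti(case_dir, "phantom000", volumes, labels)
    print("wrote:", sorted(p.name for p in case_dir.iterdir()))

    case = load_case(case_dir)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # depth 10 < 144: everything is kept
        ds = case_to_slices(case, crop=48)

    stack = ds.stacks[0]
    print(f"{len(ds)} slices of shape {stack.shape}, {stack.n_modalities} modalities")
    brain = stack.images[0] != 0
    print(
        f"normalized brain region: mean {stack.images[0][brain].mean():+.4f}, "
        f"sd {stack.images[0][brain].std():.4f}; background stays 0: "
        f"{bool((stack.images[0][~brain] == 0).all())}"
    )
    print("internal label values:", np.unique(stack.labels).tolist())
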