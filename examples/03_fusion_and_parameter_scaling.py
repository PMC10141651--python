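"""The hybrid fusion block and how it changes parameter scaling."""

import numpy as np

from fusionseg import NetworkConfig, count_parameters
from fusionseg.fusion import HAFB, hybrid_fuse
from fusionseg.nn import Tensor

rng = np.random.default_rng(0)
maps = [Tensor(rng.standard_normal((1, 8, 16, 16)).astype(np.float32)) for _ in range(4)]

# sum/product/max fusion: 4 maps of 8 channels -> one map of 24 channels
fused = hybrid_fuse(maps)
print(f"fused 4 x 8-channel maps -> {fused.shape[1]} channels (always 3C)")
perm = hybrid_fuse([maps[3], maps[1], maps[0], maps[2]])
print("bit-identical under modality permutation:", bool((fused.data == perm.data).all()))

block = HAFB(8, rng)
out = block(maps)
gate = block.attention.last_gate
print(f"attention gate range: ({gate.min():.3f}, {gate.max():.3f})  output {out.shape}")

# parameter counts over 1..6 modalities, reference width (base 32)
print("\nmodalities   plain (M)   +fusion (M)")
for n in range(1, 7):
    plain = count_parameters(NetworkConfig(n_modalities=n, use_hafb=False))
    fuse = count_parameters(NetworkConfig(n_modalities=n, use_hafb=True))
    marker = "<-- fusion smaller" if fuse < plain else ""
    print(f"  {n}          {plain/1e6:8.2f}    {fuse/1e6:8.2f}   {marker}")

# the fusion variant grows linearly (constant first differences), the plain
# variant quadratically (constant second differences): pinning the skip
# bundle at 3C is what keeps the decoder independent of the modality count
fused_counts = [count_parameters(NetworkConfig(n_modalities=n, use_hafb=True)) for n in range(1, 7)]
plain_counts = [count_parameters(NetworkConfig(n_modalities=n, use_hafb=False)) for n in range(1, 7)]
print("fusion first differences: ", set(np.diff(fused_counts).tolist()))
print("plain second differences: ", set(np.diff(plain_counts, n=2).tolist()))
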