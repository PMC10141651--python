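"""Synthetic multi-modal brain-tumor phantoms.

Each phantom slice emulates the layout of a BraTS-style case: four
co-registered MRI modalities (T1, T1CE, FLAIR, T2) of the same anatomy,
with an integer label map whose classes nest like real gliomas — an edema
ellipse (class 2) containing a necrotic/non-enhancing core (class 1) that
in turn contains an enhancing blob (class 3, the raw BraTS class 4). The
brain is a noisy elliptical disc on a zero background.

Each modality renders the same geometry with its own per-class mean
intensity. The means are chosen so that no single modality separates all
four classes (e.g. enhancing tumor is isointense with brain on T1, edema
with brain on T1CE), which makes multi-modal fusion genuinely informative
on these phantoms rather than decorative.

These phantoms are deliberately simple: no bias fields, no anatomy, no 3-D
tumor growth. They exist so every downstream stage — preprocessing, the
network, the pretext task, training, evaluation — can be exercised and
tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "ModalityStack",
    "MODALITY_NAMES",
    "CLASS_MEANS",
    "generate_case",
    "generate_volume",
    "write_case_nifti",
]

MODALITY_NAMES = ("t1", "t1ce", "flair", "t2")

#: per-modality mean intensity for [brain tissue, class 1, class 2, class 3];
#: within each modality at least two classes are (near-)isointense, across
#: modalities every class is distinguishable
CLASS_MEANS = {
    "t1": (0.50, 0.30, 0.45, 0.50),
    "t1ce": (0.45, 0.28, 0.46, 0.90),
    "flair": (0.40, 0.55, 0.85, 0.55),
    "t2": (0.35, 0.60, 0.80, 0.62),
}


def modality_name(index: int) -> str:
    """Name for modality ``index``; beyond the four MRI sequences, numbered."""
    if index < len(MODALITY_NAMES):
        return MODALITY_NAMES[index]
    return f"mod{index}"


def _class_means(index: int) -> np.ndarray:
    base = np.array(CLASS_MEANS[MODALITY_NAMES[index % 4]])
    # extra synthetic modalities get a small offset so they stay distinct
    return base + 0.02 * (index // 4 + (1 if index >= 4 else 0))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case."""

    image_side: int = 64
    n_modalities: int = 4
    noise_sd: float = 0.05
    tumor_fraction_range: tuple[float, float] = (0.05, 0.15)
    seed: int = 0

    def __post_init__(self):
        if self.image_side < 32:
            raise ValueError(f"image_side must be >= 32, got {self.image_side}")
        if self.n_modalities < 1:
            raise ValueError("n_modalities must be >= 1")
        lo, hi = self.tumor_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"tumor fractions must satisfy 0 < lo < hi < 1, got {lo}, {hi}")


@dataclass
class ModalityStack:
    """One case: co-registered per-modality 2-D images plus a label map.

    Labels use the internal encoding {0, 1, 2, 3}; 3 stands for the raw
    BraTS class 4 (enhancing tumor).
    """

    images: list[np.ndarray]
    labels: np.ndarray
    case_id: str = ""
    slice_index: int = 0
    modality_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError(f"modality images disagree in shape: {sorted(shapes)}")
        if self.labels.shape != self.images[0].shape:
            raise ValueError("labels shape differs from image shape")
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"labels contain values outside {{0,1,2,3}}: {sorted(bad)}")
        if not self.modality_names:
            self.modality_names = tuple(modality_name(i) for i in range(len(self.images)))

    @property
    def n_modalities(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def as_array(self) -> np.ndarray:
        """Stack modalities into a (n_modalities, H, W) float32 array."""
        return np.stack(self.images).astype(np.float32)


def _ellipse_mask(side: int, center, axes, angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    cy, cx = center
    a, b = axes
    c, s = np.cos(angle), np.sin(angle)
    u = (yy - cy) * c + (xx - cx) * s
    v = -(yy - cy) * s + (xx - cx) * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _tumor_geometry(rng: np.random.Generator, side: int, frac_range) -> np.ndarray | None:
    """Sample nested tumor label geometry; returns labels or None on a bad draw."""
    lo, hi = frac_range
    span = hi - lo
    target = rng.uniform(lo + 0.15 * span, hi - 0.15 * span)
    area = target * side * side
    aspect = rng.uniform(0.75, 1.3)
    a = np.sqrt(area * aspect / np.pi)
    b = np.sqrt(area / (aspect * np.pi))
    angle = rng.uniform(0.0, np.pi)
    brain_r = 0.42 * side
    brain_c = (side / 2.0, side / 2.0)
    margin = brain_r - max(a, b) - 1.0
    if margin <= 0:
        return None
    # uniform center inside the disc that keeps the tumor within the brain
    r = margin * np.sqrt(rng.uniform())
    phi = rng.uniform(0.0, 2 * np.pi)
    center = (brain_c[0] + r * np.sin(phi), brain_c[1] + r * np.cos(phi))

    edema = _ellipse_mask(side, center, (a, b), angle)
    jitter = rng.uniform(-0.12, 0.12, size=2) * min(a, b)
    core = _ellipse_mask(side, (center[0] + jitter[0], center[1] + jitter[1]), (0.62 * a, 0.62 * b), angle)
    core &= edema
    jitter2 = rng.uniform(-0.15, 0.15, size=2) * min(a, b)
    enh = _ellipse_mask(
        side, (center[0] + jitter[0] + jitter2[0], center[1] + jitter[1] + jitter2[1]), (0.32 * a, 0.32 * b), angle
    )
    enh &= core

    labels = np.zeros((side, side), dtype=np.int64)
    labels[edema] = 2
    labels[core] = 1
    labels[enh] = 3
    frac = (labels > 0).mean()
    if not (lo <= frac <= hi):
        return None
    return labels


def generate_case(spec: PhantomSpec) -> ModalityStack:
    """Generate one synthetic multi-modal slice; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    labels = None
    for _ in range(200):
        labels = _tumor_geometry(rng, side, spec.tumor_fraction_range)
        if labels is not None:
            break
    if labels is None:
        raise ValueError(
            "could not place a tumor with the requested fraction range inside the brain disc"
        )
    brain = _ellipse_mask(side, (side / 2.0, side / 2.0), (0.42 * side, 0.42 * side), 0.0)
    images = []
    for m in range(spec.n_modalities):
        means = _class_means(m)
        img = np.zeros((side, side), dtype=np.float32)
        img[brain] = means[0]
        for cls in (1, 2, 3):
            img[labels == cls] = means[cls]
        noise = rng.normal(0.0, spec.noise_sd, size=(side, side)).astype(np.float32)
        img[brain] += noise[brain]
        images.append(img)
    return ModalityStack(images=images, labels=labels, case_id=f"phantom-{spec.seed}")


def generate_volume(
    spec: PhantomSpec, depth: int
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Stack per-slice phantoms into (side, side, depth) volumes.

    Returns a modality-name -> 3-D array map plus a 3-D label volume in the
    raw BraTS encoding {0, 1, 2, 4}.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    side = spec.image_side
    names = [modality_name(i) for i in range(spec.n_modalities)]
    volumes = {nm: np.zeros((side, side, depth), dtype=np.float32) for nm in names}
    label_vol = np.zeros((side, side, depth), dtype=np.int16)
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(depth)
    for z in range(depth):
        slice_spec = PhantomSpec(
            image_side=side,
            n_modalities=spec.n_modalities,
            noise_sd=spec.noise_sd,
            tumor_fraction_range=spec.tumor_fraction_range,
            seed=int(child_seeds[z] % (2**31)),
        )
        stack = generate_case(slice_spec)
        for nm, img in zip(names, stack.images):
            volumes[nm][:, :, z] = img
        raw = stack.labels.copy()
        raw[raw == 3] = 4
        label_vol[:, :, z] = raw
    return volumes, label_vol


def phantom_dataset(
    n_cases: int,
    spec: PhantomSpec | None = None,
    normalize_intensity: bool = True,
) -> list[ModalityStack]:
    """A list of independent phantom slices, seeded from ``spec.seed``.

    With ``normalize_intensity`` each modality image is z-scored over its
    nonzero pixels, matching what the preprocessing pipeline feeds the
    network for real cases.
    """
    from .preprocess import normalize

    if spec is None:
        spec = PhantomSpec()
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_cases)
    out = []
    for i in range(n_cases):
        child = PhantomSpec(
            image_side=spec.image_side,
            n_modalities=spec.n_modalities,
            noise_sd=spec.noise_sd,
            tumor_fraction_range=spec.tumor_fraction_range,
            seed=int(seeds[i] % (2**31)),
        )
        stack = generate_case(child)
        if normalize_intensity:
            stack = ModalityStack(
                images=[normalize(im) for im in stack.images],
                labels=stack.labels,
                case_id=stack.case_id,
                slice_index=stack.slice_index,
                modality_names=stack.modality_names,
            )
        out.append(stack)
    return out


def write_case_nifti(out_dir, case_id: str, volumes: dict[str, np.ndarray], labels: np.ndarray) -> list:
    """Write one case as NIfTI files named ``{case_id}_{modality}.nii.gz``.

    The label volume (raw encoding {0,1,2,4}) goes to ``{case_id}_seg.nii.gz``.
    """
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    affine = np.eye(4)
    written = []
    for nm, vol in volumes.items():
        path = os.path.join(out_dir, f"{case_id}_{nm}.nii.gz")
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)
        written.append(path)
    seg_path = os.path.join(out_dir, f"{case_id}_seg.nii.gz")
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), seg_path)
    written.append(seg_path)
    return written
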