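"""Reading BraTS-style NIfTI cases and slicing them into training inputs.

The raw cases are 3-D volumes (240x240x155 in BraTS) of four co-registered
modalities plus an integer label volume in the encoding {0, 1, 2, 4}. The
pipeline keeps the centered run of 144 axial slices, center-crops each
slice to 224x224, remaps label 4 to the contiguous internal value 3, and
z-scores intensities over the nonzero (brain) region of each slice and
modality. The axial axis is the third array axis; neither the slice-window
offset nor the normalization is dictated by the data format, so both are
plain functions that callers can swap out.
"""

from __future__ import annotations

import glob
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import ModalityStack

__all__ = [
    "MODALITY_SUFFIXES",
    "RawCase",
    "SliceDataset",
    "slice_window",
    "select_slices",
    "center_crop",
    "crop_offset",
    "remap_labels",
    "restore_labels",
    "normalize",
    "load_case",
    "case_to_slices",
    "embed_prediction",
    "write_prediction",
]

MODALITY_SUFFIXES = ("t1", "t1ce", "flair", "t2")
DEFAULT_N_SLICES = 144
DEFAULT_CROP = 224

RAW_LABELS = (0, 1, 2, 4)
_REMAP = {0: 0, 1: 1, 2: 2, 4: 3}
_RESTORE = {0: 0, 1: 1, 2: 2, 3: 4}


@dataclass
class RawCase:
    """One case's modality volumes and label volume, as read from disk."""

    modality_volumes: dict[str, np.ndarray]
    label_volume: np.ndarray | None
    case_id: str = ""

    def __post_init__(self):
        if not self.modality_volumes:
            raise ValueError("a case needs at least one modality volume")
        shapes = {v.shape for v in self.modality_volumes.values()}
        if self.label_volume is not None:
            shapes.add(self.label_volume.shape)
        if len(shapes) != 1:
            raise ValueError(f"volumes disagree in shape: {sorted(shapes)}")

    @property
    def depth(self) -> int:
        return next(iter(self.modality_volumes.values())).shape[2]


@dataclass
class SliceDataset:
    """Ordered 2-D training samples with (case_id, slice_index) provenance."""

    stacks: list[ModalityStack] = field(default_factory=list)
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.stacks)

    def __getitem__(self, i) -> ModalityStack:
        return self.stacks[i]

    def __iter__(self):
        return iter(self.stacks)

    def extend(self, other: "SliceDataset") -> None:
        self.stacks.extend(other.stacks)
        self.provenance.extend(other.provenance)


def slice_window(depth: int, n_slices: int = DEFAULT_N_SLICES) -> range:
    """Index range of the centered ``n_slices`` axial slices.

    For depth D the window starts at floor((D - n) / 2); a 155-deep BraTS
    volume keeps indices 5..148. Shallower volumes keep everything.
    """
    if depth <= n_slices:
        return range(depth)
    start = (depth - n_slices) // 2
    return range(start, start + n_slices)


def select_slices(volume: np.ndarray, n_slices: int = DEFAULT_N_SLICES) -> list[np.ndarray]:
    """Centered run of ``n_slices`` axial (third-axis) slices of a 3-D volume."""
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={volume.ndim}")
    depth = volume.shape[2]
    if depth < n_slices:
        warnings.warn(
            f"volume depth {depth} < {n_slices}; returning all slices", stacklevel=2
        )
    return [volume[:, :, z] for z in slice_window(depth, n_slices)]


def crop_offset(side: int, target: int) -> int:
    return (side - target) // 2


def center_crop(image: np.ndarray, target_side: int = DEFAULT_CROP) -> np.ndarray:
    """Centered ``target_side`` square window of a 2-D slice."""
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got ndim={image.ndim}")
    h, w = image.shape
    if h < target_side or w < target_side:
        raise ValueError(f"slice {h}x{w} smaller than crop target {target_side}")
    oy, ox = crop_offset(h, target_side), crop_offset(w, target_side)
    return image[oy : oy + target_side, ox : ox + target_side]


def remap_labels(labels: np.ndarray) -> np.ndarray:
    """Map raw BraTS labels {0,1,2,4} to the contiguous encoding {0,1,2,3}."""
    bad = set(np.unique(labels)) - set(RAW_LABELS)
    if bad:
        raise ValueError(f"unexpected label value(s) {sorted(bad)}; expected {RAW_LABELS}")
    out = labels.astype(np.int64, copy=True)
    out[labels == 4] = 3
    return out


def restore_labels(labels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`remap_labels`: {0,1,2,3} back to {0,1,2,4}."""
    bad = set(np.unique(labels)) - {0, 1, 2, 3}
    if bad:
        raise ValueError(f"unexpected internal label value(s) {sorted(bad)}")
    out = labels.astype(np.int16, copy=True)
    out[labels == 3] = 4
    return out


def normalize(image: np.ndarray) -> np.ndarray:
    """Z-score over nonzero (brain) pixels; background stays exactly zero.

    A constant nonzero region maps to zero, and an all-zero slice is
    returned unchanged, so empty slices are safe to keep in a dataset.
    """
    out = np.zeros_like(image, dtype=np.float32)
    mask = image != 0
    if not mask.any():
        return out
    vals = image[mask].astype(np.float64)
    sd = vals.std()
    if sd < 1e-12:
        return out
    out[mask] = ((vals - vals.mean()) / sd).astype(np.float32)
    return out


# -- NIfTI I/O ------------------------------------------------------------


def _find_modality_file(case_dir: str, case_id: str, suffix: str) -> str | None:
    pattern = os.path.join(case_dir, f"{case_id}_{suffix}.nii*")
    hits = sorted(glob.glob(pattern))
    return hits[0] if hits else None


def load_case(case_dir: str, case_id: str | None = None) -> RawCase:
    """Read one case from a directory of ``{case_id}_{modality}.nii[.gz]`` files.

    The modality suffix convention is ``_t1``, ``_t1ce``, ``_flair``,
    ``_t2`` with an optional ``_seg`` label volume. When ``case_id`` is not
    given it is inferred from the files present.
    """
    import nibabel as nib

    if case_id is None:
        segs = sorted(glob.glob(os.path.join(case_dir, "*_seg.nii*")))
        if not segs:
            raise FileNotFoundError(f"no *_seg.nii[.gz] in {case_dir} to infer case_id from")
        base = os.path.basename(segs[0])
        case_id = base[: base.index("_seg")]
    volumes = {}
    for suffix in MODALITY_SUFFIXES:
        path = _find_modality_file(case_dir, case_id, suffix)
        if path is not None:
            volumes[suffix] = np.asarray(nib.load(path).dataobj, dtype=np.float32)
    if not volumes:
        raise FileNotFoundError(f"no modality volumes for case {case_id} in {case_dir}")
    seg_path = _find_modality_file(case_dir, case_id, "seg")
    labels = None
    if seg_path is not None:
        labels = np.rint(np.asarray(nib.load(seg_path).dataobj)).astype(np.int16)
    return RawCase(modality_volumes=volumes, label_volume=labels, case_id=case_id)


def case_to_slices(
    case: RawCase,
    crop: int = DEFAULT_CROP,
    n_slices: int = DEFAULT_N_SLICES,
    normalize_intensity: bool = True,
    keep_empty: bool = True,
) -> SliceDataset:
    """Apply the full slice pipeline to one raw case.

    Slice selection -> center crop -> label remap -> per-slice, per-modality
    normalization. Slices with an empty brain mask are kept by default.
    """
    names = sorted(case.modality_volumes, key=_suffix_order)
    per_mod = {nm: select_slices(case.modality_volumes[nm], n_slices) for nm in names}
    if case.label_volume is not None:
        label_slices = select_slices(case.label_volume, n_slices)
    else:
        label_slices = [
            np.zeros(per_mod[names[0]][0].shape, dtype=np.int64) for _ in per_mod[names[0]]
        ]
    indices = list(slice_window(case.depth, n_slices))
    ds = SliceDataset()
    for pos, z in enumerate(indices):
        images = []
        for nm in names:
            img = center_crop(per_mod[nm][pos], crop).astype(np.float32)
            if normalize_intensity:
                img = normalize(img)
            images.append(img)
        labels = remap_labels(center_crop(label_slices[pos], crop))
        if not keep_empty and not any(im.any() for im in images):
            continue
        ds.stacks.append(
            ModalityStack(
                images=images,
                labels=labels,
                case_id=case.case_id,
                slice_index=z,
                modality_names=tuple(names),
            )
        )
        ds.provenance.append((case.case_id, z))
    return ds


def _suffix_order(name: str) -> int:
    try:
        return MODALITY_SUFFIXES.index(name)
    except ValueError:
        return len(MODALITY_SUFFIXES)


def embed_prediction(
    pred_slices: list[np.ndarray],
    slice_indices: list[int],
    volume_shape: tuple[int, int, int],
) -> np.ndarray:
    """Zero-pad cropped prediction slices back into the original 3-D frame.

    ``pred_slices`` are internal-encoding label maps (e.g. 224x224); the
    result is a raw-encoding {0,1,2,4} volume of ``volume_shape`` (e.g.
    240x240x155) with background everywhere outside the predicted window.
    """
    out = np.zeros(volume_shape, dtype=np.int16)
    h, w, _ = volume_shape
    for pred, z in zip(pred_slices, slice_indices):
        ph, pw = pred.shape
        oy, ox = crop_offset(h, ph), crop_offset(w, pw)
        out[oy : oy + ph, ox : ox + pw, z] = restore_labels(pred)
    return out


def write_prediction(path, pred_volume: np.ndarray) -> None:
    """Write a raw-encoding prediction volume as NIfTI."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(pred_volume.astype(np.int16), np.eye(4)), str(path))
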