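"""Volume containers, NIfTI I/O, brain masking and intensity normalization.

Inputs are assumed skull-stripped and co-registered multi-channel brain MR
volumes (FLAIR, T1, T2, T1ce) at 1 mm isotropic resolution, with exact-zero
background, plus integer label volumes using the BraTS file convention
{0: background/healthy, 1: necrosis/non-enhancing, 2: edema, 4: enhancing}.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: Fixed channel order used everywhere in the pipeline.
CHANNEL_ORDER: tuple[str, ...] = ("FLAIR", "T1", "T2", "T1ce")

#: Label values in the file (BraTS) convention and the internal contiguous one.
BRATS_LABELS: tuple[int, ...] = (0, 1, 2, 4)
CONTIGUOUS_LABELS: tuple[int, ...] = (0, 1, 2, 3)


def brats_to_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map file labels {0,1,2,4} to contiguous class indices {0,1,2,3}."""
    out = labels.astype(np.int16, copy=True)
    out[labels == 4] = 3
    return out


def contiguous_to_brats(labels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`brats_to_contiguous` (lossless)."""
    out = labels.astype(np.int16, copy=True)
    out[labels == 3] = 4
    return out


def _check_spacing(spacing):
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing}")


@dataclass
class MultiChannelVolume:
    """Four co-registered MR channels stacked as a (4, X, Y, Z) array."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(CHANNEL_ORDER):
            raise ValueError(
                f"expected a ({len(CHANNEL_ORDER)}, X, Y, Z) array, got {self.data.shape}"
            )
        _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {name: self.data[i] for i, name in enumerate(CHANNEL_ORDER)}

    def channel(self, name: str) -> np.ndarray:
        return self.data[CHANNEL_ORDER.index(name)]


@dataclass
class LabelVolume:
    """Per-voxel integer tissue labels in either label convention."""

    data: np.ndarray
    scheme: str = "brats"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, np.int16)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got shape {self.data.shape}")
        allowed = BRATS_LABELS if self.scheme == "brats" else CONTIGUOUS_LABELS
        if self.scheme not in ("brats", "contiguous"):
            raise ValueError(f"unknown label scheme {self.scheme!r}")
        bad = np.setdiff1d(np.unique(self.data), allowed)
        if bad.size:
            raise ValueError(f"label values {bad.tolist()} not in {allowed}")
        _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_contiguous(self) -> "LabelVolume":
        if self.scheme == "contiguous":
            return self
        return LabelVolume(brats_to_contiguous(self.data), "contiguous",
                           self.spacing, self.affine)

    def to_brats(self) -> "LabelVolume":
        if self.scheme == "brats":
            return self
        return LabelVolume(contiguous_to_brats(self.data), "brats",
                           self.spacing, self.affine)


@dataclass
class BrainMask:
    """Binary support of the brain, aligned with its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# NIfTI I/O


def _spacing_from(img) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return (float(z[0]), float(z[1]), float(z[2]))


def _find_channel_file(directory: Path, name: str) -> Path:
    """Locate the NIfTI file for one channel by a token in its filename."""
    token = name.lower()
    candidates = []
    for p in sorted(directory.iterdir()):
        if not (p.name.endswith(".nii") or p.name.endswith(".nii.gz")):
            continue
        stem = p.name.lower()
        if token == "t1":
            # avoid matching the post-contrast channel
            hit = "t1" in stem and "t1ce" not in stem and "t1gd" not in stem
        else:
            hit = token in stem
        if hit:
            candidates.append(p)
    if not candidates:
        raise FileNotFoundError(f"missing channel {name!r} in {directory}")
    return candidates[0]


def read_volume(path: str | Path) -> MultiChannelVolume | LabelVolume:
    """Read a multi-channel volume (directory of 4 NIfTIs) or a label NIfTI.

    A directory is searched for one file per channel (FLAIR, T1, T2, T1ce,
    matched by filename token); a single 3D NIfTI is read as a label volume.
    """
    path = Path(path)
    if path.is_dir():
        arrays, affine, spacing = [], None, None
        for name in CHANNEL_ORDER:
            img = nib.load(_find_channel_file(path, name))
            arrays.append(np.asanyarray(img.dataobj, np.float32))
            if affine is None:
                affine, spacing = img.affine, _spacing_from(img)
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"channel shape mismatch in {path}: {sorted(shapes)}")
        return MultiChannelVolume(np.stack(arrays), spacing, affine)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D label volume (shape {data.shape})")
    return LabelVolume(np.rint(data).astype(np.int16), "brats",
                       _spacing_from(img), img.affine)


def write_volume(volume: MultiChannelVolume | LabelVolume, path: str | Path) -> list[Path]:
    """Write a label NIfTI (file path) or per-channel NIfTIs (directory path).

    Geometry (affine) is passed through untouched; voxel data round-trips
    bit-exactly.
    """
    path = Path(path)
    if isinstance(volume, LabelVolume):
        path.parent.mkdir(parents=True, exist_ok=True)
        affine = volume.affine if volume.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(volume.data.astype(np.int16), affine), path)
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    affine = volume.affine if volume.affine is not None else np.eye(4)
    written = []
    for i, name in enumerate(CHANNEL_ORDER):
        p = path / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(volume.data[i].astype(np.float32), affine), p)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Brain mask and normalization


def derive_brain_mask(volume: MultiChannelVolume) -> BrainMask:
    """Support of the skull-stripped brain: voxels where any channel is nonzero."""
    mask = np.any(volume.data != 0, axis=0)
    if not mask.any():
        raise ValueError("volume is all zero: no brain present")
    return BrainMask(mask, volume.spacing)


def zscore_normalize(volume: MultiChannelVolume, mask: BrainMask) -> MultiChannelVolume:
    """Per-channel zero-mean/unit-variance normalization over brain voxels.

    Statistics (population standard deviation) are computed over in-mask
    voxels only; out-of-mask voxels are left at exactly 0.
    """
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    if mask.n_voxels < 2:
        raise ValueError("brain mask must contain at least 2 voxels")
    out = np.zeros_like(volume.data)
    m = mask.data
    for i, name in enumerate(CHANNEL_ORDER):
        vals = volume.data[i][m]
        mu = vals.mean(dtype=np.float64)
        sd = vals.std(dtype=np.float64)  # population (ddof=0)
        if sd < 1e-12:
            raise ValueError(f"channel {name} has zero intensity spread inside the mask")
        out[i][m] = ((vals - mu) / sd).astype(np.float32)
    return MultiChannelVolume(out, volume.spacing, volume.affine)


def n4_bias_correct(in_path: str | Path, out_path: str | Path,
                    executable: str | None = None) -> Path:
    """Optional bias-field correction pre-hook.

    When ``executable`` points at an external N4 tool (e.g. ITK's
    ``N4BiasFieldCorrection``) it is invoked as
    ``executable -i in_path -o out_path``; otherwise the step is skipped and
    the input path is returned unchanged. The correction itself is never
    re-implemented here.
    """
    if executable is None:
        return Path(in_path)
    subprocess.run([executable, "-i", str(in_path), "-o", str(out_path)], check=True)
    return Path(out_path)
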