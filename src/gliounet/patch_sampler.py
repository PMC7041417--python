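"""Weighted 3D patch extraction for training and non-overlapping tiling.

Training patches come from two sources: a regular lattice of seed patches
filtered to those with more than 60% brain content, plus extra patches
centred on whole-tumor boundary voxels (a random 30% of boundary locations),
which counteracts the severe tumor/healthy class imbalance by oversampling
the interfaces the network misclassifies most. Inference uses non-overlapping
tiles of the zero-padded volume, reassembled and cropped to the input shape.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.segmentation import find_boundaries

from .io_preprocess import BrainMask, LabelVolume, MultiChannelVolume

#: Labels counting as whole tumor in the BraTS file convention.
WT_LABELS: tuple[int, ...] = (1, 2, 4)


class NoTumorWarning(UserWarning):
    """Raised (as a warning) when boundary extraction finds no tumor voxels."""


@dataclass(frozen=True)
class PatchSpec:
    """A patch location: low corner, edge length and provenance."""

    corner: tuple[int, int, int]
    size: int = 64
    origin: str = "grid-seed"  # grid-seed | boundary-weighted | inference-tile

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError(f"patch size must be positive, got {self.size}")
        if any(c < 0 for c in self.corner):
            raise ValueError(f"patch corner must be non-negative, got {self.corner}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(c, c + self.size) for c in self.corner)


@dataclass
class PatchSet:
    """Aligned image/label patches plus their specs and the sampling seed."""

    specs: list[PatchSpec]
    images: np.ndarray  # (N, 4, s, s, s) float32
    labels: np.ndarray | None = None  # (N, s, s, s) int16, BraTS convention
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.specs)


def padded_shape(shape: tuple[int, ...], patch_size: int) -> tuple[int, ...]:
    """Shape zero-padded up (high side) to the next multiple of patch_size."""
    return tuple(-(-s // patch_size) * patch_size for s in shape)


def seed_grid(shape: tuple[int, int, int], patch_size: int = 64,
              stride: int | None = None, origin: str = "grid-seed") -> list[PatchSpec]:
    """Regular lattice of patch corners over the zero-padded volume.

    With ``stride == patch_size`` (the default) the lattice is the exact
    non-overlapping tiling of the padded grid; smaller strides give
    overlapping seed patches.
    """
    stride = patch_size if stride is None else stride
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    pad = padded_shape(shape, patch_size)
    axes = [range(0, p - patch_size + 1, stride) for p in pad]
    return [
        PatchSpec((x, y, z), patch_size, origin)
        for x in axes[0] for y in axes[1] for z in axes[2]
    ]


def brain_fraction_filter(specs: list[PatchSpec], mask: BrainMask,
                          threshold: float = 0.6) -> list[PatchSpec]:
    """Keep specs whose in-patch brain fraction is strictly above threshold."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if not specs:
        return []
    size = specs[0].size
    pad = padded_shape(mask.shape, size)
    padded = np.zeros(pad, bool)
    padded[tuple(slice(0, s) for s in mask.shape)] = mask.data
    kept = []
    for spec in specs:
        frac = padded[spec.slices].mean()
        if frac > threshold:
            kept.append(spec)
    return kept


def wt_boundary_voxels(labels: LabelVolume) -> np.ndarray:
    """Voxel coordinates of the whole-tumor boundary ("thick" interface).

    A voxel is a boundary voxel when the binary whole-tumor mask differs
    from at least one 6-connected neighbour, counting voxels on both sides
    of the interface. Returns an (N, 3) integer array in lexicographic
    order; with no tumor present an empty array is returned and a
    :class:`NoTumorWarning` is issued.
    """
    wt = np.isin(labels.to_brats().data, WT_LABELS)
    if not wt.any():
        warnings.warn("no tumor voxels: whole-tumor boundary is empty", NoTumorWarning)
        return np.empty((0, 3), np.int64)
    boundary = find_boundaries(wt, connectivity=1, mode="thick")
    return np.argwhere(boundary)


def sample_boundary_patches(boundary: np.ndarray, volume_shape: tuple[int, int, int],
                            fraction: float = 0.3, patch_size: int = 64,
                            rng_seed: int = 0, max_patches: int | None = None) -> list[PatchSpec]:
    """Draw patches centred on a random fraction of boundary voxels.

    ``round(fraction * n_boundary)`` distinct voxels are chosen uniformly
    without replacement with the supplied seed; each becomes a patch center
    (corner = center - size//2), clipped into the padded grid. The output is
    deterministic given (boundary, fraction, seed). ``max_patches`` caps the
    draw for scaled-down runs.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    boundary = np.asarray(boundary, np.int64).reshape(-1, 3)
    if boundary.shape[0] == 0:
        return []
    # canonical ordering so the draw depends only on the set of voxels
    order = np.lexsort((boundary[:, 2], boundary[:, 1], boundary[:, 0]))
    boundary = boundary[order]
    n_sel = int(np.rint(fraction * boundary.shape[0]))
    if max_patches is not None:
        n_sel = min(n_sel, max_patches)
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(boundary.shape[0], size=n_sel, replace=False))
    pad = padded_shape(volume_shape, patch_size)
    half = patch_size // 2
    specs = []
    for cx, cy, cz in boundary[idx]:
        corner = tuple(
            int(np.clip(c - half, 0, p - patch_size))
            for c, p in zip((cx, cy, cz), pad)
        )
        specs.append(PatchSpec(corner, patch_size, "boundary-weighted"))
    return specs


def extract_patches(volume: MultiChannelVolume, labels: LabelVolume | None,
                    specs: list[PatchSpec], rng_seed: int | None = None) -> PatchSet:
    """Cut the specified 4-channel (and label) patches from the padded volume.

    The volume is zero-padded on the high side to the next multiple of the
    patch size (never reflected); patches reaching into the margin read
    exact zeros there.
    """
    if not specs:
        raise ValueError("no patch specs supplied")
    sizes = {s.size for s in specs}
    if len(sizes) != 1:
        raise ValueError(f"all specs must share one patch size, got {sorted(sizes)}")
    size = specs[0].size
    pad = padded_shape(volume.shape, size)
    for spec in specs:
        if any(c + size > p for c, p in zip(spec.corner, pad)):
            raise ValueError(f"spec {spec} exceeds padded bounds {pad}")
    pimg = np.zeros((volume.data.shape[0],) + pad, np.float32)
    pimg[(slice(None),) + tuple(slice(0, s) for s in volume.shape)] = volume.data
    plab = None
    if labels is not None:
        if labels.shape != volume.shape:
            raise ValueError(f"labels shape {labels.shape} != volume shape {volume.shape}")
        plab = np.zeros(pad, np.int16)
        plab[tuple(slice(0, s) for s in labels.shape)] = labels.to_brats().data
    images = np.stack([pimg[(slice(None),) + s.slices] for s in specs])
    lab = np.stack([plab[s.slices] for s in specs]) if plab is not None else None
    return PatchSet(list(specs), images, lab, rng_seed)


def assemble_prediction(tiles: list[tuple[PatchSpec, np.ndarray]],
                        original_shape: tuple[int, int, int]) -> np.ndarray:
    """Concatenate non-overlapping predicted tiles and crop the padding off.

    Tiles must jointly cover the padded grid exactly once; overlaps or gaps
    raise an error.
    """
    if not tiles:
        raise ValueError("no tiles supplied")
    size = tiles[0][0].size
    pad = padded_shape(original_shape, size)
    out = np.zeros(pad, np.int16)
    count = np.zeros(pad, np.uint8)
    for spec, patch in tiles:
        if patch.shape != (size,) * 3:
            raise ValueError(f"tile at {spec.corner} has shape {patch.shape}, "
                             f"expected {(size,) * 3}")
        out[spec.slices] = patch
        count[spec.slices] += 1
    if (count > 1).any():
        raise ValueError("overlapping tiles: padded grid covered more than once")
    if (count == 0).any():
        raise ValueError("missing tiles: padded grid not fully covered")
    return out[tuple(slice(0, s) for s in original_shape)]


# ---------------------------------------------------------------------------
# Training inventory and persistence


def training_patch_inventory(volume: MultiChannelVolume, labels: LabelVolume,
                             mask: BrainMask, patch_size: int = 64,
                             stride: int | None = None, brain_threshold: float = 0.6,
                             boundary_fraction: float = 0.3, rng_seed: int = 0,
                             filter_boundary_patches: bool = False,
                             max_boundary_patches: int | None = None) -> PatchSet:
    """Full weighted training inventory: filtered grid seeds + boundary patches.

    Duplicate corners between the two sources are kept on purpose — the
    oversampling of boundary regions is the point of the scheme.
    """
    seeds = seed_grid(volume.shape, patch_size, stride)
    seeds = brain_fraction_filter(seeds, mask, brain_threshold)
    boundary = wt_boundary_voxels(labels)
    extra = sample_boundary_patches(boundary, volume.shape, boundary_fraction,
                                    patch_size, rng_seed, max_boundary_patches)
    if filter_boundary_patches:
        extra = brain_fraction_filter(extra, mask, brain_threshold)
    return extract_patches(volume, labels, seeds + extra, rng_seed)


def save_patchset(patches: PatchSet, directory: str | Path) -> Path:
    """Persist a PatchSet as .npz arrays plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {"images": patches.images}
    if patches.labels is not None:
        arrays["labels"] = patches.labels
    np.savez_compressed(directory / "patches.npz", **arrays)
    manifest = {
        "rng_seed": patches.rng_seed,
        "specs": [
            {"corner": list(s.corner), "size": s.size, "origin": s.origin}
            for s in patches.specs
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_patchset(directory: str | Path) -> PatchSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    with np.load(directory / "patches.npz") as data:
        images = data["images"]
        labels = data["labels"] if "labels" in data.files else None
    specs = [
        PatchSpec(tuple(s["corner"]), s["size"], s["origin"])
        for s in manifest["specs"]
    ]
    return PatchSet(specs, images, labels, manifest["rng_seed"])
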