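"""False-positive removal on predicted label volumes.

Two operations, applied after tile-based prediction: retain only the
largest 3D connected component of the whole-tumor mask (spurious distant
blobs are erased), and zero out anything predicted outside the brain mask
(a logical AND, which removes artefacts in the zero-padding margin). Both
are idempotent and never create tumor voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_preprocess import BrainMask, LabelVolume

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ComponentReport:
    """Outcome of connected-component analysis on the whole-tumor mask."""

    component_count: int
    component_sizes: tuple[int, ...]
    retained_component_id: int  # 1-based label id; -1 when no components

    def __post_init__(self):
        if self.component_count and self.component_sizes:
            best = max(self.component_sizes)
            kept = self.component_sizes[self.retained_component_id - 1]
            if kept != best:
                raise ValueError("retained component must be one of maximal size")


def keep_largest_component(labels: LabelVolume,
                           connectivity: int = 26,
                           min_size_fraction: float | None = None
                           ) -> tuple[LabelVolume, ComponentReport]:
    """Erase all tumor voxels outside the largest whole-tumor component.

    Components are computed on the binary whole-tumor mask (any nonzero
    label) so that, e.g., a necrotic core disconnected from its enhancing
    rim is not deleted; class labels inside the retained component are
    untouched. Size ties break to the component discovered first in scan
    order. With ``min_size_fraction`` set, every component at least that
    fraction of the largest is kept instead (useful for bifocal tumors,
    where keeping only one component is a known failure mode).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    wt = labels.data != 0
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    comp, n = ndimage.label(wt, structure=structure)
    if n == 0:
        return (
            LabelVolume(labels.data.copy(), labels.scheme, labels.spacing, labels.affine),
            ComponentReport(0, (), -1),
        )
    sizes = np.bincount(comp.ravel())[1:]
    keep_id = int(np.argmax(sizes)) + 1  # argmax takes the first maximum
    if min_size_fraction is None:
        keep = comp == keep_id
    else:
        ids = np.flatnonzero(sizes >= min_size_fraction * sizes[keep_id - 1]) + 1
        keep = np.isin(comp, ids)
    out = np.where(keep, labels.data, 0).astype(np.int16)
    return (
        LabelVolume(out, labels.scheme, labels.spacing, labels.affine),
        ComponentReport(int(n), tuple(int(s) for s in sizes), keep_id),
    )


def apply_brain_mask(labels: LabelVolume, mask: BrainMask) -> LabelVolume:
    """Zero every label voxel outside the brain mask (logical AND)."""
    if mask.shape != labels.shape:
        raise ValueError(f"mask shape {mask.shape} != label shape {labels.shape}")
    out = np.where(mask.data, labels.data, 0).astype(np.int16)
    return LabelVolume(out, labels.scheme, labels.spacing, labels.affine)
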