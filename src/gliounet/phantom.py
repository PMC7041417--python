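"""Synthetic multi-channel glioma phantoms with ground-truth labels.

A phantom is a zero-background brain ellipsoid containing one or two tumor
foci built from nested, smoothly deformed spheroids: a necrotic core
(label 1) inside an enhancing rim (label 4) inside peritumoral edema
(label 2). Channel intensities follow the qualitative MR contrasts of the
real disease — edema bright on FLAIR/T2, the enhancing rim bright on T1ce,
necrosis dark on T1ce — plus seeded Gaussian noise inside the brain. The
radial deformation (a low-order directional perturbation) keeps the network
from learning a perfect-sphere prior. Full-size (240x240x155) defaults land
in the ~99% non-tumor imbalance regime of real cohorts.

Intensities are qualitative emulations, not fits to real MR distributions:
the goal is learnability and pipeline coverage, not radiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import LabelVolume, MultiChannelVolume, CHANNEL_ORDER

#: Per-tissue mean intensity per channel (FLAIR, T1, T2, T1ce).
DEFAULT_INTENSITIES: dict[str, tuple[float, float, float, float]] = {
    "background": (0.0, 0.0, 0.0, 0.0),
    "healthy": (0.40, 0.50, 0.40, 0.50),
    "edema": (0.85, 0.40, 0.85, 0.45),
    "enhancing": (0.60, 0.55, 0.60, 0.95),
    "necrosis": (0.50, 0.30, 0.55, 0.10),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise of a synthetic glioma volume.

    ``radii`` are the (necrosis, enhancing, edema) spheroid radii in voxels
    and must be strictly increasing; ``deform`` is the relative amplitude of
    the smooth radial perturbation of each interface.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    brain_axes: tuple[float, float, float] | None = None
    tumor_center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] | None = None
    intensities: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 0.03
    deform: float = 0.12
    n_foci: int = 1
    foci_scale: float = 0.45
    rng_seed: int = 0

    def resolved(self) -> "PhantomConfig":
        """Fill geometry defaults derived from the grid shape."""
        shape = tuple(int(s) for s in self.shape)
        brain = self.brain_axes or tuple(0.44 * s for s in shape)
        center = tuple(s / 2.0 for s in shape)
        tc = self.tumor_center or tuple(
            c + f * a for c, a, f in zip(center, brain, (0.30, 0.15, 0.0)))
        m = min(shape)
        radii = self.radii or (0.073 * m, 0.115 * m, 0.170 * m)
        cfg = PhantomConfig(shape, brain, tc, radii, dict(self.intensities),
                            self.noise_sd, self.deform, self.n_foci,
                            self.foci_scale, self.rng_seed)
        cfg.validate()
        return cfg

    def validate(self):
        r1, r2, r3 = self.radii
        if not 0 < r1 < r2 < r3:
            raise ValueError(f"radii must satisfy 0 < r1 < r2 < r3, got {self.radii}")
        if self.n_foci not in (1, 2):
            raise ValueError("n_foci must be 1 or 2")
        if self.noise_sd < 0 or not 0 <= self.deform < 0.5:
            raise ValueError("noise_sd must be >= 0 and deform in [0, 0.5)")
        for focus_center, scale in self._foci():
            self._check_fit(focus_center, r3 * scale)

    def _foci(self):
        yield self.tumor_center, 1.0
        if self.n_foci == 2:
            center = tuple(s / 2.0 for s in self.shape)
            mirrored = tuple(2 * c - t for c, t in zip(center, self.tumor_center))
            yield mirrored, self.foci_scale

    def _check_fit(self, focus_center, r_out):
        center = tuple(s / 2.0 for s in self.shape)
        off = np.sqrt(sum(((t - c) / a) ** 2
                          for t, c, a in zip(focus_center, center, self.brain_axes)))
        reach = off + r_out * (1 + self.deform) / min(self.brain_axes)
        if reach > 1.0:
            raise ValueError(
                f"tumor focus at {focus_center} (outer radius {r_out:.1f}) does not "
                f"fit inside the brain ellipsoid")


def full_size_config(**overrides) -> PhantomConfig:
    """A 240x240x155 phantom in the ~99% non-tumor imbalance regime."""
    defaults = dict(shape=(240, 240, 155), brain_axes=(100.0, 105.0, 68.0),
                    radii=(11.0, 18.0, 27.0))
    defaults.update(overrides)
    return PhantomConfig(**defaults)


_TISSUE_LABEL = {"necrosis": 1, "edema": 2, "enhancing": 4}


def _deformation_field(nx, ny, nz, amp: float, rng: np.random.Generator):
    """Smooth multiplicative radius perturbation 1 + amp * f(direction).

    f is a random combination of first- and second-order direction-cosine
    terms, normalised so |f| <= 1; the same field scales every interface of
    a focus, which preserves the nested topology exactly.
    """
    basis = (nx, ny, nz, nx * ny, ny * nz, nz * nx,
             nx * nx - ny * ny, 3 * nz * nz - 1.0)
    coef = rng.normal(size=len(basis))
    coef /= np.abs(coef).sum() + 1e-12
    f = np.zeros_like(nx)
    for c, b in zip(coef, basis):
        f += c * b
    return 1.0 + amp * f


def generate_phantom(config: PhantomConfig | None = None
                     ) -> tuple[MultiChannelVolume, LabelVolume]:
    """Build one seeded phantom: 4 aligned channels plus BraTS-style labels."""
    cfg = (config or PhantomConfig()).resolved()
    rng = np.random.default_rng(cfg.rng_seed)
    shape = cfg.shape
    center = tuple(s / 2.0 for s in shape)
    x, y, z = np.ogrid[:shape[0], :shape[1], :shape[2]]
    coords = (x.astype(np.float32), y.astype(np.float32), z.astype(np.float32))

    brain = sum(((c - mu) / a) ** 2
                for c, mu, a in zip(coords, center, cfg.brain_axes)) <= 1.0

    labels = np.zeros(shape, np.int16)
    for focus_center, scale in cfg._foci():
        dx = [c - mu for c, mu in zip(coords, focus_center)]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        safe_r = np.maximum(r, 1e-6)
        n = [d / safe_r for d in dx]
        f = _deformation_field(n[0], n[1], n[2], cfg.deform, rng)
        r1, r2, r3 = (ri * scale for ri in cfg.radii)
        inside = brain  # tumors are clipped to the brain (fit is pre-validated)
        labels[(r <= r3 * f) & inside] = _TISSUE_LABEL["edema"]
        labels[(r <= r2 * f) & inside] = _TISSUE_LABEL["enhancing"]
        labels[(r <= r1 * f) & inside] = _TISSUE_LABEL["necrosis"]

    tissue_of_label = {0: "healthy", 1: "necrosis", 2: "edema", 4: "enhancing"}
    data = np.zeros((len(CHANNEL_ORDER),) + shape, np.float32)
    for lab, tissue in tissue_of_label.items():
        sel = brain & (labels == lab)
        means = cfg.intensities[tissue]
        for ch in range(len(CHANNEL_ORDER)):
            data[ch][sel] = means[ch]
    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd,
                           (len(CHANNEL_ORDER),) + shape).astype(np.float32)
        data += noise * brain[None]
    # the background stays exactly zero (skull-stripped contract)
    return (
        MultiChannelVolume(data),
        LabelVolume(labels, "brats"),
    )


def imbalance_profile(labels: LabelVolume) -> dict[int, float]:
    """Fraction of voxels per class value (file convention)."""
    d = labels.to_brats().data
    total = d.size
    return {int(v): float((d == v).sum()) / total for v in (0, 1, 2, 4)}
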