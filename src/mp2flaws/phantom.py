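"""NIfTI I/O, synthetic brain phantom, and image-domain contrast metrics.

The phantom is a concentric-geometry stand-in for an in-vivo acquisition:
a WM core with a CSF pocket (ventricle), a GM shell, a CSF rim and empty
background, traversed by a smooth multiplicative B1+ field.  Every voxel
receives the EPG-simulated complex (INV1, INV2) signal pair of its tissue
at its local B1 scale plus complex Gaussian noise, so the image path can
be exercised end to end with known ground truth.  Masks exclude nothing
but the geometry itself — voxels are pure tissue by construction, which
mirrors working from high-probability segmentations without implementing
segmentation.

Image-domain CNR follows the robust convention: difference of mean tissue
intensities divided by the median absolute deviation (raw MAD, no Gaussian
consistency factor) of the UNI white-matter signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .epg import TissueParams
from .sequence import SequenceParams, simulate_signal_grid

__all__ = [
    "ImageVolume",
    "PhantomSpec",
    "read_nifti",
    "write_nifti",
    "generate_phantom",
    "estimate_image_cnr",
    "contrast_ratio",
]


@dataclass
class ImageVolume:
    """A voxel array with isotropic-or-not spacing in mm.

    ``polarity`` optionally carries the sign of INV1 voxels for
    magnitude-only data (the UNI ratio needs the INV1 polarity).
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    polarity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.all(np.isfinite(np.abs(self.data))):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


def read_nifti(path: str | Path) -> ImageVolume:
    """Load a NIfTI volume; raises a clear error for non-NIfTI input."""
    try:
        img = nib.load(str(path))
    except (nib.filebasedimages.ImageFileError, FileNotFoundError) as exc:
        raise ValueError(f"not a readable NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data, spacing)


def write_nifti(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume with a diagonal affine from its spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return Path(path)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, B1 field and noise of the synthetic phantom.

    The concentric radii are fractions of the half-extent: WM core with a
    central CSF pocket, GM shell, CSF rim, zero background.  The B1 field
    varies smoothly (cosine ramp) along the first axis over ``b1_range``
    and is quantized to ``n_b1_levels`` simulation levels.
    """

    shape: tuple = (40, 40, 40)
    spacing: tuple = (0.65, 0.65, 0.65)
    b1_range: tuple = (0.5, 1.4)
    n_b1_levels: int = 10
    sigma: float = 0.0
    seed: int = 20221109

    def __post_init__(self) -> None:
        if self.n_b1_levels < 1:
            raise ValueError("n_b1_levels must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 < self.b1_range[0] <= self.b1_range[1]:
            raise ValueError("b1_range must be positive and ordered")


def _labels(shape) -> np.ndarray:
    """Concentric tissue labels: 0 bg, 1 WM, 2 GM, 3 CSF."""
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    r = np.sqrt(sum(g ** 2 for g in grids))
    labels = np.zeros(shape, dtype=np.uint8)
    labels[r < 0.85] = 3          # CSF rim
    labels[r < 0.70] = 2          # GM shell
    labels[r < 0.45] = 1          # WM core
    labels[r < 0.15] = 3          # central CSF pocket (ventricle)
    return labels


def _b1_field(spec: PhantomSpec) -> np.ndarray:
    lo, hi = spec.b1_range
    x = np.linspace(0.0, np.pi, spec.shape[0])
    ramp = lo + (hi - lo) * 0.5 * (1.0 - np.cos(x))  # smooth lo -> hi
    field = np.broadcast_to(ramp[:, None, None], spec.shape).copy()
    if spec.n_b1_levels == 1:
        return np.full(spec.shape, 0.5 * (lo + hi))
    levels = np.linspace(lo, hi, spec.n_b1_levels)
    idx = np.abs(field[..., None] - levels).argmin(axis=-1)
    return levels[idx]


def generate_phantom(
    spec: PhantomSpec,
    seq: SequenceParams,
    tissues: Mapping[str, TissueParams],
):
    """Simulate complex INV1/INV2 phantom volumes plus per-tissue masks.

    Returns ``(inv1, inv2, masks)`` where the volumes are complex
    :class:`ImageVolume` objects and ``masks`` maps tissue name to a
    boolean array.  Seeded generation is bit-reproducible.
    """
    labels = _labels(spec.shape)
    b1 = _b1_field(spec)
    levels = np.unique(b1)
    order = {"WM": 1, "GM": 2, "CSF": 3}

    inv1 = np.zeros(spec.shape, dtype=complex)
    inv2 = np.zeros(spec.shape, dtype=complex)
    for name, code in order.items():
        sig = simulate_signal_grid(seq, tissues[name], levels,
                                   [(seq.alpha1, seq.alpha2)])
        for i, level in enumerate(levels):
            sel = (labels == code) & (b1 == level)
            inv1[sel] = sig[i, 0, 0]
            inv2[sel] = sig[i, 0, 1]
    if spec.sigma > 0:
        # complex noise everywhere, including the empty background
        rng = np.random.default_rng(spec.seed)
        inv1 += rng.standard_normal(spec.shape) * spec.sigma \
            + 1j * rng.standard_normal(spec.shape) * spec.sigma
        inv2 += rng.standard_normal(spec.shape) * spec.sigma \
            + 1j * rng.standard_normal(spec.shape) * spec.sigma
    masks = {name: labels == code for name, code in order.items()}
    masks["background"] = labels == 0
    vol1 = ImageVolume(inv1, spec.spacing, polarity=np.sign(inv1.real))
    vol2 = ImageVolume(inv2, spec.spacing)
    return vol1, vol2, masks


def estimate_image_cnr(img: ImageVolume, mask_a: np.ndarray, mask_b: np.ndarray,
                       uni: ImageVolume, uni_wm_mask: np.ndarray) -> float:
    """Signed image-domain CNR.

    Difference of mean intensities of ``img`` over the two masks, divided
    by the raw median absolute deviation of the UNI image over the WM
    mask.  Scale-invariant under joint rescaling of ``img`` and ``uni``.
    """
    for m in (mask_a, mask_b, uni_wm_mask):
        if not np.any(m):
            raise ValueError("empty mask")
    wm = np.real(uni.data[uni_wm_mask])
    mad = np.median(np.abs(wm - np.median(wm)))
    if mad == 0:
        raise ValueError("zero MAD in the UNI WM mask; noiseless input?")
    a = np.real(img.data[mask_a]).mean()
    b = np.real(img.data[mask_b]).mean()
    return float((a - b) / mad)


def contrast_ratio(img: ImageVolume, mask_a: np.ndarray, mask_b: np.ndarray,
                   uni: ImageVolume, uni_wm_mask: np.ndarray) -> float:
    """Tissue contrast as a percentage of the UNI WM signal intensity."""
    for m in (mask_a, mask_b, uni_wm_mask):
        if not np.any(m):
            raise ValueError("empty mask")
    wm_mean = np.real(uni.data[uni_wm_mask]).mean()
    if wm_mean == 0:
        raise ValueError("zero UNI WM mean")
    a = np.real(img.data[mask_a]).mean()
    b = np.real(img.data[mask_b]).mean()
    return float(100.0 * (a - b) / wm_mean)
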