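"""UNI and FLAWS image-combination operators.

All combiners are ratios of the two inversion images and are therefore
invariant to receive-field, proton-density and T2* factors common to both
inputs (for the beta-regularized variants, invariant once intensities are
large against beta).  They apply elementwise to scalars, numpy arrays or
whole volumes.

UNI      : Re(S1* . S2) / (|S1|^2 + |S2|^2),  range [-0.5, 0.5]
FLAWS_min: min(I1, I2) / (I1 + I2),           range [0, 0.5]
FLAWS_hc : (I1 - I2 - beta) / (I1 + I2 + 2 beta)
FLAWS_hco: (I2 - I1 - beta) / (I1 + I2 + 2 beta)

The minimum-intensity projection of hc and hco reproduces FLAWS_min up to
the affine map ``2 x - 1`` when beta = 0, with the advantage that beta > 0
pushes the empty background to -0.5 (background suppression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CombinerConfig",
    "uni",
    "flaws_min",
    "flaws_hc",
    "flaws_hco",
    "flaws_min_from_hc",
    "combine_volume",
]


@dataclass(frozen=True)
class CombinerConfig:
    """Combination settings: background regularization and intensity scale.

    ``beta`` is interpreted on the common intensity range to which both
    inputs are rescaled before combination (joint 99.9th percentile mapped
    to ``intensity_scale``).
    """

    beta: float = 70.0
    intensity_scale: float = 4095.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not self.intensity_scale > 0:
            raise ValueError("intensity_scale must be positive")


def uni(s1, s2):
    """Complex-ratio uniform image; 0 by convention where both inputs vanish."""
    s1 = np.asarray(s1, dtype=complex)
    s2 = np.asarray(s2, dtype=complex)
    denom = np.abs(s1) ** 2 + np.abs(s2) ** 2
    num = np.real(np.conj(s1) * s2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def flaws_min(i1, i2):
    """Sum-normalized minimum intensity projection of the two magnitudes."""
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if np.any(i1 < 0) or np.any(i2 < 0):
        raise ValueError("flaws_min expects non-negative magnitudes")
    denom = i1 + i2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, np.minimum(i1, i2) / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def _ratio(num, denom):
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def flaws_hc(i1, i2, beta: float = 0.0):
    """High-contrast FLAWS ratio ``(I1 - I2 - beta) / (I1 + I2 + 2 beta)``."""
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    return _ratio(i1 - i2 - beta, i1 + i2 + 2.0 * beta)


def flaws_hco(i1, i2, beta: float = 0.0):
    """Opposite-contrast FLAWS ratio ``(I2 - I1 - beta) / (I1 + I2 + 2 beta)``."""
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    return _ratio(i2 - i1 - beta, i1 + i2 + 2.0 * beta)


def flaws_min_from_hc(i1, i2, beta: float = 0.0):
    """Minimum intensity projection of FLAWS_hc and FLAWS_hco.

    At beta = 0 this equals ``2 * flaws_min(I1, I2) - 1`` exactly; with
    beta > 0 empty background maps to -0.5.
    """
    return np.minimum(flaws_hc(i1, i2, beta), flaws_hco(i1, i2, beta))


_MODES = ("uni", "flaws_min", "flaws_hc", "flaws_hco")


def _rescale(a1: np.ndarray, a2: np.ndarray, scale: float):
    """Map the joint 99.9th percentile of both magnitudes to ``scale``."""
    ref = np.percentile(np.concatenate([a1.ravel(), a2.ravel()]), 99.9)
    if ref <= 0:
        return a1, a2
    factor = scale / ref
    return a1 * factor, a2 * factor


def combine_volume(inv1, inv2, mode: str, cfg: CombinerConfig | None = None):
    """Voxelwise combination of two inversion-image volumes.

    Parameters
    ----------
    inv1, inv2 : ImageVolume
        Matching-grid volumes.  For ``mode="uni"`` complex or signed data
        are used directly (the ratio needs the INV1 polarity); the FLAWS
        modes use magnitudes, rescaled to the common range of ``cfg``.
    mode : {"uni", "flaws_min", "flaws_hc", "flaws_hco"}

    Returns
    -------
    ImageVolume with the combined data on the same grid.
    """
    from .phantom import ImageVolume  # local import to avoid a cycle

    cfg = cfg or CombinerConfig()
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    d1, d2 = inv1.data, inv2.data
    if d1.shape != d2.shape:
        raise ValueError(f"shape mismatch: {d1.shape} vs {d2.shape}")

    if mode == "uni":
        s1 = d1
        if not np.iscomplexobj(s1) and inv1.polarity is not None:
            s1 = np.abs(d1) * inv1.polarity
        out = uni(s1, d2)
    else:
        m1, m2 = np.abs(d1), np.abs(d2)
        m1, m2 = _rescale(m1, m2, cfg.intensity_scale)
        if mode == "flaws_min":
            out = flaws_min(m1, m2)
        elif mode == "flaws_hc":
            out = flaws_hc(m1, m2, cfg.beta)
        else:
            out = flaws_hco(m1, m2, cfg.beta)
    return ImageVolume(np.asarray(out, dtype=float), spacing=inv1.spacing)
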