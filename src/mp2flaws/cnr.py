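"""Monte-Carlo noise propagation and the joint UNI/FLAWS CNR objective.

Complex Gaussian noise (independent per real/imaginary channel, SD
``sigma``) is added to the simulated INV1/INV2 center-of-k-space signals;
the image combiners are applied to each noisy draw and the CNR between two
tissues is the mean of the contrast difference divided by its SD, sign
preserved.  ``sigma`` is calibrated once per TR_GRE so that the reference
tissue (WM) has the target SNR (default 20) in the INV2 image at nominal
B1, and is then held constant across the whole flip-angle/TI/TR grid.

The joint objective is

    CNR_total = (FLAWS_min CNR_GM-CSF + FLAWS_min CNR_GM-WM
                 + UNI CNR_WM-GM + UNI CNR_GM-CSF) / sqrt(TR_MP2RAGE)

reported per sqrt(ms), i.e. CNR per unit time.  Signed CNRs are used so a
contrast reversal penalizes the objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .contrast import flaws_min, uni
from .epg import TissueParams
from .sequence import SequenceParams, SignalPair, simulate_signal_grid

__all__ = [
    "NoiseModel",
    "B1Grid",
    "CNRMap",
    "COMPONENT_CHANNELS",
    "calibrate_sigma",
    "mc_contrast_cnr",
    "b1_averaged_cnr",
    "grid_channel_cnrs",
    "cnr_total",
]

#: the four signed component channels of the joint objective, as
#: (channel name, combiner, tissue A, tissue B) with CNR = CNR(A) - CNR(B)
COMPONENT_CHANNELS = (
    ("uni_wm_gm", "uni", "WM", "GM"),
    ("uni_gm_csf", "uni", "GM", "CSF"),
    ("flaws_gm_wm", "flaws_min", "GM", "WM"),
    ("flaws_gm_csf", "flaws_min", "GM", "CSF"),
)


@dataclass(frozen=True)
class NoiseModel:
    """Monte-Carlo noise configuration.

    ``sigma`` is the per-channel complex-noise SD in signal units; when
    ``None`` it must be calibrated first (:func:`calibrate_sigma`).
    """

    sigma: float | None = None
    target_snr: float = 20.0
    reference_tissue: str = "WM"
    n_reps: int = 100_000
    seed: int = 20221109

    def __post_init__(self) -> None:
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.target_snr > 0:
            raise ValueError("target_snr must be positive")


@dataclass(frozen=True)
class B1Grid:
    """Transmit-field scaling factors; default 0.5-1.4 in steps of 0.1."""

    scales: tuple = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or any(s <= 0 for s in self.scales):
            raise ValueError("B1 scales must be positive and non-empty")


@dataclass
class CNRMap:
    """Signed CNR values on a flip-angle grid, one 2D array per channel.

    ``channels`` holds the four component channels plus ``uni_total``,
    ``flaws_total`` and the per-unit-time ``cnr_total``; each array has
    shape ``(len(alpha1_grid), len(alpha2_grid))``.
    """

    alpha1_grid: np.ndarray
    alpha2_grid: np.ndarray
    channels: dict
    tr_mp2rage: float

    def to_frame(self):
        import pandas as pd

        a1, a2 = np.meshgrid(self.alpha1_grid, self.alpha2_grid, indexing="ij")
        data = {"alpha1": a1.ravel(), "alpha2": a2.ravel()}
        data.update({k: v.ravel() for k, v in self.channels.items()})
        return pd.DataFrame(data)


def calibrate_sigma(
    seq: SequenceParams,
    tissues: Mapping[str, TissueParams],
    reference_fa: tuple[float, float] | None = None,
    noise: NoiseModel | None = None,
) -> float:
    """Noise SD giving the reference tissue the target SNR in INV2 at B1=1.

    The returned sigma is meant to be held constant for every flip-angle
    pair and TI combination sharing the same TR_GRE.
    """
    noise = noise or NoiseModel()
    fa = reference_fa or (seq.alpha1, seq.alpha2)
    tissue = tissues[noise.reference_tissue]
    sig = simulate_signal_grid(seq, tissue, [1.0], [fa])
    s2 = abs(sig[0, 0, 1])
    if s2 == 0:
        raise ValueError("reference INV2 signal is zero; cannot calibrate sigma")
    return s2 / noise.target_snr


def _noisy_channels(s_by_tissue, sigma, n_reps, rng):
    """Noisy per-tissue contrast draws -> dict of per-channel CNR values.

    ``s_by_tissue`` maps tissue name to a complex array of shape
    ``(n_b1, 2)``.  Returns per-channel arrays of shape ``(n_b1,)``.
    Works on the real/imaginary channels directly; with sigma > 0 the
    denominators are almost surely non-zero, so no guards are needed.
    """
    contrasts = {}
    for name, s in s_by_tissue.items():  # s: (n_b1, 2) complex
        n_b1 = s.shape[0]
        draws = rng.standard_normal((4, n_b1, n_reps))
        draws *= sigma
        re1 = draws[0]
        re1 += s[:, None, 0].real
        im1 = draws[1]
        im1 += s[:, None, 0].imag
        re2 = draws[2]
        re2 += s[:, None, 1].real
        im2 = draws[3]
        im2 += s[:, None, 1].imag
        a1 = re1 * re1 + im1 * im1
        a2 = re2 * re2 + im2 * im2
        m1 = np.sqrt(a1)
        m2 = np.sqrt(a2)
        contrasts[name] = {
            "uni": (re1 * re2 + im1 * im2) / (a1 + a2),
            "flaws_min": np.minimum(m1, m2) / (m1 + m2),
        }
    out = {}
    for channel, combiner, ta, tb in COMPONENT_CHANNELS:
        diff = contrasts[ta][combiner] - contrasts[tb][combiner]
        sd = diff.std(axis=-1)
        out[channel] = np.where(sd > 0, diff.mean(axis=-1) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def mc_contrast_cnr(
    pair_a: SignalPair,
    pair_b: SignalPair,
    combiner: str,
    noise: NoiseModel,
) -> float:
    """Signed Monte-Carlo CNR between two tissue signal pairs.

    ``combiner`` is ``"uni"`` (complex ratio on noisy complex signals) or
    ``"flaws_min"`` (sum-normalized minimum on noisy magnitudes).  Draws
    are independent per tissue and per inversion image; identical seeds
    give bit-identical results.
    """
    if noise.sigma is None:
        raise ValueError("noise.sigma must be calibrated before Monte-Carlo runs")
    if combiner not in ("uni", "flaws_min"):
        raise ValueError(f"unknown combiner {combiner!r}")
    rng = np.random.default_rng(noise.seed)
    s_by_tissue = {
        "A": np.array([[pair_a.s1, pair_a.s2]]),
        "B": np.array([[pair_b.s1, pair_b.s2]]),
    }
    contrasts = {}
    for name, s in s_by_tissue.items():
        draws = rng.standard_normal((1, noise.n_reps, 2, 2)) * noise.sigma
        s1 = s[:, None, 0] + draws[..., 0, 0] + 1j * draws[..., 0, 1]
        s2 = s[:, None, 1] + draws[..., 1, 0] + 1j * draws[..., 1, 1]
        contrasts[name] = uni(s1, s2) if combiner == "uni" else flaws_min(
            np.abs(s1), np.abs(s2))
    diff = contrasts["A"] - contrasts["B"]
    sd = float(diff.std())
    return float(diff.mean() / sd) if sd > 0 else 0.0


def b1_averaged_cnr(
    seq: SequenceParams,
    tissues: Mapping[str, TissueParams],
    fa_pair: tuple[float, float],
    b1: B1Grid | None = None,
    noise: NoiseModel | None = None,
) -> dict:
    """Per-channel signed CNRs averaged over the B1+ grid for one FA pair.

    Averaging is arithmetic over the per-scale signed CNRs, matching the
    way the flip-angle maps are scored.  Also returns ``uni_total``,
    ``flaws_total`` and the per-unit-time ``cnr_total``.
    """
    b1 = b1 or B1Grid()
    noise = noise or NoiseModel()
    channels = grid_channel_cnrs(seq, tissues, list(b1.scales),
                                 [fa_pair], noise)
    out = {k: float(v[0]) for k, v in channels.items()}
    return out


def grid_channel_cnrs(
    seq: SequenceParams,
    tissues: Mapping[str, TissueParams],
    b1_scales: Sequence[float],
    fa_pairs: Sequence[tuple[float, float]],
    noise: NoiseModel,
    max_cycles: int = 50,
) -> dict:
    """B1-averaged per-channel CNRs for every flip-angle pair.

    The EPG steady state is simulated for the whole (B1, FA) batch per
    tissue; the Monte-Carlo stage then processes one FA pair at a time
    with an independent, reproducible noise substream per pair (spawned
    from ``noise.seed``).  Returns arrays of shape ``(n_pairs,)`` for the
    four component channels plus ``uni_total``, ``flaws_total`` and
    ``cnr_total``.
    """
    if noise.sigma is None:
        raise ValueError("noise.sigma must be calibrated before Monte-Carlo runs")
    b1_scales = list(b1_scales)
    fa_pairs = [tuple(p) for p in fa_pairs]
    signals = {
        name: simulate_signal_grid(seq, t, b1_scales, fa_pairs,
                                   max_cycles=max_cycles)
        for name, t in tissues.items()
    }
    n_pairs = len(fa_pairs)
    streams = np.random.SeedSequence(noise.seed).spawn(n_pairs)
    acc = {c[0]: np.empty(n_pairs) for c in COMPONENT_CHANNELS}
    for p in range(n_pairs):
        rng = np.random.default_rng(streams[p])
        s_by_tissue = {name: sig[:, p, :] for name, sig in signals.items()}
        per_b1 = _noisy_channels(s_by_tissue, noise.sigma, noise.n_reps, rng)
        for channel, vals in per_b1.items():
            acc[channel][p] = vals.mean()
    acc["uni_total"] = acc["uni_wm_gm"] + acc["uni_gm_csf"]
    acc["flaws_total"] = acc["flaws_gm_wm"] + acc["flaws_gm_csf"]
    acc["cnr_total"] = cnr_total(
        {c[0]: acc[c[0]] for c in COMPONENT_CHANNELS}, seq.tr_mp2rage)
    return acc


def cnr_total(channels: Mapping[str, np.ndarray | float], tr_mp2rage: float):
    """Joint objective: sum of the four component channels per sqrt(TR).

    ``channels`` must contain ``uni_wm_gm``, ``uni_gm_csf``,
    ``flaws_gm_wm`` and ``flaws_gm_csf``; TR in ms, result per sqrt(ms).
    """
    total = (np.asarray(channels["flaws_gm_csf"]) + np.asarray(channels["flaws_gm_wm"])
             + np.asarray(channels["uni_wm_gm"]) + np.asarray(channels["uni_gm_csf"]))
    out = total / np.sqrt(tr_mp2rage)
    return out if np.ndim(out) else float(out)
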