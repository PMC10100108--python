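"""MP2RAGE sequence assembly, steady-state EPG simulation and timing math.

One MP2RAGE cycle is: adiabatic inversion -> delay TA -> first GRE block
(INV1, nominal flip alpha1) -> delay TB -> second GRE block (INV2, alpha2)
-> delay TC -> next inversion.  TI1 and TI2 are measured from the inversion
pulse to the excitation of the k-space-center line of each block, so the
delays follow from the TIs, the block length and the center-line index.

The simulator iterates whole cycles from thermal equilibrium until the two
recorded center-of-k-space signals reach a periodic steady state.  Signals
are recorded immediately after the excitation pulse and demodulated by the
transmit phase of that pulse (the receiver tracks the transmitter under RF
spoiling), so that for an ideally spoiled train the recorded signal is the
real quantity ``sin(alpha) * Mz``.

``closed_form_signal`` provides the classical ideal-spoiling longitudinal
recursion (complete transverse spoiling each TR), solved exactly as the
fixed point of the affine one-cycle map.  It is both a fast approximation
and an independent oracle for the EPG engine in the T2 -> 0 limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .epg import (
    SpoilingSchedule,
    TissueParams,
    _apply_rotation,
    _apply_shift,
    diffusion_factors,
    rf_spoil_phases,
    TRUNCATION_THRESHOLD,
)

__all__ = [
    "SequenceParams",
    "BlockTiming",
    "SignalPair",
    "SimulationToggles",
    "InfeasibleTimingError",
    "ConvergenceError",
    "block_timing",
    "center_index",
    "is_feasible",
    "simulate_steady_state",
    "simulate_signal_grid",
    "closed_form_signal",
    "scan_duration",
]


class InfeasibleTimingError(ValueError):
    """Raised when a TI/TR combination leaves a negative inter-block delay."""


class ConvergenceError(RuntimeError):
    """Raised when the steady-state iteration fails to converge."""


@dataclass(frozen=True)
class SequenceParams:
    """Full MP2RAGE protocol description.  All times in ms, angles in degrees.

    ``n_exc`` is the number of excitations per GRE block and ``k_center``
    the 0-based index of the excitation that acquires the k-space center
    (set by the partial-Fourier factor, see :func:`center_index`).  ``te``
    is recorded for bookkeeping only: both images share it and the ratio
    contrasts cancel T2* weighting, so it plays no role in signal formation.
    """

    tr_mp2rage: float
    tr_gre: float
    ti1: float
    ti2: float
    alpha1: float
    alpha2: float
    n_exc: int
    k_center: int
    spoiling: SpoilingSchedule = field(default_factory=SpoilingSchedule)
    eff: float = 1.0
    te: float | None = None

    def __post_init__(self) -> None:
        for name in ("tr_mp2rage", "tr_gre", "ti1", "ti2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.ti1 < self.ti2 < self.tr_mp2rage:
            raise ValueError("require TI1 < TI2 < TR_MP2RAGE")
        if self.n_exc < 1:
            raise ValueError("n_exc must be >= 1")
        if not 0 <= self.k_center < self.n_exc:
            raise ValueError("k_center must be in [0, n_exc)")
        if not 0 <= self.eff <= 1:
            raise ValueError("eff must be in [0, 1]")

    def with_flips(self, alpha1: float, alpha2: float) -> "SequenceParams":
        return replace(self, alpha1=alpha1, alpha2=alpha2)


@dataclass(frozen=True)
class BlockTiming:
    """Free-relaxation delays of one cycle: TA (pre-block-1), TB, TC."""

    ta: float
    tb: float
    tc: float


@dataclass(frozen=True)
class SignalPair:
    """Complex INV1/INV2 center-of-k-space signals for one tissue x B1."""

    s1: complex
    s2: complex
    tissue: str = ""
    b1_scale: float = 1.0


@dataclass(frozen=True)
class SimulationToggles:
    """Physics toggles for the effect-isolation experiments.

    ``use_t2=False`` annihilates the transverse magnetization every TR
    (ideal spoiling), in which case neither diffusion nor RF phase cycling
    can influence the signal.  ``use_rf_spoiling=False`` fires every pulse
    with a constant (zero) phase.
    """

    use_t2: bool = True
    use_diffusion: bool = True
    use_rf_spoiling: bool = True


def block_timing(seq: SequenceParams) -> BlockTiming:
    """Delays implied by the TI definitions; raises if any is negative."""
    ta = seq.ti1 - seq.k_center * seq.tr_gre
    tb = seq.ti2 - seq.ti1 - seq.n_exc * seq.tr_gre
    tc = seq.tr_mp2rage - seq.ti2 - (seq.n_exc - seq.k_center) * seq.tr_gre
    if ta < 0 or tb < 0 or tc < 0:
        raise InfeasibleTimingError(
            f"infeasible TI/TR combination: TA={ta:.1f}, TB={tb:.1f}, TC={tc:.1f} ms "
            f"(TI1={seq.ti1}, TI2={seq.ti2}, TR={seq.tr_mp2rage})"
        )
    return BlockTiming(ta, tb, tc)


def is_feasible(seq: SequenceParams) -> bool:
    try:
        block_timing(seq)
    except InfeasibleTimingError:
        return False
    return True


def center_index(n_inner: int, partial_fourier: float) -> int:
    """Index of the k-space-center excitation under linear ordering.

    A partial-Fourier factor ``pf`` keeps the last ``pf * n_inner`` lines of
    the full matrix, so the (asymmetric) center is reached after
    ``n_inner * (pf - 1/2)`` acquired lines.
    """
    if not 0.5 < partial_fourier <= 1:
        raise ValueError("partial_fourier must be in (0.5, 1]")
    return int(round(n_inner * (partial_fourier - 0.5)))


def scan_duration(seq: SequenceParams, n_outer: int, grappa: int = 1,
                  acs_lines: int = 0, pf_outer: float = 1.0) -> float:
    """Acquisition time in seconds: one TR_MP2RAGE per acquired outer line.

    Outer phase-encode lines after partial Fourier are undersampled by the
    GRAPPA factor; the autocalibration block re-acquires the fraction of
    its lines that the regular pattern skips.
    """
    if grappa < 1:
        raise ValueError("grappa must be >= 1")
    acquired = math.ceil(n_outer * pf_outer / grappa) + acs_lines * (1.0 - 1.0 / grappa)
    return math.ceil(acquired) * seq.tr_mp2rage / 1000.0


# ---------------------------------------------------------------------------
# steady-state EPG engine (batched over B1 scales x flip-angle pairs)
# ---------------------------------------------------------------------------

def _ideal_spoiling_mz_fixed_point(seq, tissue, timing, flips1_rad, flips2_rad):
    """Mz immediately before the inversion under ideal spoiling, per batch."""
    pd = tissue.PD
    e1_tr = math.exp(-seq.tr_gre / tissue.T1)
    rec = pd * (1.0 - e1_tr)
    a = np.full_like(flips1_rad, -seq.eff)
    b = np.zeros_like(flips1_rad)
    for dt, flips in ((timing.ta, flips1_rad), (timing.tb, flips2_rad),
                      (timing.tc, None)):
        e = math.exp(-dt / tissue.T1)
        a, b = e * a, e * b + pd * (1.0 - e)
        if flips is None:
            break
        pa = np.cos(flips) * e1_tr
        pan = pa ** seq.n_exc
        pb = np.where(pa != 1.0, rec * (1.0 - pan) / (1.0 - pa), rec * seq.n_exc)
        a, b = pan * a, pan * b + pb
    return b / (1.0 - a)

def simulate_signal_grid(
    seq: SequenceParams,
    tissue: TissueParams,
    b1_scales,
    fa_pairs,
    toggles: SimulationToggles | None = None,
    max_order: int | None = None,
    tol: float = 1e-9,
    max_cycles: int = 50,
) -> np.ndarray:
    """Steady-state INV1/INV2 signals for every (B1 scale, flip pair).

    Parameters
    ----------
    b1_scales : array-like of float
        Transmit-field scaling factors applied to both nominal flips.
    fa_pairs : array-like of (alpha1, alpha2) in degrees
        Nominal flip-angle combinations.
    toggles : SimulationToggles, optional
        Physics toggles; all effects on by default.

    Returns
    -------
    ndarray, shape (n_b1, n_pairs, 2), complex
        Demodulated center-of-k-space signals (INV1, INV2), in units of the
        equilibrium magnetization (i.e. already scaled by PD).
    """
    toggles = toggles or SimulationToggles()
    timing = block_timing(seq)
    b1 = np.atleast_1d(np.asarray(b1_scales, dtype=float))
    pairs = np.atleast_2d(np.asarray(fa_pairs, dtype=float))
    if np.any(b1 <= 0):
        raise ValueError("b1 scales must be positive")
    n_b1, n_pairs = b1.size, pairs.shape[0]

    # batch layout: (b1, pair) flattened, order axis last
    flips1 = np.deg2rad(np.outer(b1, pairs[:, 0]).reshape(-1, 1))
    flips2 = np.deg2rad(np.outer(b1, pairs[:, 1]).reshape(-1, 1))
    batch = flips1.shape[0]

    k_cap = 2 * seq.n_exc + 2 if max_order is None else max_order
    Fp = np.zeros((batch, k_cap + 1), dtype=complex)
    Fm = np.zeros_like(Fp)
    Z = np.zeros_like(Fp)
    # warm start at the ideal-spoiling fixed point of Mz before the
    # inversion; the 1e-9 cycle-to-cycle criterion below still decides
    # convergence, this only shortens the transient
    Z[:, 0] = _ideal_spoiling_mz_fixed_point(seq, tissue, timing,
                                             flips1[:, 0], flips2[:, 0])

    phases = np.deg2rad(rf_spoil_phases(2 * seq.n_exc, seq.spoiling.phase_increment))
    if not toggles.use_rf_spoiling:
        phases = np.zeros_like(phases)

    use_diff = toggles.use_diffusion and tissue.D > 0
    if use_diff:
        ap_tr, am_tr, az_tr = diffusion_factors(k_cap + 1, seq.tr_gre, tissue,
                                                seq.spoiling, shifting=True)
        static = {
            dt: diffusion_factors(k_cap + 1, dt, tissue, seq.spoiling, shifting=False)
            for dt in {timing.ta, timing.tb, timing.tc}
        }

    e1_tr = np.exp(-seq.tr_gre / tissue.T1)
    e2_tr = np.exp(-seq.tr_gre / tissue.T2)
    rec_tr = tissue.PD * (1.0 - e1_tr)

    # active-order window: k_active grows with each gradient shift and is
    # trimmed wherever trailing amplitudes fall below the truncation threshold
    k_active = 0

    def free_delay(dt: float, k_hi: int) -> None:
        e1 = np.exp(-dt / tissue.T1)
        e2 = np.exp(-dt / tissue.T2)
        Fp[:, : k_hi + 1] *= e2
        Fm[:, : k_hi + 1] *= e2
        Z[:, : k_hi + 1] *= e1
        Z[:, 0] += tissue.PD * (1.0 - e1)
        if use_diff and dt > 0:
            ap, am, az = static[dt]
            Fp[:, : k_hi + 1] *= ap[: k_hi + 1]
            Fm[:, : k_hi + 1] *= am[: k_hi + 1]
            Z[:, : k_hi + 1] *= az[: k_hi + 1]

    def run_block(flips, phase_offset: int, record_at: int):
        nonlocal k_active
        recorded = None
        c2 = np.cos(flips / 2.0) ** 2
        s2 = np.sin(flips / 2.0) ** 2
        sa = np.sin(flips)
        ca = np.cos(flips)
        for j in range(seq.n_exc):
            phi = phases[phase_offset + j]
            eip = np.exp(1j * phi)
            eim = np.conj(eip)
            coeffs = (c2, s2 * eip * eip, -1j * eip * sa,
                      s2 * eim * eim, c2, 1j * eim * sa,
                      -0.5j * eim * sa, 0.5j * eip * sa, ca)
            hi = k_active + 1
            fp, fm, z = Fp[:, :hi], Fm[:, :hi], Z[:, :hi]
            fp2, fm2, z2 = _apply_rotation(fp, fm, z, coeffs)
            Fp[:, :hi], Fm[:, :hi], Z[:, :hi] = fp2, fm2, z2
            if j == record_at:
                # demodulate by the transmit phase; the extra i makes the
                # ideally spoiled signal real and signed (sin(a) * Mz)
                recorded = 1j * np.exp(-1j * phi) * Fp[:, 0].copy()
            if not toggles.use_t2:
                Fp[:, :hi] = 0.0
                Fm[:, :hi] = 0.0
                Z[:, :hi] *= e1_tr
                Z[:, 0] += rec_tr
                continue
            Fp[:, :hi] *= e2_tr
            Fm[:, :hi] *= e2_tr
            Z[:, :hi] *= e1_tr
            Z[:, 0] += rec_tr
            if use_diff:
                Fp[:, :hi] *= ap_tr[:hi]
                Fm[:, :hi] *= am_tr[:hi]
                Z[:, :hi] *= az_tr[:hi]
            hi2 = min(k_active + 1, k_cap) + 1
            Fp[:, :hi2], Fm[:, :hi2], Z[:, :hi2] = _apply_shift(
                Fp[:, :hi2], Fm[:, :hi2], Z[:, :hi2]
            )
            k_active = min(k_active + 1, k_cap)
            # trim the window where trailing orders have decayed away
            while k_active > 0 and (
                np.max(np.abs(Fp[:, k_active])) < TRUNCATION_THRESHOLD
                and np.max(np.abs(Fm[:, k_active])) < TRUNCATION_THRESHOLD
                and np.max(np.abs(Z[:, k_active])) < TRUNCATION_THRESHOLD
            ):
                Fp[:, k_active] = 0.0
                Fm[:, k_active] = 0.0
                Z[:, k_active] = 0.0
                k_active -= 1
        return recorded

    s_prev = None
    for cycle in range(max_cycles):
        # inversion with post-pulse crusher
        hi = k_active + 1
        Z[:, :hi] *= -seq.eff
        Fp[:, :hi] = 0.0
        Fm[:, :hi] = 0.0
        free_delay(timing.ta, k_active)
        s1 = run_block(flips1, 0, seq.k_center)
        free_delay(timing.tb, k_active)
        s2 = run_block(flips2, seq.n_exc, seq.k_center)
        free_delay(timing.tc, k_active)
        s = np.stack([s1, s2], axis=-1)
        if s_prev is not None:
            scale = max(np.max(np.abs(s)), 1e-30)
            if np.max(np.abs(s - s_prev)) < tol * scale:
                return s.reshape(n_b1, n_pairs, 2)
        s_prev = s
    raise ConvergenceError(
        f"steady state not reached after {max_cycles} cycles "
        f"(tissue {tissue.name}, TR {seq.tr_mp2rage} ms, tol {tol})"
    )


def simulate_steady_state(
    seq: SequenceParams,
    tissue: TissueParams,
    b1_scale: float = 1.0,
    toggles: SimulationToggles | None = None,
    max_order: int | None = None,
    tol: float = 1e-9,
    max_cycles: int = 50,
) -> SignalPair:
    """Steady-state INV1/INV2 signals for one tissue at one B1 scale."""
    sig = simulate_signal_grid(seq, tissue, [b1_scale],
                               [(seq.alpha1, seq.alpha2)], toggles=toggles,
                               max_order=max_order, tol=tol, max_cycles=max_cycles)
    return SignalPair(complex(sig[0, 0, 0]), complex(sig[0, 0, 1]),
                      tissue=tissue.name, b1_scale=b1_scale)


# ---------------------------------------------------------------------------
# ideal-spoiling closed form (longitudinal recursion, affine fixed point)
# ---------------------------------------------------------------------------

def _compose(a1, b1, a2, b2):
    """Composition (second after first) of affine maps x -> a x + b."""
    return a2 * a1, a2 * b1 + b2


def closed_form_signal(
    seq: SequenceParams,
    tissue: TissueParams,
    b1_scale: float = 1.0,
    eff: float | None = None,
) -> SignalPair:
    """INV1/INV2 signals under ideal transverse spoiling.

    Only Mz is propagated: inversion, mono-exponential recovery over the
    delays, and a ``cos(alpha) * E1`` recursion per excitation.  The
    periodic steady state is the fixed point of the affine one-cycle map;
    the recorded signal is ``sin(alpha) * Mz`` just before each center
    pulse.
    """
    timing = block_timing(seq)
    eff = seq.eff if eff is None else eff
    pd = tissue.PD
    e1_tr = math.exp(-seq.tr_gre / tissue.T1)
    rec = pd * (1.0 - e1_tr)

    def delay_map(dt):
        e = math.exp(-dt / tissue.T1)
        return e, pd * (1.0 - e)

    def pulse_tr_map(alpha_rad):
        return math.cos(alpha_rad) * e1_tr, rec

    a1r = math.radians(seq.alpha1 * b1_scale)
    a2r = math.radians(seq.alpha2 * b1_scale)

    # one full cycle starting right before the inversion
    a, b = -eff, 0.0
    a, b = _compose(a, b, *delay_map(timing.ta))
    pa, pb = pulse_tr_map(a1r)
    a, b = _compose(a, b, pa ** seq.n_exc, pb * (1 - pa ** seq.n_exc) / (1 - pa)
                    if pa != 1 else pb * seq.n_exc)
    a, b = _compose(a, b, *delay_map(timing.tb))
    pa2, pb2 = pulse_tr_map(a2r)
    a, b = _compose(a, b, pa2 ** seq.n_exc, pb2 * (1 - pa2 ** seq.n_exc) / (1 - pa2)
                    if pa2 != 1 else pb2 * seq.n_exc)
    a, b = _compose(a, b, *delay_map(timing.tc))
    if abs(1.0 - a) < 1e-15:
        raise ConvergenceError("degenerate cycle map: no unique fixed point")
    mz = b / (1.0 - a)  # Mz immediately before the inversion

    # walk the converged cycle to the two center pulses
    mz = -eff * mz
    da, db = delay_map(timing.ta)
    mz = da * mz + db
    mz = (pa ** seq.k_center) * mz + (
        pb * (1 - pa ** seq.k_center) / (1 - pa) if pa != 1 else pb * seq.k_center
    )
    s1 = math.sin(a1r) * mz
    rest = seq.n_exc - seq.k_center
    mz = (pa ** rest) * mz + (
        pb * (1 - pa ** rest) / (1 - pa) if pa != 1 else pb * rest
    )
    da, db = delay_map(timing.tb)
    mz = da * mz + db
    mz = (pa2 ** seq.k_center) * mz + (
        pb2 * (1 - pa2 ** seq.k_center) / (1 - pa2) if pa2 != 1 else pb2 * seq.k_center
    )
    s2 = math.sin(a2r) * mz
    return SignalPair(complex(s1), complex(s2), tissue=tissue.name, b1_scale=b1_scale)
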