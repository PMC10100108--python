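"""Extended phase graph (EPG) primitives for RF-spoiled gradient-echo simulation.

The magnetization of an isochromat ensemble is represented by configuration
states ``F+(k)``, ``F-(k)`` and ``Z(k)`` indexed by the integer dephasing
order ``k`` (cycles of gradient-induced dephasing across one voxel).  The
elementary operators in this module — RF rotation, relaxation/recovery,
gradient shift, diffusion attenuation and inversion — are composed by
:mod:`mp2flaws.sequence` into the MP2RAGE timing structure.

All amplitudes are complex.  ``F-(k)`` stores the conjugate of the ``-k``
transverse configuration, so ``F-(0) == conj(F+(0))`` at all times.  The
operators act on the trailing axis of arbitrarily batched arrays, which is
what makes grid searches over flip angles and B1 scales affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueParams",
    "SpoilingSchedule",
    "EPGState",
    "equilibrium_state",
    "rf_rotation",
    "relax_recover",
    "gradient_shift",
    "diffusion_attenuate",
    "invert",
    "rf_spoil_phase",
]

#: amplitudes below this are treated as numerically zero when truncating orders
TRUNCATION_THRESHOLD = 1e-10


@dataclass(frozen=True)
class TissueParams:
    """Relaxation, density and diffusion parameters of one tissue class.

    Parameters
    ----------
    name : str
        Label, e.g. ``"WM"``, ``"GM"`` or ``"CSF"``.
    T1, T2 : float
        Longitudinal / transverse relaxation times in ms.  ``T2 <= T1``.
    PD : float
        Relative proton density in ``(0, 1]``.
    D : float
        Apparent diffusion coefficient in mm^2/s.
    """

    name: str
    T1: float
    T2: float
    PD: float
    D: float = 0.0

    def __post_init__(self) -> None:
        if not self.T1 > 0:
            raise ValueError(f"T1 must be positive, got {self.T1}")
        if not self.T2 > 0:
            raise ValueError(f"T2 must be positive, got {self.T2}")
        if self.T2 > self.T1:
            raise ValueError(f"T2 ({self.T2}) must not exceed T1 ({self.T1})")
        if not 0 < self.PD <= 1:
            raise ValueError(f"PD must be in (0, 1], got {self.PD}")
        if self.D < 0:
            raise ValueError(f"D must be non-negative, got {self.D}")


@dataclass(frozen=True)
class SpoilingSchedule:
    """RF and gradient spoiling configuration.

    ``phase_increment`` is the quadratic RF phase-cycling increment in
    degrees.  ``dephasing_per_tr`` is the gradient-induced dephasing across
    one voxel per GRE repetition, in cycles; together with ``voxel_size``
    (mm) it sets the diffusion b-factors of the stored configurations.
    """

    phase_increment: float = 50.0
    dephasing_per_tr: float = 1.0
    voxel_size: float = 0.65

    def __post_init__(self) -> None:
        if not 0 <= self.phase_increment < 360:
            raise ValueError("phase_increment must be in [0, 360)")
        if not self.dephasing_per_tr > 0:
            raise ValueError("dephasing_per_tr must be positive")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def grad_wavenumber(self) -> float:
        """Dephasing wavenumber accrued per TR, in rad/mm."""
        return 2.0 * np.pi * self.dephasing_per_tr / self.voxel_size


@dataclass
class EPGState:
    """Configuration-state amplitudes of one isochromat ensemble.

    ``Fplus[k]``, ``Fminus[k]`` and ``Z[k]`` hold the amplitudes for
    dephasing orders ``k = 0..max_order``.  ``PD`` records the equilibrium
    magnitude toward which ``Z(0)`` recovers.
    """

    Fplus: np.ndarray
    Fminus: np.ndarray
    Z: np.ndarray
    PD: float = 1.0

    def __post_init__(self) -> None:
        self.Fplus = np.asarray(self.Fplus, dtype=complex)
        self.Fminus = np.asarray(self.Fminus, dtype=complex)
        self.Z = np.asarray(self.Z, dtype=complex)
        if not (self.Fplus.shape == self.Fminus.shape == self.Z.shape):
            raise ValueError("Fplus, Fminus and Z must share one shape")

    @property
    def max_order(self) -> int:
        return self.Fplus.shape[-1] - 1

    def copy(self) -> "EPGState":
        return EPGState(self.Fplus.copy(), self.Fminus.copy(), self.Z.copy(), self.PD)

    def transverse_magnitude(self) -> float:
        """Total transverse configuration magnitude, sum over orders."""
        return float(np.sum(np.abs(self.Fplus)) + np.sum(np.abs(self.Fminus[..., 1:])))


def equilibrium_state(tissue: TissueParams, max_order: int) -> EPGState:
    """Thermal equilibrium: ``Z(0) = PD``, everything else zero."""
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    n = max_order + 1
    state = EPGState(np.zeros(n, complex), np.zeros(n, complex), np.zeros(n, complex),
                     PD=tissue.PD)
    state.Z[0] = tissue.PD
    return state


# ---------------------------------------------------------------------------
# batched kernels — operate on the trailing (order) axis of (..., K+1) arrays
# ---------------------------------------------------------------------------

def rotation_coefficients(flip_rad, phase_rad):
    """The 3x3 configuration-state mixing coefficients for an RF pulse.

    Returns the nine coefficients ``(a..i)`` of the matrix that maps
    ``(F+, F-, Z)`` at every order.  ``flip_rad`` may be an array (it
    broadcasts against the batch); ``phase_rad`` is scalar.
    """
    flip_rad = np.asarray(flip_rad, dtype=float)
    c2 = np.cos(flip_rad / 2.0) ** 2
    s2 = np.sin(flip_rad / 2.0) ** 2
    sa = np.sin(flip_rad)
    ca = np.cos(flip_rad)
    eip = np.exp(1j * phase_rad)
    eim = np.conj(eip)
    return (
        c2, s2 * eip ** 2, -1j * eip * sa,
        s2 * eim ** 2, c2, 1j * eim * sa,
        -0.5j * eim * sa, 0.5j * eip * sa, ca,
    )


def _apply_rotation(Fp, Fm, Z, coeffs):
    a, b, c, d, e, f, g, h, i = coeffs
    Fp_new = a * Fp + b * Fm + c * Z
    Fm_new = d * Fp + e * Fm + f * Z
    Z_new = g * Fp + h * Fm + i * Z
    return Fp_new, Fm_new, Z_new


def _apply_relax(Fp, Fm, Z, dt, tissue: TissueParams, recover: bool = True):
    e2 = np.exp(-dt / tissue.T2)
    e1 = np.exp(-dt / tissue.T1)
    Fp = Fp * e2
    Fm = Fm * e2
    Z = Z * e1
    if recover:
        Z[..., 0] += tissue.PD * (1.0 - e1)
    return Fp, Fm, Z


def _apply_shift(Fp, Fm, Z):
    """One cycle of gradient dephasing: F+ orders up, F- orders down."""
    Fp_new = np.empty_like(Fp)
    Fm_new = np.empty_like(Fm)
    Fp_new[..., 1:] = Fp[..., :-1]
    Fp_new[..., 0] = np.conj(Fm[..., 1]) if Fm.shape[-1] > 1 else 0.0
    Fm_new[..., :-1] = Fm[..., 1:]
    Fm_new[..., -1] = 0.0
    # keep the F-(0) = conj(F+(0)) redundancy coherent
    Fm_new[..., 0] = np.conj(Fp_new[..., 0])
    return Fp_new, Fm_new, Z


def diffusion_factors(n_orders: int, dt: float, tissue: TissueParams,
                      spoiling: SpoilingSchedule, shifting: bool = True):
    """Per-order diffusion attenuation factors over an interval ``dt`` (ms).

    With the spoiler gradient on (``shifting=True``) the transverse order
    ``k`` moves linearly to ``k+1`` during the interval, giving the b-factor
    ``kg^2 * dt * (k^2 + k + 1/3)`` for ``F+`` (and ``k^2 - k + 1/3`` for the
    stored conjugate orders in ``F-``, which move from ``-k`` to ``-k+1``).
    Longitudinal configurations keep a static wavenumber: ``b = kg^2 dt k^2``.
    With the gradient off, all orders are static.
    """
    k = np.arange(n_orders, dtype=float)
    kg2 = spoiling.grad_wavenumber ** 2
    dt_s = dt / 1000.0  # D is in mm^2/s
    if shifting:
        b_plus = kg2 * dt_s * (k ** 2 + k + 1.0 / 3.0)
        b_minus = kg2 * dt_s * (k ** 2 - k + 1.0 / 3.0)
    else:
        b_plus = b_minus = kg2 * dt_s * k ** 2
    b_z = kg2 * dt_s * k ** 2
    return np.exp(-b_plus * tissue.D), np.exp(-b_minus * tissue.D), np.exp(-b_z * tissue.D)


# ---------------------------------------------------------------------------
# public single-state operators
# ---------------------------------------------------------------------------

def rf_rotation(state: EPGState, flip: float, phase: float = 0.0) -> EPGState:
    """Apply an RF pulse of the given flip angle and phase (degrees).

    Mixes every order's ``(F+, F-, Z)`` triple with the standard
    configuration-state rotation matrix; conserves ``|F+|^2+|F-|^2+2|Z|^2``
    per order.
    """
    if not 0 <= flip < 360:
        raise ValueError(f"flip must be in [0, 360) degrees, got {flip}")
    coeffs = rotation_coefficients(np.deg2rad(flip), np.deg2rad(phase))
    Fp, Fm, Z = _apply_rotation(state.Fplus, state.Fminus, state.Z, coeffs)
    return EPGState(Fp, Fm, Z, state.PD)


def relax_recover(state: EPGState, dt: float, tissue: TissueParams) -> EPGState:
    """T2 decay on F, T1 decay on Z, with ``Z(0)`` recovery toward PD."""
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    Fp, Fm, Z = _apply_relax(state.Fplus.copy(), state.Fminus.copy(),
                             state.Z.copy(), dt, tissue)
    return EPGState(Fp, Fm, Z, state.PD)


def gradient_shift(state: EPGState) -> EPGState:
    """Advance transverse configurations by one dephasing cycle.

    ``F+`` orders move up, ``F-`` orders move down with the ``F-(1)`` state
    crossing into ``conj(F+(0))``; amplitudes pushed past ``max_order`` are
    dropped (truncation).  ``Z`` is untouched.
    """
    Fp, Fm, Z = _apply_shift(state.Fplus, state.Fminus, state.Z.copy())
    return EPGState(Fp, Fm, Z, state.PD)


def diffusion_attenuate(state: EPGState, dt: float, tissue: TissueParams,
                        spoiling: SpoilingSchedule, shifting: bool = True) -> EPGState:
    """Attenuate configurations by diffusion through the spoiler gradient."""
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    ap, am, az = diffusion_factors(state.max_order + 1, dt, tissue, spoiling, shifting)
    return EPGState(state.Fplus * ap, state.Fminus * am, state.Z * az, state.PD)


def invert(state: EPGState, eff: float = 1.0) -> EPGState:
    """Adiabatic inversion: ``Z -> -eff * Z``, transverse crushed."""
    if not 0 <= eff <= 1:
        raise ValueError(f"eff must be in [0, 1], got {eff}")
    Fp = np.zeros_like(state.Fplus)
    Fm = np.zeros_like(state.Fminus)
    return EPGState(Fp, Fm, -eff * state.Z, state.PD)


def rf_spoil_phase(pulse_index: int, increment: float = 50.0) -> float:
    """Quadratic RF-spoiling phase ``inc * n(n+1)/2 mod 360`` in degrees."""
    if pulse_index < 0:
        raise ValueError("pulse_index must be >= 0")
    n = pulse_index
    return float((increment * (n * (n + 1)) / 2.0) % 360.0)


def rf_spoil_phases(n_pulses: int, increment: float = 50.0) -> np.ndarray:
    """Vector of quadratic spoiling phases for pulses ``0..n_pulses-1`` (deg)."""
    n = np.arange(n_pulses, dtype=float)
    return (increment * n * (n + 1) / 2.0) % 360.0
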