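"""Elementary EPG operators against closed forms and a Bloch-ensemble oracle.

The independent oracle simulates N uniformly dephased isochromats with
plain 3x3 Bloch rotation matrices and extracts configuration amplitudes by
a discrete Fourier transform over the dephasing angle; it shares no code
with the EPG operators it checks.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mp2flaws.epg import (
    SpoilingSchedule,
    TissueParams,
    diffusion_attenuate,
    diffusion_factors,
    equilibrium_state,
    gradient_shift,
    invert,
    relax_recover,
    rf_rotation,
    rf_spoil_phase,
    rf_spoil_phases,
)


# ---------------------------------------------------------------------------
# Bloch isochromat-ensemble oracle
# ---------------------------------------------------------------------------

def bloch_rotation_matrix(flip_deg: float, phase_deg: float) -> np.ndarray:
    """3x3 rotation of (mx, my, mz): flip about the phase axis.

    Convention chosen to match F+ = mx + i my with a pulse of phase 0
    tipping +z toward -y.
    """
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    rz = lambda t: np.array([[np.cos(t), -np.sin(t), 0],
                             [np.sin(t), np.cos(t), 0],
                             [0, 0, 1]])
    rx = np.array([[1, 0, 0],
                   [0, np.cos(a), -np.sin(a)],
                   [0, np.sin(a), np.cos(a)]])
    return rz(p) @ rx @ rz(-p)


class IsochromatEnsemble:
    """N uniformly dephased spins; configuration states via DFT."""

    def __init__(self, n: int, pd: float = 1.0):
        self.theta = 2 * np.pi * np.arange(n) / n
        self.m = np.zeros((n, 3))
        self.m[:, 2] = pd
        self.pd = pd

    def rotate(self, flip, phase):
        self.m = self.m @ bloch_rotation_matrix(flip, phase).T

    def dephase(self):
        """One gradient cycle: spin j precesses by its own theta_j."""
        mxy = (self.m[:, 0] + 1j * self.m[:, 1]) * np.exp(1j * self.theta)
        self.m[:, 0], self.m[:, 1] = mxy.real, mxy.imag

    def relax(self, dt, tissue):
        e1, e2 = np.exp(-dt / tissue.T1), np.exp(-dt / tissue.T2)
        self.m[:, :2] *= e2
        self.m[:, 2] = self.m[:, 2] * e1 + tissue.PD * (1 - e1)

    def f_config(self, k: int) -> complex:
        mxy = self.m[:, 0] + 1j * self.m[:, 1]
        return np.mean(mxy * np.exp(-1j * k * self.theta))

    def z_config(self, k: int) -> complex:
        return np.mean(self.m[:, 2] * np.exp(-1j * k * self.theta))


WM = TissueParams("WM", 1220.0, 45.9, 0.69)


def test_equilibrium_state():
    state = equilibrium_state(WM, max_order=200)
    assert state.Z[0] == pytest.approx(0.69)
    assert np.all(state.Z[1:] == 0)
    assert state.transverse_magnitude() == 0.0
    unit = equilibrium_state(TissueParams("t", 1000, 100, 1.0), 5)
    assert unit.Z[0] == 1.0


def test_rotation_identity_and_full_tip():
    state = equilibrium_state(TissueParams("t", 1000, 100, 1.0), 10)
    same = rf_rotation(state, 0.0, 0.0)
    assert np.allclose(same.Z, state.Z) and same.transverse_magnitude() == 0
    tipped = rf_rotation(state, 90.0, 0.0)
    assert abs(tipped.Fplus[0]) == pytest.approx(1.0)
    assert abs(tipped.Z[0]) == pytest.approx(0.0, abs=1e-15)


def test_rotation_rejects_out_of_range_flip():
    state = equilibrium_state(WM, 4)
    with pytest.raises(ValueError):
        rf_rotation(state, 360.0, 0.0)
    with pytest.raises(ValueError):
        rf_rotation(state, -5.0, 0.0)


def test_rotation_matches_bloch_ensemble_single_pulse():
    """30 deg / 50 deg pulse on equilibrium vs 360-isochromat Bloch rotation."""
    state = rf_rotation(equilibrium_state(TissueParams("t", 1000, 100, 1.0), 4),
                        30.0, 50.0)
    ens = IsochromatEnsemble(360)
    ens.rotate(30.0, 50.0)
    assert state.Fplus[0] == pytest.approx(ens.f_config(0), abs=1e-12)
    assert state.Fminus[0] == pytest.approx(np.conj(ens.f_config(0)), abs=1e-12)
    assert state.Z[0] == pytest.approx(ens.z_config(0), abs=1e-12)


@given(
    flip=st.floats(min_value=0, max_value=359.9),
    phase=st.floats(min_value=0, max_value=360),
)
def test_rotation_conserves_configuration_norm(flip, phase):
    """|F+|^2 + |F-|^2 + 2|Z|^2 per order is invariant under any pulse."""
    rng = np.random.default_rng(0)
    state = equilibrium_state(WM, 6)
    state.Fplus[:] = rng.standard_normal(7) + 1j * rng.standard_normal(7)
    state.Fminus[:] = rng.standard_normal(7) + 1j * rng.standard_normal(7)
    state.Z[:] = rng.standard_normal(7) + 1j * rng.standard_normal(7)
    before = (np.abs(state.Fplus) ** 2 + np.abs(state.Fminus) ** 2
              + 2 * np.abs(state.Z) ** 2)
    after_state = rf_rotation(state, flip, phase)
    after = (np.abs(after_state.Fplus) ** 2 + np.abs(after_state.Fminus) ** 2
             + 2 * np.abs(after_state.Z) ** 2)
    assert np.allclose(before, after, atol=1e-12)


def test_relaxation_identity_recovery_and_null_point():
    state = rf_rotation(equilibrium_state(WM, 4), 90.0, 0.0)
    assert np.allclose(relax_recover(state, 0.0, WM).Fplus, state.Fplus)

    recovered = relax_recover(state, 50 * WM.T1, WM)
    assert recovered.Z[0] == pytest.approx(WM.PD)
    assert recovered.transverse_magnitude() < 1e-15

    inverted = invert(equilibrium_state(WM, 4), eff=1.0)
    nulled = relax_recover(inverted, WM.T1 * np.log(2), WM)
    assert abs(nulled.Z[0]) < 1e-12

    with pytest.raises(ValueError):
        relax_recover(state, -1.0, WM)


def test_gradient_shift_definition_and_composition(rng):
    state = equilibrium_state(WM, 5)
    shifted = gradient_shift(state)
    assert shifted.transverse_magnitude() == 0.0  # no transverse to move

    state = rf_rotation(equilibrium_state(TissueParams("t", 1000, 100, 1.0), 5),
                        90.0, 0.0)
    a = state.Fplus[0]
    shifted = gradient_shift(state)
    assert shifted.Fplus[1] == pytest.approx(a)
    # F+(0) is fed from F-(1), empty here
    assert shifted.Fplus[0] == pytest.approx(np.conj(state.Fminus[1]))

    # operator composition: shifting twice equals two successive shifts
    state.Fplus[:] = rng.standard_normal(6) + 1j * rng.standard_normal(6)
    state.Fminus[:] = rng.standard_normal(6) + 1j * rng.standard_normal(6)
    state.Fminus[0] = np.conj(state.Fplus[0])
    once = gradient_shift(gradient_shift(state))
    twice = gradient_shift(gradient_shift(state.copy()))
    assert np.allclose(once.Fplus, twice.Fplus)
    assert np.allclose(once.Fminus, twice.Fminus)


def test_diffusion_b_factor_against_quadrature():
    """exp(-D int k(t)^2 dt) with linearly growing moment, by quadrature."""
    from scipy.integrate import quad

    spoil = SpoilingSchedule(dephasing_per_tr=1.0, voxel_size=0.65)
    tissue = TissueParams("t", 1000, 100, 1.0, D=0.8e-3)
    dt = 7.26
    kg = spoil.grad_wavenumber
    for k in (0, 1, 5):
        integral, _ = quad(lambda t, k=k: (kg * (k + t / (dt / 1000))) ** 2,
                           0, dt / 1000)
        expected = np.exp(-tissue.D * integral)
        ap, _, _ = diffusion_factors(k + 1, dt, tissue, spoil, shifting=True)
        assert ap[k] == pytest.approx(expected, rel=1e-10)


def test_diffusion_trivial_cases():
    spoil = SpoilingSchedule()
    no_diff = TissueParams("t", 1000, 100, 1.0, D=0.0)
    state = rf_rotation(equilibrium_state(no_diff, 4), 45.0, 0.0)
    out = diffusion_attenuate(state, 7.26, no_diff, spoil)
    assert np.allclose(out.Fplus, state.Fplus)

    csf = TissueParams("CSF", 3350, 1000, 1.0, D=3e-3)
    state = equilibrium_state(csf, 4)
    out = diffusion_attenuate(state, 100.0, csf, spoil)
    assert out.Z[0] == pytest.approx(1.0)  # b_L(0) = 0: never attenuated


def test_inversion():
    state = equilibrium_state(TissueParams("t", 1000, 100, 1.0), 4)
    assert invert(state, 1.0).Z[0] == pytest.approx(-1.0)
    assert invert(state, 0.96).Z[0] == pytest.approx(-0.96)
    assert invert(state, 0.0).Z[0] == 0.0
    tipped = rf_rotation(state, 45.0, 10.0)
    assert invert(tipped, 1.0).transverse_magnitude() == 0.0  # crusher


@pytest.mark.parametrize(
    "n,inc,expected",
    [(0, 50.0, 0.0), (3, 50.0, 300.0), (2, 117.0, 351.0)],
)
def test_quadratic_spoil_phase(n, inc, expected):
    assert rf_spoil_phase(n, inc) == pytest.approx(expected)
    assert rf_spoil_phases(n + 1, inc)[n] == pytest.approx(expected)


def test_epg_matches_bloch_ensemble_for_spoiled_train():
    """10-pulse RF-spoiled GRE train vs 720 dephased isochromats, < 1e-8."""
    tissue = TissueParams("t", 1000.0, 80.0, 1.0)
    n_pulses, flip, tr = 10, 15.0, 7.26
    state = equilibrium_state(tissue, n_pulses + 2)
    ens = IsochromatEnsemble(720)
    epg_signals, bloch_signals = [], []
    for n in range(n_pulses):
        phase = rf_spoil_phase(n, 50.0)
        state = rf_rotation(state, flip, phase)
        ens.rotate(flip, phase)
        epg_signals.append(state.Fplus[0])
        bloch_signals.append(ens.f_config(0))
        state = relax_recover(state, tr, tissue)
        state = gradient_shift(state)
        ens.relax(tr, tissue)
        ens.dephase()
    assert np.max(np.abs(np.array(epg_signals) - np.array(bloch_signals))) < 1e-8
    # final state: compare a few configuration orders too
    for k in range(4):
        assert state.Fplus[k] == pytest.approx(ens.f_config(k), abs=1e-8)
        assert state.Z[k] == pytest.approx(ens.z_config(k), abs=1e-8)


def test_tissue_params_validation():
    with pytest.raises(ValueError):
        TissueParams("x", -1, 50, 0.5)
    with pytest.raises(ValueError):
        TissueParams("x", 1000, 2000, 0.5)  # T2 > T1
    with pytest.raises(ValueError):
        TissueParams("x", 1000, 50, 0.0)
    with pytest.raises(ValueError):
        TissueParams("x", 1000, 50, 0.5, D=-1e-3)
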