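# Methods

## Scope and model

`mp2flaws` simulates the MP2RAGE pulse sequence — one adiabatic inversion
followed by two RF-spoiled gradient-echo (GRE) readout blocks per cycle —
and optimizes its timing and flip angles so that a single 7T scan yields
both a T1-weighted uniform image (UNI) and gray-matter-dominant fluid-and-
white-matter-suppressed (FLAWS) contrasts.  The magnetization is propagated
with the extended phase graph (EPG) formalism: configuration states
`F+(k)`, `F-(k)`, `Z(k)` indexed by integer dephasing order `k`, evolved by
the standard rotation, relaxation, gradient-shift and diffusion operators.
No assumption of complete transverse spoiling is made; RF spoiling is
modeled explicitly with a quadratic phase schedule (default increment 50°),
and diffusion attenuates stored configurations through the per-TR spoiler
gradient.

Per tissue the model needs T1, T2, relative proton density PD and an
apparent diffusion coefficient D.  The bundled adult 7T values are
WM 1220/45.9 ms, PD 0.69; GM 2132/55 ms, PD 0.82; CSF 3350/1000 ms, PD 1.
D is not part of the published tissue set; the defaults are standard adult
literature values (WM 0.70e-3, GM 0.80e-3, CSF 3.0e-3 mm²/s) and are
configurable.  Transmit-field (B1+) inhomogeneity is handled by scaling
the nominal flip angles over a grid of factors, default 0.5–1.4 in steps
of 0.1.

## Sequence timing

TI1 and TI2 are measured from the inversion pulse to the *excitation* of
the k-space-center line of each GRE block (echo shifts cancel in the ratio
images, so TE never enters signal formation).  With `n_exc` excitations
per block and center index `k_center` (from the partial-Fourier factor
under linear ordering: `round(n_inner * (pf - 1/2))`), the free delays are

    TA = TI1 - k_center * TR_GRE
    TB = TI2 - TI1 - n_exc * TR_GRE
    TC = TR_MP2RAGE - TI2 - (n_exc - k_center) * TR_GRE

and any negative delay marks the TI pair infeasible (the optimizer masks
such cells).  Scan duration is `TR_MP2RAGE` per acquired outer
phase-encode line, with partial Fourier, GRAPPA undersampling and
autocalibration lines accounted as
`ceil(n_outer * pf / R) + acs * (1 - 1/R)`; printed protocol durations are
reproduced to within two TR_MP2RAGE.

## Steady-state engine

One cycle is `invert -> TA -> block1(alpha1) -> TB -> block2(alpha2) ->
TC`.  Within a block, each TR applies the RF rotation (flip = nominal
angle × B1 scale, phase from the quadratic schedule), records the
demodulated `F+(0)` immediately after the center pulse, then relaxes,
attenuates by diffusion and shifts by one dephasing cycle.  Signals are
demodulated by the transmit phase (receiver tracks transmitter), with a
phase convention that makes the ideally spoiled signal the real, signed
quantity `sin(alpha) * Mz`.

Numerical choices:

- **Periodicity of the spoiling schedule.** The quadratic phase counter
  resets at each inversion.  A free-running counter is not periodic in the
  cycle and admits no strict steady state; the reset makes the cycle map
  well defined so the iteration can converge to 1e-9.
- **Steady state** is found by iterating whole cycles until the two
  recorded signals change by less than 1e-9 (relative), cap 50 cycles.
  The iteration is warm-started at the ideal-spoiling fixed point of Mz
  (an affine one-cycle map solved exactly), which shortens the transient
  without affecting the converged answer.
- **Truncation.** Orders are allocated up to `2*n_exc + 2` but the engine
  tracks the highest active order and trims wherever trailing amplitudes
  fall below 1e-10; with T2 and diffusion on, the active window stabilizes
  around order 20–40, which is what makes dense grids affordable.
- **Inversion** scales all `Z(k)` by `-eff` (efficiency default 1.0) and
  crushes transverse states — the adiabatic pulse is followed by a
  spoiler, and the long TC makes residual transverse negligible anyway.
- **Diffusion b-factors.** The spoiler is modeled as one full dephasing
  cycle per voxel (0.65 mm) per TR_GRE, accruing linearly across the TR:
  a transverse order moving k -> k+1 sees `b = kg² dt (k² + k + 1/3)` with
  `kg = 2π/voxel`; longitudinal and delay-interval states see the static
  `kg² dt k²`.  The actual spoiler moment of the product sequence is not
  public; one cycle/voxel is the conventional choice and is configurable.
- **Physics toggles** reproduce the effect-isolation experiments:
  disabling T2 crushes the transverse magnetization each TR (ideal
  spoiling), after which the RF-spoiling and diffusion toggles are
  provably inert; this limit coincides with the closed-form longitudinal
  recursion to 1e-9 and is tested as such.

The closed-form path (`closed_form_signal`) propagates only Mz through
inversion, exponential delays and the per-pulse `cos(alpha)·E1` recursion,
solving the periodic steady state as the fixed point of the affine cycle
map.  It serves as an independent oracle: the EPG engine must match it in
the T2->0 limit, and with full physics the UNI-relevant WM/GM signals stay
within 5% of it (the residual being the real transverse-coherence
oscillations).

## Noise model and CNR

Complex Gaussian noise (SD sigma per channel) is added to the complex
INV1/INV2 center-of-k-space signals; 100,000 repetitions by default.  The
CNR between two tissues for a combiner (UNI on complex signals, FLAWS_min
on magnitudes) is `mean(contrast_A - contrast_B) / SD(contrast_A -
contrast_B)`, sign preserved so a contrast reversal penalizes the
objective.  Per flip-angle pair, signed CNRs are averaged over the ten B1
scales.  The joint objective is

    CNR_total = (FLAWS_min CNR_GM-CSF + FLAWS_min CNR_GM-WM
                 + UNI CNR_WM-GM + UNI CNR_GM-CSF) / sqrt(TR_MP2RAGE)

in units of 1/sqrt(ms).

**Sigma calibration.** The target is an SNR of about 20 in the INV2 image,
held constant across everything sharing one TR_GRE.  The reference is the
WM INV2 magnitude at B1 = 1.0 under the TR 4000 ms initial protocol's
flip pair (5°/4°) for the TR_GRE = 7.26 ms family, and under the final
protocol's pair (4°/5°) for TR_GRE = 7.9 ms.  Neither the tissue nor the
flip pair behind the published "approximately 20" is stated, so absolute
CNRs carry this convention; CNR ratios between protocols do not depend on
it.  Monte-Carlo streams are spawned per flip-angle cell from a single
seed (default 20221109), making every result bit-reproducible.

## Optimization

The TI search evaluates every feasible (TI1, TI2) pair (TI1 from 600 ms in
200 ms steps, TI2 2000–3200 ms) at each TR in {4000, 4500, 5000} ms,
recording the maximum CNR_total over a flip-angle grid — coarse (α1 1–9°,
α2 1–17°, step 2°) for surveys, fine (both 1–10°, step 1°) for the
reported maxima.  The flip-angle selection then maximizes the FLAWS_min
total CNR subject to retaining at least 85% of the maximum total UNI CNR;
ties break toward smaller α2 then α1 (lower SAR).  The T1-sensitivity
analysis repeats the argmax over a 4×4 Cartesian grid of WM T1 in
[800, 1150] ms × GM T1 in [1550, 1900] ms (the published analysis states
only the count, 16, and the spans).

Two genuine sensitivities are worth knowing about.  First, the WM INV1
signal is near its null at TI1 = 650 ms (that is the FLAWS design point),
so FLAWS_min channels react strongly to anything that moves tiny signals —
a 4% change in inversion efficiency reorders near-tied plateau cells even
though UNI optimization is unaffected.  Second, the UNI GM–CSF channel
sits near its contrast reversal at the TR 4000 protocol (reversed below
α2 ≈ 3°) and is the quantity most sensitive to the CSF transverse/
diffusion conventions, since CSF (T2 = 1000 ms) is the one tissue whose
signal is strongly shaped by unspoiled coherences.

## Image path and phantom

UNI is `Re(S1* S2) / (|S1|² + |S2|²)`; FLAWS_min is `min(I1, I2) /
(I1 + I2)` on magnitudes; FLAWS_hc/hco are `(I1 - I2 - β)/(I1 + I2 + 2β)`
and its opposite, with β = 70 suppressing the noise-enhanced background to
-0.5 (the minimum projection of hc and hco equals `2·FLAWS_min - 1` at
β = 0, exactly).  Before FLAWS combination, volumes are rescaled so the
joint 99.9th percentile maps to a common range (default 4095); the
absolute scanner scale on which β = 70 was tuned is not reproducible, only
the functional form.  All-zero voxels return the background value rather
than erroring.  Image-domain CNR divides the mean tissue difference by the
*raw* median absolute deviation of the UNI WM signal (no 1.4826 factor —
the convention is unstated, and the choice scales all image CNRs by one
constant); contrast ratios are percentages of the mean UNI WM intensity.

The synthetic phantom is concentric geometry (WM core with a central CSF
pocket, GM shell, CSF rim, empty background) with a smooth cosine B1 ramp
spanning 0.5–1.4 that is quantized to the simulation's B1 levels.  Voxels
receive the EPG steady-state complex signal of their tissue at their local
B1, plus complex noise.  It exercises every image-path operation with
known ground truth, but it is not anatomy: no partial-volume voxels, no
receive-field bias, no motion or reconstruction artifacts — passing the
image-path tests says the operators are correct, not that in-vivo CNR
values are reproduced (the in-vivo rows of the published comparison are
out of scope by design).

## Problem sizes and defaults used in tests and the acceptance script

Simulation grids run at the study's conditions: 10 B1 scales × 100 fine
flip-angle pairs per tissue, 180 or 192 excitations per block, and 100,000
noise repetitions per Monte-Carlo cell (20,000 in a few auxiliary
invariance tests where only an argmax is needed).  Phantom tests use
16³–26³ voxel volumes, which already contain thousands of voxels per
tissue class.

## Known limitations

- Magnetization transfer, exchange, slice profiles, off-resonance and B0
  effects are out of scope; echo formation and k-space reconstruction
  (GRAPPA/partial-Fourier) are not simulated — their effect enters only
  through line counting in the duration estimate and the center index.
- The spoiler gradient moment and the diffusion coefficients are
  conventions (see above); absolute CNRs, most visibly the small UNI
  GM-CSF channel, inherit them.
- T1-map generation from UNI is deliberately not implemented.
- The sub-TR ordering of recording vs. relaxation within a repetition is
  a convention; it moves signals only in the fourth decimal.
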