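# Methods

## Model

The medium is described by a polarization equation of motion with two
fractional time derivatives,

    γα D^(α+1) P + γβ D^β P = ωp² E,

which for harmonic fields E ∝ e^(−iωt), ω > 0, gives the susceptibility

    χ(ω) = ωp² / ( γα (−iω)^(α+1) + γβ (−iω)^β ).

Assumptions: the medium is linear, spatially local and isotropic; only
ω > 0 is modelled (no electrostatics — a static field induces no bounded
polarization for the metallic orders); magnetic response and spatial
dispersion are absent.  The orders α and β are real; γα > 0 and γβ ≥ 0
carry the left-over fractional units so χ is dimensionless.  The
oscillator strength ωp² may be negative: that sign choice produces the
broad anomalous dispersion (∂ε′/∂ω < 0) characteristic of tissue spectra.
Permittivity adds a conduction channel, ε(ω) = ε∞ + χ(ω) + iσ/(ωε0).

Identifiability: χ depends on (ωp², γα, γβ) only through the two ratios
ωp²/γα and γβ/γα.  The medium type keeps all three fields (they are the
natural constants of the equation of motion), but any spectrum
determines them only up to a common factor — the fitting module
therefore pins the normalized γα to 1.

Conventions: e^(−iωt) (physics) is canonical internally, with the
principal branch (−iω)^x = ω^x e^(−iπx/2).  The familiar engineering
forms of the Debye, Cole–Cole and Havriliak–Negami references
(`+iωτ` denominators) are evaluated as written and conjugated to the
physics convention; a `UnitSystem` flag converts on input/output.  The
wave vector k = (ω/c)√ε takes the root with Im k ≥ 0 (decaying forward
wave).

## Discretization

The truncated Grunwald–Letnikov derivative on samples f(t − kΔt),

    D^ν f ≈ (1/Δt^ν) Σ_{k=0..N} w_k f(t − kΔt),
    w_0 = 1,  w_k = w_{k−1} (1 − (ν+1)/k),

is the computational primitive.  The multiplicative recurrence is exact
where the Γ-function form is defined and remains well-defined at integer
orders, where the Γ form hits poles; for integer ν the weights truncate
to the classical difference stencil.  Weight tables are computed once
per (order, N) and cached.  Only the left-sided, causal derivative is
used; histories shorter than N+1 samples are implicitly zero-padded (the
medium starts at rest, matching the solver's initialization).

The order-(α+1) operator is discretized as a first difference of
order-α sums and the order-β operator as a two-sample average of
order-β sums.  Collecting the coefficient of each P_{t−j} and dividing
by the coefficient of P_{t+1} yields the polarization recursion

    P_{t+1} = coef_P_t·P_t + coef_P_tm1·P_{t−1}
              + Σ_{j=2..N} c_j P_{t−j} + coef_E·Ē,

whose memory weights vanish identically beyond P_{t−1} at α = β = 1,
reducing the update exactly to the classic Drude ADE
P_{t+1} = [2P_t − (1−γΔt/2)P_{t−1} + ωp²Δt²Ē]/(1+γΔt/2).

Field coupling.  Two drive timings Ē are implemented:

* `trapezoidal` (default): Ē = (E^n + E^{n+1})/2, solved jointly with
  the E update (one scalar linear solve per cell).  This time-centred
  coupling is stable through the 1-D vacuum Courant limit Δt = 1 even
  though the Drude permittivity drops below one at high frequency, and
  its steady-state response carries a half-step phase lag between the P
  and E samples — the dominant, O(Δt) contribution to the measured
  susceptibility error.
* `explicit`: Ē = E^n, the literal form of the derivation.  Simpler,
  but von Neumann analysis and direct simulation show it loses
  stability slightly *below* Δt = 1 with this medium (growth factor
  ≈ 1.35/step at Δt = 1.0), because ε < 1 above the plasma frequency
  makes the phase velocity superluminal.

Both couplings are checked against independently coded classic-Drude
loops at α = β = 1.  The E update uses the polarization current
(P_{t+1} − P_t)/Δt; the H update is the standard Yee leapfrog.  Units
are normalized, c = Δx = ε0 = 1, so Δt equals the Courant number.

Boundaries are first-order Mur; with the default 2000-cell grid and a
probe near the source, residual reflections are negligible during the
measurement window (the measurement band lies in the evanescent region,
so little energy reaches the ends).  Sources are soft (additive): a
monochromatic sine with a raised-cosine ramp (default 10 periods) or a
Gaussian pulse for broadband sanity checks.  Divergence is detected,
not raised: max|E| > 10⁶ × source amplitude, checked every 100 steps —
an unambiguous signature of exponential blow-up at negligible cost.

## Susceptibility measurement and the error tables

One frequency point: drive at ω, discard the ramp plus 30 settle
periods, then project E and P at a probe 4 cells from the source onto
e^(−iωt) over 16 periods; χ_num = P̂/(ε0 Ê).  The probe sits in the near
field deliberately — in the measurement band the medium is opaque and
the local P/E ratio *is* the realized susceptibility (it satisfies the
polarization recursion identically, wherever the probe sits).

The band-mean error η averages |χ_num − χ_th|/|χ_th| (complex modulus;
a real-part-only metric is available) over 15 frequencies at the
midpoints of equal subintervals of (0.3 ωp, ωp), expressed in percent.
Unstable runs report η = ∞.  The error-table protocol uses the
normalized medium ωp = 0.3, γα = 1, γβ = 0.1 and N = 12 memory terms —
the memory depth of the reference implementation these tables describe;
the package-wide default is the more conservative N = 32.

Error anatomy, as measured by the package itself: the half-step P/E
sampling lag contributes ≈ (ω̄Δt/2)·100 % ≈ 10·Δt % over the band
(≈ 0.5 % at Δt = 0.05, ≈ 4.8 % at Δt = 0.5), growing linearly with the
time step; GL truncation adds a low-frequency bias that dominates for
strongly fractional orders at fixed N (e.g. α = 0.5 at N = 12); spatial
numerical dispersion is sub-percent at these resolutions.

Measured stability map (trapezoidal coupling, Δt = 0.5 unless noted):
stable for α in (0, ~1.35) at β = 1 — the scheme diverges for α ≳ 1.4
and at the integer endpoint α = 2; stable for β in [0, 1.2], divergent
for β in [1.3, 1.9], stable again at the integer point β = 2 (where the
weights truncate); at α = β = 1 stable through Δt = 1.0 and divergent
from Δt ≈ 1.05.  The α = 0 limit (a first-order equation) is A-stable
under the trapezoidal coupling; the explicit coupling is unstable
there.  The upper-α range is a known limitation: the wave-coupled
scheme, not the bare recursion, is what destabilizes it.

Near the stability edge (Δt = 1.0) the steady-state error is sharply
defined (η ≈ 9.6 % at α = β = 1) and robust to settle time, probe
position, window length and grid size; measurements relying on
broadband pulses or short windows can report substantially larger
values there because weakly damped band-edge modes contaminate the
spectra.  This protocol sensitivity is inherent to operating at the
margin and is why the package uses the monochromatic steady-state
protocol throughout.

## Synthetic tissue spectra and fitting

The generator emulates the *shape* of published whole-blood spectra
over 10⁷–10¹⁰ Hz: two Cole–Cole relaxation terms (a fast ~8 ps
water-like process, ε-amplitude 56, and a large slow ~130 ns dispersion,
amplitude 5200, both with broadening 0.1) plus a dc conductivity of
0.7 S/m, evaluated on a log-spaced grid with independent multiplicative
Gaussian noise on ε′ and the loss channel.  It is a synthetic stand-in:
it reproduces broad anomalous dispersion, realistic magnitudes and a
smooth two-process structure, but not instrument artefacts, correlated
errors, tissue heterogeneity or the additional relaxations outside the
band — so passing fits demonstrate estimator correctness on
well-specified data, not performance on real measurements.

Fitting is bounded nonlinear least squares (trust-region reflective) on
the concatenated *relative* residuals of ε′ and the loss channel —
relative, because the observables span decades over the band.  The loss
channel is total conductivity σ_dc + ε0·ω·Im χ or imaginary
permittivity, per the data flag.  Frequencies are normalized internally
by ω0 = 2π·(geometric mean of the band) so all free parameters are
O(1); bounds keep α in (0, 2) and β in [0, 1.3) — the scheme's stable
region — with ωp² signed.  Multi-start: seeded Latin-hypercube initial
points (default 8) plus, for the fractional fit, the standard-Drude
solution as an extra start, which makes the nested-model inequality
(fractional residual ≤ standard residual) hold by construction.
Non-convergence returns a flagged result, never an exception.

## Numerical choices and degenerate inputs

* Branch: (−iω)^x = ω^x e^(−iπx/2), continuous in x, matching integer
  powers; ω ≤ 0 rejected everywhere.
* The update denominator γα·w0/(ΔtΔt^α) + γβ·w0/(2Δt^β) is positive for
  every valid medium; a vanishing denominator raises a degenerate-medium
  error rather than producing NaNs.
* Vacuum cells never update P (their history stays exactly zero), so a
  vacuum grid reduces to textbook nondispersive FDTD.
* χ_th = 0 (vacuum reference) switches the relative error to absolute.
* Resolution guards warn below 10 time steps per period or 10 cells per
  analytic wavelength.
* CSV output uses 12 significant digits with `inf` literals, making
  identical configurations byte-reproducible.

## Known limitations

1-D only; no PML (first-order Mur suffices for the evanescent-band
protocol but reflects a few percent for obliquely-resolved broadband
runs); plain O(N) memory summation per cell (adequate at desk scale —
the 15-frequency error band at Δt = 0.05 runs in ~25 s on one CPU);
the upper-α stability ceiling noted above; fit uncertainties are not
quantified (point estimates only); the synthetic generator's caveats
above apply to every fitting result.
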