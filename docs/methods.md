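# Methods

## Model

`sdhrev` simulates the soluble SDHA/SDHB subcomplex of succinate
dehydrogenase running in the quinol–fumarate reductase (reverse) direction,
as probed in protein-film voltammetry: an electrode at potential E_out
exchanges single electrons with the [3Fe-4S] cluster, which relays them
through [4Fe-4S] and [2Fe-2S] to the covalent FAD of the flavoprotein
subunit, where fumarate is reduced to succinate. The network has 22 kinetic
processes:

* 1–3: Butler–Volmer electrode step and the two inter-cluster transfers;
* 4–16: the flavin-site diagram — fumarate binding to FAD, FADH• or FADH₂
  (4, 10, 12), six one-electron transfers from [2Fe-2S]⁻ to each bound or
  free flavin state (5, 6, 9, 11, 13, 15), hydride transfer/isomerization
  FADH₂·fum ⇌ FAD·suc (7), and succinate release from FAD·suc, FADH•·suc,
  FADH₂·suc (8, 14, 16);
* 17–20: ROS side reactions — H₂O₂ by FADH₂, superoxide by FADH₂, FADH• and
  [3Fe-4S]⁻;
* 21–22: Mn-SOD dismutation (Michaelis–Menten, V_max = 5.6·10⁴ µM/s,
  K_m = 50 µM) and first-order H₂O₂ efflux (k = 30 s⁻¹).

Thirteen species are integrated; the oxidized cluster forms and free FAD are
reconstructed from the four moiety conservations (pool totals 235 µM each),
so conservation holds exactly along any trajectory of the reduced system. A
redundant 17-species right-hand side exists solely to verify, by direct
integration, that the explicit stoichiometry conserves each moiety; it also
defines the semantics of the SBML export.

All units are µM, s, mV. Model assumptions worth keeping in mind: the
electrode is the only electron source (no quinone-pool kinetics), membrane
potential and proton-motive force are absent, O₂ and the dicarboxylates are
clamped, and pH enters only as a constant factor in the trimolecular rate
laws.

## Thermodynamic consistency

Equilibrium constants derive from midpoint potentials with a thermal voltage
RT/F fixed at **25 mV**. This convention is deliberate: it reproduces every
printed constant exactly (e^(60/25) = 11.023, e^(2·769/25) = 5.2·10²⁶,
e^(2·79/25) = 555.6), whereas the physical 25.69 mV does not. It is
configurable through `PhysicalConstants`.

The flavin diagram closes four thermodynamic cycles, so five constants are
always recomputed:

    Keq7  = 555.6/(Keq8·Keq12)          Keq6 = Keq11·Keq12/Keq10
    Keq5  = 1/(Keq4·Keq6·Keq7·Keq8)     Keq13 = Keq8·Keq9/Keq14
    Keq15 = 1/(Keq7·Keq12·Keq13·Keq16)

After `derive_dependent_keqs` (applied by every constructor) all four cycle
products equal 1 to ≤10⁻¹⁰ relative. The independent constants keep their
printed experimental values; these carry rounding of up to ~4% (most
visibly Keq9 = 0.006 vs the Nernst-exact 0.00622), so the *printed* set
closes the free-flavin loop only to ~4%. Consequences: (i) cycle-derived
Keq15 = 0.300 vs the printed 0.289; (ii) at the closed-form zero-current
potential a residual inter-pathway circulation of ~0.006 µM/s persists. The
test suite uses a Nernst-exact variant wherever strict equilibrium is
asserted; the default set matches what the published figures were computed
from (the caption-level Keq13 values 2.4·10⁻⁴…240 µM⁻¹ only follow from
Keq9 = 0.006).

Variant construction (`make_variant`) moves the binding/release pairs of
reactions 10, 12, 14, 16 (k and k⁻ separately), recomputes their Keq as
k/k⁻, and re-propagates the cycles — reproducing, e.g., Keq13 = 0.24 µM⁻¹
when k14 = k16 = 10⁻² s⁻¹ against the basal k⁻ = 0.04 µM⁻¹s⁻¹.

## Proton and oxygen conventions

The trimolecular electron-transfer laws contain H⁺ explicitly. The package
enters it as the **pH-7.4 hydrogen-ion concentration on the µM scale,
10^(−1.4) = 0.0398** (configurable via `ClampedEnvironment.Hplus`). The
choice is physically motivated — the iron–sulfur midpoint potentials are
quoted at pH 7.4 — and it is the value under which the simulated
tunnel-diode thresholds land on the experimentally observed potentials: the
slow-succinate-release variant peaks at −79 mV (observed ≈ −80 mV) and the
slow-fumarate-binding variant at −202 mV (reported ≈ −200 mV). Setting
H⁺ = 1 shifts every threshold ≈ +81 mV (= vT·ln(1/H)); the package leaves
that as a valid configuration for reference-activity analyses such as the
+37.4 mV zero-current potential.

Electrode sweeps of electron/succinate fluxes and the fumarate titrations
default to **anaerobic** conditions (O₂ = 0), the regime of the voltammetry
experiments they emulate; there V_rev_tot = V₁ = 2·V_suc_tot exactly. ROS
scans default to O₂ = 240 µM (air-saturated buffer). ROS magnitudes scale
nearly linearly with the clamped O₂; the curve shapes do not.

## Steady-state computation

Rate constants span >10 orders of magnitude (k7 = 2.78·10⁶ s⁻¹ vs
k14 = 10⁻³ s⁻¹ in the variants), so every solve treats the system as stiff:

1. **Integration route (default):** BDF integration from the fully oxidized
   state (all 13 dynamic species zero) over staged windows (t = 1, 10², 10⁴,
   10⁶ s; rtol 10⁻⁹, atol 10⁻¹²), with a damped-Newton polish
   (`scipy.optimize.root`, hybr, complex-step Jacobian) attempted after each
   window.
2. **Root-finding route (cross-check):** a deliberately loose, short burn-in
   (rtol 10⁻³, t ≤ 100 s) followed by pure Newton. `crosscheck` solves both
   routes independently and flags any species/flux disagreement beyond 10⁻⁴
   relative instead of hiding it — disagreement would be the signature of
   multistability or a stiffness failure.
3. **Extended-precision polish:** the acceptance tolerance
   (max|dy/dt| < 10⁻⁹·pool/s = 2.35·10⁻⁷ µM/s) lies *below* what any
   64/80-bit state can express near full pool reduction: the
   [3Fe-4S]⁻/[4Fe-4S] exchange has Jacobian entries ~10¹¹ s⁻¹ (k2/Keq2 with
   Keq2 = 2.78·10⁻⁶), and the representation spacing of a ~235 µM species
   times that sensitivity gives a residual floor ≈ 5·10⁻⁷ µM/s. The final
   Newton stage therefore iterates at 50 significant digits (mpmath) with
   the long-double Jacobian as iteration matrix. The reported
   `residual_norm` is evaluated at the high-precision solution (typically
   10⁻¹⁷–10⁻²⁴ µM/s); the stored state is its long-double rounding, which
   preserves every flux identity to better than 10⁻¹² relative.

Sweeps solve each grid point from the default initial condition — no
continuation — so hysteresis cannot be imported from the initial guess;
initial-condition independence is separately tested from random conserving
states (Dirichlet split of the flavin pool, fixed seed).

## Threshold definition

The experimental literature uses "threshold potential" loosely for the onset
of the current drop. The package operationalizes it as the **argmax** of the
chosen steady-state flux over the E_out grid, refined by a quadratic fit
through the three bracketing points, reported with the grid spacing as
uncertainty; a maximum on the grid boundary reports "none" (monotone curve).
The default grid is +100 → −400 mV at 2 mV.

## What reproduces, and what does not

Reproduced quantitatively: the Nernst/detailed-balance constant layer; the
zero-current potential closed form E_eq = (vT/2)·ln(fum·H²·(K₁K₂K₃)²/suc);
tunnel-diode thresholds of −79 mV (k14 = k16 = 10⁻² s⁻¹) and −202 mV
(k10 = k12 = 10⁻⁴ µM⁻¹s⁻¹); absence of a threshold for the off-rate scans;
the threshold ordering as k14 = k16 decreases; [3Fe-4S]⁻ near-saturation by
−60 mV with [2Fe-2S]⁻ lagging until ≈ −200 mV; specific H₂O₂ rates above
10³ pmol·min⁻¹·mg⁻¹ only for slow fumarate binding, with slow succinate
release an order of magnitude lower.

Known deviations (documented, not patched): (i) beyond the threshold the
residual succinate release flows through V16 = k16·[FADH₂·suc] (all exit
routes < 3% of the curve peak there), whereas the original figure text
attributes the tail to V8 or V14 depending on the scan — in this model the
fast [2Fe-2S]⁻→flavin transfer V15 (k15·[2Fe-2S]⁻·H ≈ 9·10³ s⁻¹ at full
reduction) always outcompetes direct release from FADH•·suc, and
stationarity then forces V16 = V15; (ii) the k14 = k16 = 1 s⁻¹ variant is
monotone out to −600 mV here (its plateau release ≈ 232 µM/s exceeds any
achievable V8 peak), rather than weakly nonmonotone; (iii) the steady-state
electron balance gives V_rev_tot = V₁ = V₂ = V₃ (single-electron chain),
not 2·V₁ — the package asserts the mass-balance identity.

## Synthetic data and the variant catalog

There is no external data; "data" are parameter configurations. The variant
catalog enumerates every simulated curve as one of four one-parameter scans
(fumarate on-rate, fumarate off-rate, succinate off-rate, succinate on-rate
around the dicarboxylate site), maps each (figure, panel, curve) to a
variant label, and regenerates the parameter files with detailed-balance
validation on write. The generator emulates parameter variation only — it
does not emulate measurement noise, enzyme heterogeneity, film loss, or
mass-transport limitation of real voltammetry, so passing tests demonstrate
properties of the kinetic scheme, not of electrode experiments.

## Problem sizes

Default test and acceptance runs use: 2 mV sweeps only where a threshold is
graded (a coarse 10–20 mV scan followed by a 2 mV window around the detected
maximum elsewhere); ROS scans at 25 mV; titrations over 10–26 logarithmic
fumarate points spanning ≥ 2 decades. Each steady-state solve takes
~0.1–0.5 s; full suites complete in a few minutes on one core.

## Limitations

Absolute ROS rates inherit the uncertainty of the clamped O₂ and of the
ROS rate constants taken from forward-direction calibrations; only their
ratios across variants are robust. The model cannot address quinone-pool
dynamics, membrane potential, pH gradients, or the forward
(succinate-oxidizing) catalytic cycle beyond the reversibility of reactions
1–16. The SBML export targets Level 3 Version 2 core with content MathML
and is validated by symbolic round-trip within this package, not against an
external SBML toolchain.
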