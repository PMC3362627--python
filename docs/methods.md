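# Methods

## Mean-field model of cooperative sodium-channel gating

Clustered ion channels can gate cooperatively: the opening of one channel
raises the open probability of its neighbors.  `coopna.gating` models a
population in which every channel is coupled to `K` neighbors, each open
neighbor shifting the channel's Boltzmann activation curve
`m∞(V) = 1/(1 + exp(−(V − V½)/k))` to the left by the coupling constant `J`
(mV).  In the mean-field limit the expected open-neighbor count is
`K·a·m^q`, where `a` is the available (non-inactivated) fraction and `m^q`
the open probability of an activated channel, so the activation variable
obeys

    τ_m dm/dt = m∞(V + μ a m^q) − m,        μ = K·J .

At `μ = 0` this is ordinary independent gating.  The steady states at
clamped `V` are fixed points of `F(m) = m∞(V + μ a m^q)`, a monotone
sigmoid self-map of [0, 1] with one to three fixed points.  Inverting the
fixed-point condition gives `V(m) = V½ + k·logit(m) − μ a m^q`; three
solutions exist over a window of voltages exactly when `V(m)` is
non-monotone.  For `q = 1` the fold condition `m(1−m) = k/(μa)` has real
roots iff `μa ≥ 4k`, giving the critical coupling `μ_c = 4k/a` in closed
form; for general `q` the package brackets the onset of three fixed points
by bisection in `μ`, confirming each candidate with a dense-scan
fixed-point solve (10⁴ grid points plus Brent refinement to |F(m)−m| <
1e−10).

Above `μ_c` the quasi-static *collective activation curve* `s(V) = a·m*(V)^q`
— obtained by continuing the steady state from each voltage step to the
next, as in a voltage-clamp protocol — develops a discontinuity at the
saddle-node voltage `V*` where the low-activation branch disappears.
`V*(μ, a)` is evaluated from the closed form for `q = 1` and from the fold
condition `μ a q m^q (1−m) = k` (smaller root) otherwise.  In the
strong-coupling limit `V* ≈ const − k·ln(μa)`, so the sensitivity of the
jump voltage to availability, `dV*/d(ln a)` (computed by central
differences in `ln a`, step 1e−4), saturates at `−k` independently of the
coupling strength: availability fluctuations move the firing threshold by
the same amount no matter how strong the coupling is.

Numerical choices: jump detection uses a 0.2 tolerance on adjacent open
fractions (far above the slope of any continuous sub-critical curve on a
0.1 mV grid) refined by bisection to 0.01 mV; the forward (ascending-V)
branch is the physiologically relevant one, the backward branch is provided
for hysteresis checks.  Defaults `V½ = −30 mV`, `k = 6 mV`, `q = 1`,
`τ_m = 0.1 ms` place the analysis in a generic physiological range; all are
configuration, not constants.

## The cooperative Wang-Buzsaki neuron

`coopna.neuron` embeds a fraction `p` of cooperative channels in the
Wang-Buzsaki (WB) interneuron model (C = 1 µF/cm², g_Na = 35, g_K = 9,
g_L = 0.1 mS/cm², E_Na = 55, E_K = −90, E_L = −65 mV, φ = 5, instantaneous
`m∞³h` sodium activation):

    C dV/dt = −g_Na[(1−p) m∞(V)³ h + p m_c^q h_c](V−E_Na)
              − g_K n⁴ (V−E_K) − g_L (V−E_L) + I(t)

`m_c` follows the mean-field kinetics above with the live inactivation
variable `h_c` as the availability entering the coupling shift.

**Cooperative gate defaults.**  The default cooperative gate is a steep
Boltzmann (`V½ = −48 mV`, `k = 4 mV`) with delayed activation (`q = 3`, as
in Hodgkin-Huxley-type sodium kinetics) and `τ_m = 0.05 ms`; the default
coupling is `K = 8` neighbors at `J = 24 mV`, i.e. `μ = 192 mV`, more than
ten times the critical coupling of this gate (`μ_c(q=3) = k(q+1)^{q+1}/q^{q+1}
≈ 12.6 mV` at `a = 1`).  Two constraints pin this choice.  First, the
collective jump voltage `V*` must lie *below* the activation range of the
non-cooperative sodium current (whose 10 mV/ms threshold is near −48 mV),
so that the cooperative fraction is the first conductance to gate on the
upstroke — this is what produces the rapid, cooperative AP onset and the
biphasic waveform, and it mirrors the low-threshold axonal sodium channels
that are the natural candidates for a cooperative fraction.  Second, the
resting state must survive: a first-order gate (`q = 1`) with a midpoint
low enough to satisfy the first constraint passes ~1 µA/cm² of persistent
current at rest and makes the model tonically active, whereas the cubed
gate suppresses the subthreshold open probability by orders of magnitude.
A first-order Boltzmann gate and a WB-derived activation curve
(`coop_curve="wb"`) remain selectable for sensitivity analyses.

**State-dependent inactivation.**  Sodium-channel inactivation proceeds
from the open state and is only weakly voltage dependent.  The cooperative
fraction therefore uses voltage-independent rates with an open-state
speed-up,

    dh_c/dt = α_hc (1 − h_c) − β_hc (1 + κ m_c^q) h_c ,

with defaults `α_hc = 0.1/ms` (recovery τ ≈ 10 ms), `β_hc = 0.03/ms`
(resting availability α/(α+β) ≈ 0.77) and `κ = 600`, giving an open-state
inactivation rate of ~18/ms.  The fast open-state collapse plays a dynamical
role beyond realism: after the all-or-none opening, the shifted activation
curve would otherwise hold the cooperative population locked open
(`m∞(V + μ h_c) ≈ 1` even at rest for strong coupling), ending in
depolarisation block; availability crashing to ≈ 0 during each AP releases
the latch.  The ~10 ms recovery lets `h_c` carry spiking history across
short interspike intervals, which makes the spike threshold — pinned to the
availability-dependent jump voltage `V*(a)` — variable under fluctuating
input.  A variant with WB voltage-dependent rates times the same
`(1 + κ m^q)` factor is selectable (`coop_inact="wb-voltage"`); it
equilibrates `h_c` to the local voltage, erasing that history.

**Integration.**  Fixed-step classical RK4 at `dt = 0.01 ms` (≤ τ_m/5 of
the cooperative gate), stimulus held piecewise-constant per step, gating
clipped to [0, 1] with clip events counted (zero in all shipped protocols).
The inner loops are numba-compiled with a plain-Python fallback;
correctness is pinned by an independently coded WB integrator (0.05 mV
sup-norm over 500 ms at p = 0) and by dt-halving convergence checks.  The
resting state is found as the lowest zero of the steady current balance
(scalar bisection with the gating variables at their low-branch steady
states, then a full 5-dimensional polish); models without a stable rest —
e.g. the 10× sodium-density control, which fires spontaneously — fall back
to a 500 ms settled on-attractor state.

## Action-potential phase-plane metrics

`coopna.ap` evaluates dV/dt along a trajectory from the model right-hand
side rather than by differencing the sampled voltage, so second-derivative
zero-crossing counts are free of differentiation noise (a finite-difference
mode exists for external traces and is cross-checked to <1% of the peak).
Definitions: *threshold* = voltage at the first upward crossing of
dV/dt = 10 mV/ms (criterion configurable, reported in all tables); *onset
rapidness* = least-squares slope of the phase plot over the arc with dV/dt
within criterion ± criterion/2; *waveform class* = sign-change count of
d²V/dt² between the threshold crossing and the voltage peak, ignoring
excursions below 1% of the window's peak |d²V/dt²| — 1 crossing is
monophasic, 3 biphasic (two acceleration phases: cooperative fraction
first, remaining channels second).  Since a valid upstroke starts
accelerating and ends decelerating the count must be odd; an even count
after noise-pruning is rounded up.  Sweeps over (p, μ) drive each cell with
a constant current at 1.2× its own rheobase and analyse the first spike
from rest, where the cooperative availability is at its resting value.

## Population encoding

`coopna.encoding` measures the population frequency-response function.
Each trial is an independent neuron receiving
`I(t) = I0 + I1 sin(2πft) + η(t)` with η an Ornstein-Uhlenbeck process
(exact one-step discretisation, stationary from the first sample).  `I0` is
calibrated by bisection — with noise seeds reused across candidate
currents, making the rate estimate monotone — to a target mean rate of
5 Hz.  The modulation `ν1(f)` and phase are the Fourier projection of the
pooled spike times at the stimulus frequency (the fundamental of the cycle
histogram, free of bin-width bias), over an integer number of cycles after
discarding a 200 ms transient; standard errors come from a 200-resample
bootstrap over trials.  The estimator is validated on inhomogeneous-Poisson
spike trains with known modulation (recovery within bootstrap error,
unbiased across replicates, below the Rayleigh null floor `2√(3ν0/T)` at
95% when `I1 = 0`).

Study conditions: `σ = 0.4 µA/cm²`, chosen to give ≈3.5 mV voltage SD at
rest (the 3–5 mV range typical of cortical background activity);
`τ_c = 20 ms` default with 60 ms as the robustness variant; `I1 = 0.2
µA/cm²` (half the noise SD, linear-response regime); trials of 10.2 s; the
highest tested frequency is 400 Hz.  At that frequency the plain WB
response is indistinguishable from the null floor while the cooperative
model (p = 0.1, μ = 192 mV) still responds at ~0.7 Hz per 0.2 µA/cm² —
the high-frequency advantage of a small strongly cooperative fraction.  A
tenfold increase of sodium density in the non-cooperative model raises the
peak dV/dt strongly but leaves the high-frequency response at the floor.

## What the synthetic fixtures do and do not show

Closed-form fixtures (logistic and double-logistic upstrokes, exponential
upstrokes with exactly linear phase plots, inhomogeneous-Poisson trains)
pin the analysis code to known answers; they emulate waveform geometry and
point-process statistics only.  Passing tests on them validates the
estimators, not the biophysics.  Conversely, all model-level results are
properties of this specific reconstruction — a single compartment, a
mean-field (infinite-cluster) description of cooperativity, frozen
temperature, current (not conductance) noise — and transfer to real
neurons only insofar as those idealisations do.

## Problem sizes

Shipped protocols are desk-scale by design: variability protocols use 25 s
of input per coupling value (≥100 spikes at 10 Hz); encoding comparisons
use 20 trials × 10.2 s per model and frequency.  These sizes give the
orderings reported here with margin; absolute gain values would need
longer runs and are not asserted anywhere in the package.

## Known limitations

- The mean-field limit ignores cluster-size fluctuations and channel noise;
  there is no stochastic single-channel mode.
- Inactivation of the cooperative fraction is a two-state availability with
  a single recovery time; real slow inactivation is multi-exponential.
- One compartment: no axon initial segment, no lateral currents, so the
  model cannot separate the cooperative and morphological explanations of
  biphasic somatic APs — it only shows the former is sufficient.
- The frequency response is measured at the fundamental only; harmonics and
  nonlinear mixing are out of scope.
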