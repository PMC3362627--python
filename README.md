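# coopna — cooperative sodium-channel gating and neuronal encoding

Biophysical models of spike generation almost always assume that
voltage-gated sodium channels open independently, coordinated only through
the membrane potential.  Clustered channels, however, can gate
*cooperatively*: one channel's opening raises its neighbors' open
probability.  `coopna` implements a model class for this situation, for
computational neuroscientists who want to ask what even a small cooperative
channel fraction does to action-potential (AP) onset dynamics, threshold
variability, and population coding.

The package has four layers:

- **`coopna.gating`** — mean-field kinetics of a coupled channel
  population.  Each channel sees its `K` neighbors through a shift of its
  Boltzmann activation curve by `J` mV per open neighbor:

  τ_m dm/dt = m∞(V + μ·a·m^q) − m, μ = K·J,

  with `a` the available (non-inactivated) fraction.  The module computes
  the fixed points of the steady-state map, the critical coupling
  μ_c (= 4k/a for q = 1) at which the collective activation curve
  s(V) = a·m*(V)^q becomes discontinuous, the jump voltage V\*, its
  sensitivity dV\*/d ln a → −k, and voltage-clamp style step responses.

- **`coopna.neuron`** — the cooperative Wang-Buzsaki (cWB) point neuron: a
  fraction `p` of the sodium conductance follows the cooperative kinetics
  (with live, state-dependent inactivation `h_c` as the availability), the
  rest is standard WB.  Deterministic fixed-step RK4, numba-accelerated,
  with spike detection, f–I curves and rheobase search.

- **`coopna.ap`** — phase-plane analytics: spike threshold (voltage at
  dV/dt = 10 mV/ms), onset rapidness (phase-plot slope at the criterion),
  peak dV/dt, monophasic/biphasic classification by the zero crossings of
  d²V/dt² during the upstroke, threshold variability under fluctuating
  input, and (p, μ) parameter sweeps.

- **`coopna.encoding`** — population frequency response: Ornstein-Uhlenbeck
  background noise, baseline calibration to a target rate, and the
  modulation amplitude ν1(f) of the population firing rate estimated by
  Fourier projection of pooled spike times, with bootstrap errors.

`coopna.fixtures` generates closed-form test waveforms and
inhomogeneous-Poisson spike trains; `coopna` also installs a CLI
(`coopna simulate | activation-curve | ap-metrics | sweep | freq-response |
fixtures`) that wraps these pipelines with JSON/YAML configs and
checkpointed sweeps.

## Worked example

```python
import numpy as np
import coopna
from coopna import ap

# 1. Channel level: the collective activation curve develops a jump
gate = coopna.CoopGateParams(v_half=-30, k=6, q=1, tau_m=0.1, K=1, J=48)
print("critical coupling:", coopna.critical_coupling(1.0, gate), "mV")
curve = coopna.collective_activation_curve(gate, 1.0, np.arange(-75, 5, 0.1))
print("discontinuous:", curve.discontinuous,
      " jump at", round(curve.v_threshold, 2), "mV")

# 2. Neuron level: one AP of the default cWB model (p = 0.1, K*J = 192 mV)
params = coopna.CWBParams()
rheo = coopna.rheobase(params)
traj = coopna.integrate(params, 1.1 * rheo, 400.0, dt=0.01)
spikes = coopna.detect_spikes(traj)
seg = ap.extract_spike_segments(traj, spikes[:1])[0]
m = ap.spike_metrics(seg)
print(f"threshold {m.threshold_v:.1f} mV, onset rapidness "
      f"{m.onset_rapidness:.1f}/ms, peak dV/dt {m.peak_vdot:.0f} mV/ms, "
      f"{m.waveform_class} ({m.zero_crossings} zero crossings)")
```

Output:

```
critical coupling: 24.0 mV
discontinuous: True  jump at -47.6 mV
threshold -53.3 mV, onset rapidness 13.2/ms, peak dV/dt 600 mV/ms, biphasic (3 zero crossings)
```

The channel-level jump at −47.6 mV is the all-or-none opening of the
coupled population (critical coupling 4k/a = 24 mV, here driven at twice
that).  At the neuron level, the small strongly coupled fraction fires
first: the AP threshold sits below the plain WB threshold, the onset is
about five times more rapid than in the uncoupled model (≈2.4/ms), and the
upstroke is biphasic — three zero crossings of d²V/dt², i.e. a fast
cooperative phase followed by the ordinary sodium upstroke, the waveform
commonly seen in cortical recordings.  The same model encodes 400 Hz input
modulations that the plain WB population cannot follow (see
`tests/test_acceptance.py` and `docs/methods.md`).

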