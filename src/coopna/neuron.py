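"""Single-compartment Wang-Buzsaki neuron with a fraction of cooperative Na+ channels.

The cooperative Wang-Buzsaki (cWB) model splits the sodium conductance into
a fraction ``p`` governed by the cooperative gate of
:mod:`coopna.gating` and a remainder with the standard instantaneous
``m_inf(V)**3 h`` kinetics.  The current balance is

    C dV/dt = -g_Na [ (1-p) m_inf(V)^3 h + p m_c^q h_c ] (V - E_Na)
              - g_K n^4 (V - E_K) - g_L (V - E_L) + I_ext

The cooperative activation variable ``m_c`` follows the mean-field kinetics
with the live inactivation variable ``h_c`` as the available fraction.
Sodium-channel inactivation is state- rather than voltage-dependent: open
channels proceed to the inactivated state fast at any voltage, while closed
channels inactivate slowly.  The default kinetics of ``h_c`` therefore use
voltage-independent base rates with an open-state speed-up,

    dh_c/dt = alpha_hc (1 - h_c) - beta_hc (1 + kappa m_c^q) h_c

so availability collapses within a fraction of a millisecond while the
cooperative population is open and recovers on a ~10 ms timescale.  The
recovery time lets ``h_c`` carry spiking history across short interspike
intervals, which is what makes the spike threshold (pinned to the
availability-dependent jump voltage) variable under fluctuating input.  A
voltage-rate variant (WB ``alpha_h/beta_h`` scaled by ``phi``, with the
same open-state factor) is selectable via ``coop_inact="wb-voltage"``.
Setting ``p = 0`` recovers the plain WB model exactly.

Integration is fixed-step classical Runge-Kutta (RK4) with the stimulus held
piecewise-constant per step; gating variables are clipped to [0, 1] after
each step and clip events counted (zero at the default step size).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import root

from . import _kernels
from .gating import CoopGateParams, steady_gate

__all__ = [
    "WBParams",
    "CWBParams",
    "NeuronState",
    "Trajectory",
    "IntegrationError",
    "rhs",
    "rest_state",
    "default_state0",
    "integrate",
    "detect_spikes",
    "fi_curve",
    "rheobase",
]

GATE_NAMES = ("h", "n", "m_c", "h_c")


@dataclass(frozen=True)
class WBParams:
    """Wang-Buzsaki membrane parameters (hippocampal interneuron model)."""

    c_m: float = 1.0      # µF/cm²
    g_na: float = 35.0    # mS/cm²
    g_k: float = 9.0
    g_l: float = 0.1
    e_na: float = 55.0    # mV
    e_k: float = -90.0
    e_l: float = -65.0
    phi: float = 5.0      # temperature factor on h, n (and h_c)

    def __post_init__(self) -> None:
        if min(self.g_na, self.g_k, self.g_l) < 0:
            raise ValueError("conductances must be >= 0")
        if not (self.e_k < self.e_l < self.e_na):
            raise ValueError("reversal potentials must satisfy e_k < e_l < e_na")
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")


@dataclass(frozen=True)
class CWBParams:
    """Cooperative WB model: membrane + cooperative-fraction parameters.

    Attributes
    ----------
    wb : WBParams
        Passive/active membrane parameters.
    p : float
        Fraction of the sodium conductance with cooperative gating, in [0, 1].
    coop : CoopGateParams
        Cooperative-gate parameters (Boltzmann curve, tau_m, coupling K*J).
    kappa : float
        Gain of the open-state-dependent speed-up of cooperative-fraction
        inactivation; 0 disables the state dependence.
    alpha_hc, beta_hc : float
        Recovery and base (closed-state) inactivation rates of the
        cooperative fraction (1/ms), used by the default "open-state"
        inactivation kinetics.  Ignored in "wb-voltage" mode.
    coop_inact : str
        "open-state" (default): constant base rates, inactivation driven by
        channel opening.  "wb-voltage": WB alpha_h/beta_h voltage rates
        scaled by phi, with the same (1 + kappa m^q) factor.
    q_noncoop : int
        Activation exponent of the non-cooperative fraction (WB default 3).
    coop_curve : str
        Steady-state curve of the cooperative gate: "boltzmann" (default) or
        "wb" (the WB model's own m_inf, shifted by the coupling term).
    """

    wb: WBParams = field(default_factory=WBParams)
    p: float = 0.1
    # Default cooperative gate: delayed activation (q = 3, as in HH-type
    # sodium kinetics) with a steep Boltzmann placed below the
    # non-cooperative activation range, mirroring the low-threshold
    # axonal channels proposed as the cooperative fraction.  The q = 3
    # exponent keeps the subthreshold cooperative current negligible so
    # the resting state survives across the whole (p, coupling) plane;
    # the steep low midpoint puts the collective all-or-none jump below
    # the ordinary spike threshold, so the cooperative fraction is the
    # first conductance to gate on the upstroke.  K*J = 192 mV is the
    # strong-coupling regime (many times the critical coupling).
    coop: CoopGateParams = field(
        default_factory=lambda: CoopGateParams(
            v_half=-48.0, k=4.0, q=3, tau_m=0.05, K=8, J=24.0
        )
    )
    kappa: float = 600.0
    alpha_hc: float = 0.1     # 1/ms: availability recovers with tau ~ 10 ms
    beta_hc: float = 0.03     # 1/ms: slow closed-state inactivation
    coop_inact: str = "open-state"
    q_noncoop: int = 3
    coop_curve: str = "boltzmann"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"cooperative fraction p must lie in [0, 1], got {self.p}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.alpha_hc <= 0 or self.beta_hc < 0:
            raise ValueError("alpha_hc must be > 0 and beta_hc >= 0")
        if self.coop_inact not in ("open-state", "wb-voltage"):
            raise ValueError(
                f"coop_inact must be 'open-state' or 'wb-voltage', got {self.coop_inact!r}")
        if self.coop_curve not in ("boltzmann", "wb"):
            raise ValueError(f"coop_curve must be 'boltzmann' or 'wb', got {self.coop_curve!r}")

    def replace(self, **kw) -> "CWBParams":
        return dataclasses.replace(self, **kw)


@dataclass
class NeuronState:
    """Instantaneous state (V, h, n, m_c, h_c)."""

    v: float
    h: float
    n: float
    m_c: float
    h_c: float

    def __post_init__(self) -> None:
        for name in GATE_NAMES:
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating variable {name} = {x} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.h, self.n, self.m_c, self.h_c])

    @classmethod
    def from_array(cls, y) -> "NeuronState":
        return cls(*[float(x) for x in y])


@dataclass
class Trajectory:
    """Uniformly sampled simulation output."""

    t: np.ndarray
    v: np.ndarray
    gates: dict            # name -> vector, keys GATE_NAMES
    i_input: np.ndarray
    meta: dict             # params, dt, seed, clip_events, ...

    def __post_init__(self) -> None:
        n = len(self.t)
        if any(len(x) != n for x in (self.v, self.i_input)) or any(
            len(g) != n for g in self.gates.values()
        ):
            raise ValueError("trajectory arrays must have equal length")

    @property
    def dt(self) -> float:
        return float(self.meta["dt_record"])

    @property
    def params(self) -> CWBParams:
        return self.meta["params"]

    def states(self) -> np.ndarray:
        """(n, 5) state array in kernel layout."""
        return np.column_stack(
            [self.v] + [self.gates[g] for g in GATE_NAMES]
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"t_ms": self.t, "v_mV": self.v}
        d.update({g: self.gates[g] for g in GATE_NAMES})
        d["i_uA_cm2"] = self.i_input
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, t: float, y: np.ndarray):
        self.t = t
        self.y = y
        super().__init__(f"non-finite state at t = {t:g} ms: {y}")


_COOP_KIND = {"boltzmann": 0.0, "wb": 1.0}
_INACT_KIND = {"open-state": 0.0, "wb-voltage": 1.0}


def pack_params(params: CWBParams) -> np.ndarray:
    """Flatten a CWBParams into the kernel parameter vector."""
    wb, c = params.wb, params.coop
    return np.array(
        [
            wb.c_m, wb.g_na, wb.g_k, wb.g_l, wb.e_na, wb.e_k, wb.e_l, wb.phi,
            params.p, float(params.q_noncoop),
            c.v_half, c.k, float(c.q), c.tau_m, c.mu,
            params.kappa, _COOP_KIND[params.coop_curve],
            params.alpha_hc, params.beta_hc, _INACT_KIND[params.coop_inact],
        ]
    )


# -- vectorised rate functions (numpy mirror of the scalar kernels) ----------

def _safe_exprel(scale, x):
    # scale*x / (1 - exp(-scale*x)) with the removable singularity at 0
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-7
    out[~small] = scale * x[~small] / -np.expm1(-scale * x[~small])
    out[small] = 1.0 + 0.5 * scale * x[small]
    return out


def alpha_m(v):
    return _safe_exprel(0.1, np.asarray(v, dtype=float) + 35.0)


def beta_m(v):
    return 4.0 * np.exp(-(np.asarray(v, dtype=float) + 60.0) / 18.0)


def alpha_h(v):
    return 0.07 * np.exp(-(np.asarray(v, dtype=float) + 58.0) / 20.0)


def beta_h(v):
    return 1.0 / (np.exp(-0.1 * (np.asarray(v, dtype=float) + 28.0)) + 1.0)


def alpha_n(v):
    return 0.1 * _safe_exprel(0.1, np.asarray(v, dtype=float) + 34.0)


def beta_n(v):
    return 0.125 * np.exp(-(np.asarray(v, dtype=float) + 44.0) / 80.0)


def m_inf_wb(v):
    am = alpha_m(v)
    return am / (am + beta_m(v))


def h_inf_wb(v):
    ah = alpha_h(v)
    return ah / (ah + beta_h(v))


def n_inf_wb(v):
    an = alpha_n(v)
    return an / (an + beta_n(v))


def _coop_minf(v, params: CWBParams):
    if params.coop_curve == "boltzmann":
        return steady_gate(v, params.coop)
    return m_inf_wb(v)


def rhs(state, i_ext, params: CWBParams):
    """Time derivative of the full state; vectorised over trailing axes.

    ``state`` may be a :class:`NeuronState`, a length-5 array, or an
    ``(n, 5)`` array of states (with ``i_ext`` scalar or length-n).
    Returns an array of the same shape as the state input.
    """
    if isinstance(state, NeuronState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    squeeze = y.ndim == 1
    y2 = np.atleast_2d(y)
    v, h, n, m_c, h_c = (y2[:, j] for j in range(5))
    wb = params.wb
    q_c = params.coop.q

    m_inf = m_inf_wb(v)
    mcq = m_c ** q_c
    i_na = wb.g_na * ((1.0 - params.p) * m_inf ** params.q_noncoop * h
                      + params.p * mcq * h_c) * (v - wb.e_na)
    i_k = wb.g_k * n ** 4 * (v - wb.e_k)
    i_l = wb.g_l * (v - wb.e_l)

    dy = np.empty_like(y2)
    dy[:, 0] = (-i_na - i_k - i_l + np.asarray(i_ext, dtype=float)) / wb.c_m
    ah, bh = alpha_h(v), beta_h(v)
    dy[:, 1] = wb.phi * (ah * (1.0 - h) - bh * h)
    dy[:, 2] = wb.phi * (alpha_n(v) * (1.0 - n) - beta_n(v) * n)
    shift = params.coop.mu * h_c * mcq
    dy[:, 3] = (_coop_minf(v + shift, params) - m_c) / params.coop.tau_m
    if params.coop_inact == "open-state":
        dy[:, 4] = (params.alpha_hc * (1.0 - h_c)
                    - params.beta_hc * (1.0 + params.kappa * mcq) * h_c)
    else:
        dy[:, 4] = wb.phi * (ah * (1.0 - h_c)
                             - bh * (1.0 + params.kappa * mcq) * h_c)
    return dy[0] if squeeze else dy


def _coop_gates_at(v: float, params: CWBParams) -> tuple[float, float]:
    """Steady (m_c, h_c) at clamped voltage, on the low-activation branch.

    Damped fixed-point iteration from the closed state; at subthreshold
    voltages this converges to the resting branch even above the critical
    coupling (where a high-activation branch coexists).
    """
    kappa, mu, q = params.kappa, params.coop.mu, params.coop.q
    if params.coop_inact == "open-state":
        ah, bh = params.alpha_hc, params.beta_hc
    else:
        ah, bh = float(alpha_h(v)), float(beta_h(v))
    m_c, h_c = 0.0, ah / (ah + bh)
    for _ in range(500):
        mcq = m_c ** q
        m_new = float(_coop_minf(v + mu * h_c * mcq, params))
        h_new = ah / (ah + bh * (1.0 + kappa * mcq))
        if abs(m_new - m_c) < 1e-14 and abs(h_new - h_c) < 1e-14:
            m_c, h_c = m_new, h_new
            break
        m_c = 0.5 * m_c + 0.5 * m_new
        h_c = 0.5 * h_c + 0.5 * h_new
    return m_c, h_c


def rest_state(params: CWBParams, v_lo: float = -80.0, v_hi: float = -45.0) -> NeuronState:
    """Resting fixed point of the full model at zero external current.

    Solves the steady current balance over V with all gating variables at
    their (low-branch) steady states, then polishes the full 5-dimensional
    root.  Raises if no rest point lies in [v_lo, v_hi].
    """

    def i_total(v: float) -> float:
        m_c, h_c = _coop_gates_at(v, params)
        y = np.array([v, float(h_inf_wb(v)), float(n_inf_wb(v)), m_c, h_c])
        return float(rhs(y, 0.0, params)[0])

    from scipy.optimize import brentq

    # lowest zero of the steady current balance = the resting point
    v_scan = np.arange(v_lo, v_hi + 0.25, 0.5)
    vals = np.array([i_total(v) for v in v_scan])
    sign_change = np.nonzero(vals[:-1] * vals[1:] <= 0)[0]
    if len(sign_change) == 0:
        raise RuntimeError(f"no resting state bracketed in [{v_lo}, {v_hi}] mV")
    i = sign_change[0]
    v0 = brentq(i_total, v_scan[i], v_scan[i + 1], xtol=1e-12)
    m_c, h_c = _coop_gates_at(v0, params)
    y0 = np.array([v0, float(h_inf_wb(v0)), float(n_inf_wb(v0)), m_c, h_c])
    sol = root(lambda y: rhs(y, 0.0, params), y0, method="hybr", tol=1e-13)
    y = sol.x if sol.success and np.max(np.abs(rhs(sol.x, 0.0, params))) < 1e-9 else y0
    y[1:] = np.clip(y[1:], 0.0, 1.0)
    return NeuronState.from_array(y)


def default_state0(params: CWBParams) -> NeuronState:
    """Initial state for simulations: the resting fixed point if one exists.

    Models without a stable rest (e.g. strongly elevated sodium density is
    spontaneously active) fall back to the state reached after settling for
    500 ms at zero external current, which lies on the free-running
    attractor.
    """
    try:
        return rest_state(params)
    except RuntimeError:
        v0 = params.wb.e_l
        m_c, h_c = _coop_gates_at(v0, params)
        y0 = NeuronState(v0, float(h_inf_wb(v0)), float(n_inf_wb(v0)), m_c, h_c)
        P = pack_params(params)
        n = int(round(500.0 / 0.01))
        out = np.empty((2, 5))
        _kernels.integrate_record(y0.as_array(), P, np.zeros(n), 0.01, n, out)
        y = out[1]
        y[1:] = np.clip(y[1:], 0.0, 1.0)
        return NeuronState.from_array(y)


def _stimulus_array(stimulus, n_steps: int, dt: float) -> np.ndarray:
    if np.isscalar(stimulus):
        return np.full(n_steps, float(stimulus))
    if callable(stimulus):
        t = np.arange(n_steps) * dt
        return np.asarray(stimulus(t), dtype=float) * np.ones(n_steps)
    arr = np.asarray(stimulus, dtype=float)
    if len(arr) < n_steps:
        raise ValueError(f"stimulus array has {len(arr)} samples, need {n_steps}")
    return np.ascontiguousarray(arr[:n_steps])


def integrate(
    params: CWBParams,
    stimulus,
    t_end: float,
    dt: float = 0.01,
    state0: NeuronState | str = "rest",
    seed: int | None = None,
    stride: int = 1,
) -> Trajectory:
    """Simulate the (c)WB neuron with fixed-step RK4.

    Parameters
    ----------
    stimulus : scalar, array, or callable t -> I
        External current density (µA/cm²), held piecewise-constant per
        integration step.  An array must supply one value per step.
    state0 : NeuronState or "rest"
        Initial state; "rest" solves for the zero-current fixed point.
    stride : int
        Record every ``stride``-th step (dt_record = stride * dt).
    seed : int, optional
        Recorded in the metadata for provenance (the integrator itself is
        deterministic; randomness lives in the stimulus).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > params.coop.tau_m / 5.0 and params.p > 0:
        raise ValueError(
            f"dt = {dt:g} ms too coarse for the cooperative gate "
            f"(need dt <= tau_m/5 = {params.coop.tau_m / 5:g} ms)")
    n_steps = int(round(t_end / dt))
    i_stim = _stimulus_array(stimulus, n_steps, dt)
    y0 = (default_state0(params) if isinstance(state0, str) else state0).as_array()
    P = pack_params(params)
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, 5))
    clips, bad = _kernels.integrate_record(y0, P, i_stim, dt, stride, out)
    if bad >= 0:
        raise IntegrationError((bad + 1) * dt, out[min(bad // stride, n_rec - 1)])
    t = np.arange(n_rec) * (dt * stride)
    i_rec = np.empty(n_rec)
    i_rec[0] = i_stim[0]
    i_rec[1:] = i_stim[stride - 1 :: stride][: n_rec - 1]
    gates = {g: out[:, j + 1] for j, g in enumerate(GATE_NAMES)}
    meta = {
        "params": params, "dt": dt, "dt_record": dt * stride, "seed": seed,
        "clip_events": int(clips), "t_end": t_end,
    }
    return Trajectory(t=t, v=out[:, 0], gates=gates, i_input=i_rec, meta=meta)


def run_spikes(
    params: CWBParams,
    stimulus,
    t_end: float,
    dt: float = 0.01,
    state0: NeuronState | str = "rest",
    v_cross: float = 0.0,
    refractory: float = 2.0,
) -> np.ndarray:
    """Simulate and return spike times only (memory-light, for long runs)."""
    n_steps = int(round(t_end / dt))
    i_stim = _stimulus_array(stimulus, n_steps, dt)
    y0 = (default_state0(params) if isinstance(state0, str) else state0).as_array()
    P = pack_params(params)
    buf = np.empty(max(64, int(t_end * 0.5)))  # generous: < 500 Hz
    n_spk, clips, bad, _y = _kernels.integrate_spikes(
        y0, P, i_stim, dt, v_cross, refractory, buf
    )
    if bad >= 0:
        raise IntegrationError((bad + 1) * dt, _y)
    return buf[:n_spk].copy()


def detect_spikes(
    traj: Trajectory, v_cross: float = 0.0, refractory: float = 2.0
) -> np.ndarray:
    """Upward crossing times of ``v_cross`` (linear interpolation), with a
    minimum separation of ``refractory`` ms."""
    v = traj.v
    up = np.nonzero((v[:-1] < v_cross) & (v[1:] >= v_cross))[0]
    if len(up) == 0:
        return np.array([])
    dt = traj.dt
    t_cross = traj.t[up] + dt * (v_cross - v[up]) / (v[up + 1] - v[up])
    keep = [0]
    for i in range(1, len(t_cross)):
        if t_cross[i] - t_cross[keep[-1]] >= refractory:
            keep.append(i)
    return t_cross[keep]


def fi_curve(
    params: CWBParams,
    i_grid,
    t_end: float = 2000.0,
    transient: float = 200.0,
    dt: float = 0.01,
) -> np.ndarray:
    """Steady-state firing rate (Hz) for each constant current in ``i_grid``."""
    i_grid = np.asarray(i_grid, dtype=float)
    if len(i_grid) > 1 and np.any(np.diff(i_grid) <= 0):
        raise ValueError("i_grid must be strictly increasing")
    rest = default_state0(params)
    rates = np.empty(len(i_grid))
    for j, i0 in enumerate(i_grid):
        spk = run_spikes(params, i0, t_end, dt=dt, state0=rest)
        rates[j] = 1000.0 * np.sum(spk >= transient) / (t_end - transient)
    return rates


def rheobase(
    params: CWBParams,
    i_lo: float = 0.0,
    i_hi: float = 5.0,
    t_end: float = 500.0,
    dt: float = 0.01,
    tol: float = 1e-3,
) -> float:
    """Smallest constant current that elicits sustained spiking, by bisection.

    "Sustained" means at least one spike after a 100 ms transient within
    ``t_end``; resolved to ``tol`` µA/cm².
    """
    rest = default_state0(params)

    def fires(i0: float) -> bool:
        spk = run_spikes(params, i0, t_end, dt=dt, state0=rest)
        return np.sum(spk >= 100.0) >= 1

    if fires(i_lo):
        raise ValueError(f"lower bracket {i_lo} already fires")
    hi = i_hi
    while not fires(hi):
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("failed to bracket rheobase")
    lo = i_lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
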