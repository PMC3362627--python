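"""Mean-field kinetics of a population of cooperatively gating sodium channels.

A channel is coupled to ``K`` neighbors; each open neighbor shifts the
channel's Boltzmann activation curve by the coupling constant ``J`` (mV).
In the mean-field limit the expected number of open neighbors is
``K * a * m**q`` (``a`` = fraction of channels available for activation), so
the activation variable obeys

    tau_m * dm/dt = m_inf(V + mu * a * m**q) - m,        mu = K * J

For ``mu = 0`` this reduces to the canonical case of independent channel
activation.  Above a critical effective coupling ``mu_c`` the steady-state
self-consistency condition ``m = m_inf(V + mu*a*m**q)`` acquires three
solutions over a window of voltages, and the collective activation curve
(the steady-state open fraction ``s(V) = a * m**q`` reached by a
voltage-step protocol) develops a discontinuity: activation of the coupled
population becomes an all-or-none event.

This module provides the fixed-point and bifurcation analysis of that map
(critical coupling, jump threshold voltage, its sensitivity to channel
availability) and direct voltage-clamp style simulation of the kinetics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CoopGateParams",
    "FixedPointSet",
    "ActivationCurveResult",
    "GateStepResponse",
    "steady_gate",
    "self_consistency_map",
    "fixed_points",
    "critical_coupling",
    "threshold_voltage",
    "threshold_sensitivity",
    "collective_activation_curve",
    "simulate_gate_step",
]


@dataclass(frozen=True)
class CoopGateParams:
    """Parameters of the cooperative activation gate.

    Attributes
    ----------
    v_half : float
        Boltzmann midpoint of the single-channel activation curve (mV).
    k : float
        Boltzmann slope factor (mV), > 0.
    q : int
        Activation exponent (open probability is ``m**q``), >= 1.
    tau_m : float
        Activation time constant (ms), > 0.
    K : int
        Number of coupled neighbor channels, >= 0.
    J : float
        Coupling constant (mV per open neighbor), >= 0.  ``J`` measures
        coupling strength as the shift along the activation curve that
        raises the open probability by as much as one open neighbor does.
    """

    v_half: float = -30.0
    k: float = 6.0
    q: int = 1
    tau_m: float = 0.1
    K: int = 8
    J: float = 12.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"slope factor k must be > 0, got {self.k}")
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be > 0, got {self.tau_m}")
        if self.q < 1 or int(self.q) != self.q:
            raise ValueError(f"activation exponent q must be an integer >= 1, got {self.q}")
        if self.K < 0 or int(self.K) != self.K:
            raise ValueError(f"neighbor count K must be an integer >= 0, got {self.K}")
        if self.J < 0:
            raise ValueError(f"coupling constant J must be >= 0, got {self.J}")

    @property
    def mu(self) -> float:
        """Effective coupling ``K * J`` (mV): total activation-curve shift
        when all neighbors are open and available."""
        return self.K * self.J

    def with_mu(self, mu: float) -> "CoopGateParams":
        """Copy with the effective coupling set to ``mu`` (K folded into J)."""
        if mu < 0:
            raise ValueError("mu must be >= 0")
        return dataclasses.replace(self, K=1, J=float(mu))


@dataclass(frozen=True)
class FixedPointSet:
    """Roots of the steady-state self-consistency condition at one voltage."""

    voltage: float
    roots: np.ndarray            # ascending, in [0, 1]
    stability: np.ndarray        # bool; stable iff map slope F'(m*) < 1

    def __post_init__(self) -> None:
        if not 1 <= len(self.roots) <= 3:
            raise ValueError(f"expected 1..3 fixed points, got {len(self.roots)}")

    @property
    def stable_roots(self) -> np.ndarray:
        return self.roots[self.stability]


@dataclass
class ActivationCurveResult:
    """Collective activation curve from a quasi-static voltage-step protocol."""

    v_grid: np.ndarray
    open_fraction: np.ndarray
    branch: str                          # "forward" (ascending V) or "backward"
    discontinuous: bool = False
    v_threshold: float | None = None
    jump_size: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voltage_mV": self.v_grid,
                "open_fraction": self.open_fraction,
                "branch": self.branch,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class GateStepResponse:
    """Open-fraction time courses for a family of voltage steps."""

    t: np.ndarray                # ms, from step onset
    v_steps: np.ndarray          # mV, one per trace
    open_fraction: np.ndarray    # shape (n_steps, n_t)
    v_hold: float
    s_hold: float

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for v, s in zip(self.v_steps, self.open_fraction):
            frames.append(
                pd.DataFrame(
                    {"time_ms": self.t, "open_fraction": s, "step_mV": v}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def steady_gate(v, params: CoopGateParams):
    """Single-channel Boltzmann steady-state activation ``m_inf(v)``.

    ``m_inf(v) = 1 / (1 + exp(-(v - v_half)/k))``; strictly increasing,
    bounded in (0, 1).  Accepts scalars or arrays.
    """
    x = (np.asarray(v, dtype=float) - params.v_half) / params.k
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if np.isscalar(v) or np.ndim(v) == 0:
        return float(out)
    return out


def self_consistency_map(m, v: float, a: float, params: CoopGateParams):
    """Steady-state map ``F(m) = m_inf(v + mu * a * m**q)``.

    Fixed points of ``F`` are the steady states of the coupled population at
    clamped voltage ``v`` with available fraction ``a``.  ``F`` is a
    non-decreasing continuous self-map of [0, 1], so at least one fixed
    point always exists.
    """
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("m must lie in [0, 1]")
    shift = params.mu * a * m ** params.q
    return steady_gate(v + shift, params)


def _map_slope(m, v: float, a: float, params: CoopGateParams):
    """Derivative dF/dm of the self-consistency map."""
    m = np.asarray(m, dtype=float)
    mu = params.mu
    q = params.q
    f = self_consistency_map(m, v, a, params)
    inner = mu * a * q * np.where(q > 1, m ** (q - 1), 1.0)
    return f * (1.0 - f) / params.k * inner


def fixed_points(
    v: float,
    a: float,
    params: CoopGateParams,
    n_scan: int = 10_000,
    tol: float = 1e-10,
) -> FixedPointSet:
    """All fixed points of the self-consistency map at voltage ``v``.

    Dense sign-change scan of ``F(m) - m`` over [0, 1] (``n_scan`` points)
    refined by bisection to ``|F(m) - m| < tol``.  A monotone sigmoid
    self-map has at most 3 fixed points, which alternate stable / unstable.
    """
    grid = np.linspace(0.0, 1.0, n_scan)
    g = self_consistency_map(grid, v, a, params) - grid
    roots: list[float] = []
    # endpoints can only be roots in degenerate limits; F maps into (0,1)
    sign = np.sign(g)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        lo, hi = grid[i], grid[i + 1]
        r = brentq(
            lambda m: self_consistency_map(m, v, a, params) - m,
            lo,
            hi,
            xtol=tol,
            rtol=8.9e-16,
        )
        roots.append(float(r))
    # exact zeros on the grid (rare; e.g. tangency landing on a grid point)
    for i in np.nonzero(g == 0.0)[0]:
        roots.append(float(grid[i]))
    roots_arr = np.array(sorted(set(np.round(roots, 12))))
    if len(roots_arr) == 0:  # numerically flat; fall back to iteration
        m = 0.5
        for _ in range(200):
            m = float(self_consistency_map(m, v, a, params))
        roots_arr = np.array([m])
    stability = _map_slope(roots_arr, v, a, params) < 1.0
    return FixedPointSet(voltage=float(v), roots=roots_arr, stability=stability)


def _inverse_voltage(m, a: float, mu: float, params: CoopGateParams):
    """Voltage at which ``m`` is a fixed point: V(m) = v_half + k*logit(m) - mu*a*m**q.

    Fixed points at clamped ``v`` are the solutions of ``V(m) = v``; three
    solutions exist for some ``v`` iff ``V`` is non-monotone on (0, 1).
    """
    m = np.asarray(m, dtype=float)
    return params.v_half + params.k * np.log(m / (1.0 - m)) - mu * a * m ** params.q


def _bistable(mu: float, a: float, params: CoopGateParams, n_scan: int = 4001) -> bool:
    """True if some clamped voltage admits three fixed points at coupling mu."""
    m = np.linspace(1e-6, 1.0 - 1e-6, n_scan)
    v_of_m = _inverse_voltage(m, a, mu, params)
    dv = np.diff(v_of_m)
    falling = np.nonzero(dv < 0)[0]
    if len(falling) == 0:
        return False
    # confirm with the fixed-point solver at a voltage inside the fold
    v_hi = v_of_m[: falling[0] + 1].max()
    v_lo = v_of_m[falling[-1] + 1 :].min()
    v_test = 0.5 * (v_lo + v_hi)
    return len(fixed_points(v_test, a, params.with_mu(mu)).roots) >= 3


def critical_coupling(
    a: float,
    params: CoopGateParams,
    method: str = "auto",
    rtol: float = 1e-5,
) -> float:
    """Smallest effective coupling ``mu_c`` at which bistability appears.

    At ``mu_c`` the self-consistency map becomes tangent to the identity
    (saddle-node of the steady state); above it the collective activation
    curve has a finite jump.  For the ``q = 1`` Boltzmann gate the tangency
    condition ``m(1-m) = k/(mu*a)`` has real solutions iff ``mu*a >= 4k``,
    giving the closed form ``mu_c = 4k/a``.

    Parameters
    ----------
    method : {"auto", "analytic", "numeric"}
        "analytic" uses the closed form (q = 1 only); "numeric" brackets the
        onset of three fixed points by bisection in mu; "auto" picks the
        closed form when available.
    """
    if a <= 0:
        raise ValueError("available fraction a must be > 0: with a = 0 no channels "
                         "can activate and coupling has no effect")
    if method not in ("auto", "analytic", "numeric"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("auto", "analytic") and params.q == 1:
        return 4.0 * params.k / a
    if method == "analytic":
        raise ValueError("closed form only available for q = 1")
    # numeric: bisection on mu for the onset of three fixed points
    lo, hi = 0.0, 8.0 * params.k / a
    while not _bistable(hi, a, params):
        hi *= 2.0
        if hi > 1e6 * params.k:
            raise RuntimeError("failed to bracket the critical coupling")
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if _bistable(mid, a, params):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _saddle_node_m(mu: float, a: float, params: CoopGateParams) -> float:
    """Lower saddle-node point m_sn of the fold (smaller root of V'(m) = 0)."""
    k, q = params.k, params.q
    if q == 1:
        disc = 1.0 - 4.0 * k / (mu * a)
        if disc < 0:
            raise ValueError(
                "no discontinuity below critical coupling: mu*a = "
                f"{mu * a:g} < 4k = {4 * k:g}"
            )
        return 0.5 * (1.0 - np.sqrt(disc))
    # V'(m) = k/(m(1-m)) - mu*a*q*m**(q-1); zero where h(m) = mu*a*q*m**q*(1-m) - k = 0
    def h(m):
        return mu * a * q * m ** q * (1.0 - m) - k

    m_peak = q / (q + 1.0)  # maximum of m**q (1-m)
    if h(m_peak) < 0:
        raise ValueError("no discontinuity below critical coupling for this (mu, a)")
    return brentq(h, 1e-12, m_peak, xtol=1e-14)


def threshold_voltage(mu: float, a: float, params: CoopGateParams) -> float:
    """Voltage ``V*`` where the lower stable branch disappears (jump location).

    This is the saddle-node at which the low-activation fixed point merges
    with the unstable middle fixed point; on the forward (ascending-voltage)
    protocol the open fraction jumps to the upper branch at ``V*``.  Defined
    only above the critical coupling.
    """
    m_sn = _saddle_node_m(mu, a, params)
    return float(_inverse_voltage(m_sn, a, mu, params))


def threshold_sensitivity(
    mu: float, a: float, params: CoopGateParams, step: float = 1e-4
) -> float:
    """Sensitivity ``dV*/d(ln a)`` of the jump voltage to channel availability.

    Central finite difference in ``ln a``.  In the strong-coupling limit
    ``mu*a >> k`` the jump voltage behaves as ``V* ~ const - k*ln(mu*a)``,
    so the sensitivity approaches ``-k`` independently of the coupling
    strength: availability-driven threshold variability saturates and is no
    longer shaped by ``mu``.
    """
    a_hi = a * np.exp(step)
    a_lo = a * np.exp(-step)
    return (threshold_voltage(mu, a_hi, params) - threshold_voltage(mu, a_lo, params)) / (
        2.0 * step
    )


def _relax_to_fixed_point(v: float, a: float, params: CoopGateParams, m0: float) -> float:
    """Stable fixed point reached by the gradient-like flow dm/dt ∝ F(m) - m from m0.

    In one dimension the flow is monotone in time, so it converges to the
    nearest fixed point in the direction of ``sign(F(m0) - m0)``.
    """
    fps = fixed_points(v, a, params)
    roots = fps.roots
    g0 = float(self_consistency_map(m0, v, a, params)) - m0
    if abs(g0) < 1e-12:
        return m0
    if g0 > 0:
        above = roots[roots >= m0 - 1e-12]
        return float(above[0]) if len(above) else float(roots[-1])
    below = roots[roots <= m0 + 1e-12]
    return float(below[-1]) if len(below) else float(roots[0])


def collective_activation_curve(
    params: CoopGateParams,
    a: float,
    v_grid: np.ndarray,
    direction: str = "forward",
    jump_tol: float = 0.2,
    v_refine: float = 0.01,
) -> ActivationCurveResult:
    """Quasi-static collective activation curve ``s(V) = a * m*(V)**q``.

    Emulates a voltage-step protocol: for each grid voltage (ascending for
    the forward branch, descending for backward) the steady state is the
    fixed point reached from the previous grid point's steady state.  Above
    the critical coupling the forward branch jumps discontinuously at the
    saddle-node voltage; the jump is detected where adjacent open fractions
    differ by more than ``jump_tol`` and its location refined by bisection
    in voltage to ``v_refine`` mV.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.ndim != 1 or len(v_grid) < 2 or np.any(np.diff(v_grid) <= 0):
        raise ValueError("v_grid must be a strictly increasing 1-D array")
    if not 0 < a <= 1:
        raise ValueError("available fraction a must lie in (0, 1]")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")

    order = np.arange(len(v_grid)) if direction == "forward" else np.arange(len(v_grid))[::-1]
    m_vals = np.empty(len(v_grid))
    m_prev = float(steady_gate(v_grid[order[0]], params))  # decoupled initial guess
    for j in order:
        m_prev = _relax_to_fixed_point(v_grid[j], a, params, m_prev)
        m_vals[j] = m_prev
    s = a * m_vals ** params.q

    result = ActivationCurveResult(v_grid=v_grid, open_fraction=s, branch=direction)
    jumps = np.nonzero(np.abs(np.diff(s)) > jump_tol)[0]
    if len(jumps) > 0:
        i = jumps[0] if direction == "forward" else jumps[-1]
        lo, hi = v_grid[i], v_grid[i + 1]
        m_lo, m_hi = m_vals[i], m_vals[i + 1]
        if direction == "forward":
            m_carry = m_lo
            while hi - lo > v_refine:
                mid = 0.5 * (lo + hi)
                m_mid = _relax_to_fixed_point(mid, a, params, m_carry)
                if abs(a * m_mid ** params.q - a * m_carry ** params.q) > jump_tol:
                    hi = mid
                else:
                    lo, m_carry = mid, m_mid
            s_lo, s_hi = a * m_carry ** params.q, a * m_hi ** params.q
        else:
            m_carry = m_hi
            while hi - lo > v_refine:
                mid = 0.5 * (lo + hi)
                m_mid = _relax_to_fixed_point(mid, a, params, m_carry)
                if abs(a * m_mid ** params.q - a * m_carry ** params.q) > jump_tol:
                    lo = mid
                else:
                    hi, m_carry = mid, m_mid
            s_lo, s_hi = a * m_lo ** params.q, a * m_carry ** params.q
        result.discontinuous = True
        result.v_threshold = 0.5 * (lo + hi)
        result.jump_size = float(abs(s_hi - s_lo))
    return result


def simulate_gate_step(
    v_hold: float,
    v_steps,
    a: float,
    params: CoopGateParams,
    dt: float = 0.005,
    t_step: float = 2.0,
) -> GateStepResponse:
    """Open-fraction time courses for voltage steps from a common holding level.

    Integrates ``tau_m * dm/dt = m_inf(v + mu*a*m**q) - m`` (RK4) from the
    steady state at ``v_hold`` for each step voltage, all steps applied from
    the same holding steady state so the available fraction stays fixed at
    ``a``.  Returns ``s(t) = a * m(t)**q`` per step.
    """
    if dt > params.tau_m / 10.0:
        raise ValueError(f"dt = {dt:g} ms too coarse; need dt <= tau_m/10 = "
                         f"{params.tau_m / 10:g} ms")
    v_steps = np.atleast_1d(np.asarray(v_steps, dtype=float))
    m0 = _relax_to_fixed_point(v_hold, a, params, float(steady_gate(v_hold, params)))
    n_t = int(round(t_step / dt)) + 1
    t = np.arange(n_t) * dt
    m = np.full(len(v_steps), m0)
    out = np.empty((len(v_steps), n_t))
    out[:, 0] = a * m ** params.q
    mu, q, tau = params.mu, params.q, params.tau_m

    def deriv(m_arr, v_arr):
        return (steady_gate(v_arr + mu * a * m_arr ** q, params) - m_arr) / tau

    for i in range(1, n_t):
        k1 = deriv(m, v_steps)
        k2 = deriv(m + 0.5 * dt * k1, v_steps)
        k3 = deriv(m + 0.5 * dt * k2, v_steps)
        k4 = deriv(m + dt * k3, v_steps)
        m = np.clip(m + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, 1.0)
        out[:, i] = a * m ** q
    return GateStepResponse(
        t=t, v_steps=v_steps, open_fraction=out, v_hold=float(v_hold),
        s_hold=float(a * m0 ** q),
    )
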