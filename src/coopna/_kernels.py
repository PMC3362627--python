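"""Fixed-step RK4 integration kernels for the (cooperative) Wang-Buzsaki neuron.

The heavy inner loops live here so they can be JIT-compiled with numba; if
numba is unavailable the same functions run as plain Python (slow but
identical numerics).  Parameters are packed into a flat float64 vector so
the kernels stay nopython-compatible; see :func:`coopna.neuron.pack_params`.

State layout: ``y = (V, h, n, m_c, h_c)``
Parameter layout (indices):
  0 c_m   1 g_na  2 g_k   3 g_l   4 e_na  5 e_k   6 e_l   7 phi
  8 p     9 q_noncoop     10 v_half  11 k_slope  12 q_coop  13 tau_m
  14 mu   15 kappa        16 coop_kind (0 = Boltzmann, 1 = WB-derived m_inf)
  17 alpha_hc  18 beta_hc 19 inact_kind (0 = open-state rates, 1 = WB voltage rates)
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


NPAR = 20


@njit(cache=True)
def _alpha_m(v):
    x = -0.1 * (v + 35.0)
    if abs(x) < 1e-7:
        return 1.0  # limit of 0.1*(v+35)/(1-exp(-0.1(v+35)))
    return 0.1 * (v + 35.0) / (1.0 - math.exp(x))


@njit(cache=True)
def _beta_m(v):
    return 4.0 * math.exp(-(v + 60.0) / 18.0)


@njit(cache=True)
def _alpha_h(v):
    return 0.07 * math.exp(-(v + 58.0) / 20.0)


@njit(cache=True)
def _beta_h(v):
    return 1.0 / (math.exp(-0.1 * (v + 28.0)) + 1.0)


@njit(cache=True)
def _alpha_n(v):
    x = -0.1 * (v + 34.0)
    if abs(x) < 1e-7:
        return 0.1
    return 0.01 * (v + 34.0) / (1.0 - math.exp(x))


@njit(cache=True)
def _beta_n(v):
    return 0.125 * math.exp(-(v + 44.0) / 80.0)


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


@njit(cache=True)
def _coop_minf(v, P):
    if P[16] == 0.0:  # Boltzmann
        return _sigmoid((v - P[10]) / P[11])
    am = _alpha_m(v)
    return am / (am + _beta_m(v))


@njit(cache=True)
def _rhs(y, i_ext, P, dy):
    v, h, n, m_c, h_c = y[0], y[1], y[2], y[3], y[4]
    phi = P[7]
    p = P[8]
    qn = P[9]
    q_c = P[12]

    am = _alpha_m(v)
    m_inf = am / (am + _beta_m(v))
    ah = _alpha_h(v)
    bh = _beta_h(v)
    an = _alpha_n(v)
    bn = _beta_n(v)

    mcq = m_c ** q_c
    i_na = P[1] * ((1.0 - p) * m_inf ** qn * h + p * mcq * h_c) * (v - P[4])
    i_k = P[2] * n ** 4 * (v - P[5])
    i_l = P[3] * (v - P[6])

    dy[0] = (-i_na - i_k - i_l + i_ext) / P[0]
    dy[1] = phi * (ah * (1.0 - h) - bh * h)
    dy[2] = phi * (an * (1.0 - n) - bn * n)
    # cooperative activation: availability a = h_c enters the coupling shift
    shift = P[14] * h_c * mcq
    dy[3] = (_coop_minf(v + shift, P) - m_c) / P[13]
    # open-state dependent inactivation of the cooperative fraction
    if P[19] == 0.0:
        dy[4] = P[17] * (1.0 - h_c) - P[18] * (1.0 + P[15] * mcq) * h_c
    else:
        dy[4] = phi * (ah * (1.0 - h_c) - bh * (1.0 + P[15] * mcq) * h_c)


@njit(cache=True)
def _rk4_step(y, i_ext, P, dt, k1, k2, k3, k4, tmp):
    _rhs(y, i_ext, P, k1)
    for j in range(5):
        tmp[j] = y[j] + 0.5 * dt * k1[j]
    _rhs(tmp, i_ext, P, k2)
    for j in range(5):
        tmp[j] = y[j] + 0.5 * dt * k2[j]
    _rhs(tmp, i_ext, P, k3)
    for j in range(5):
        tmp[j] = y[j] + dt * k3[j]
    _rhs(tmp, i_ext, P, k4)
    clips = 0
    for j in range(5):
        y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if j > 0:
            if y[j] < 0.0:
                y[j] = 0.0
                clips += 1
            elif y[j] > 1.0:
                y[j] = 1.0
                clips += 1
    return clips


@njit(cache=True)
def integrate_record(y0, P, i_stim, dt, stride, out):
    """RK4 integration recording every ``stride``-th state into ``out``.

    ``out`` must have shape ``(n_steps // stride + 1, 5)``.  The stimulus is
    held piecewise-constant over each step.  Returns ``(clip_events,
    bad_step)`` where ``bad_step`` is -1 on success or the index of the
    first non-finite step.
    """
    n = i_stim.shape[0]
    y = y0.copy()
    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    tmp = np.empty(5)
    out[0, :] = y
    clips = 0
    row = 1
    for i in range(n):
        clips += _rk4_step(y, i_stim[i], P, dt, k1, k2, k3, k4, tmp)
        if not math.isfinite(y[0]):
            return clips, i
        if (i + 1) % stride == 0:
            out[row, :] = y
            row += 1
    return clips, -1


@njit(cache=True)
def integrate_spikes(y0, P, i_stim, dt, v_cross, refractory, spike_buf):
    """RK4 integration recording only spike times (upward threshold crossings).

    Crossing times are linearly interpolated between step endpoints and
    separated by at least ``refractory`` ms.  Returns ``(n_spikes,
    clip_events, bad_step, y_final)``.
    """
    n = i_stim.shape[0]
    y = y0.copy()
    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    tmp = np.empty(5)
    clips = 0
    n_spk = 0
    last_spike = -1e18
    v_prev = y[0]
    for i in range(n):
        clips += _rk4_step(y, i_stim[i], P, dt, k1, k2, k3, k4, tmp)
        if not math.isfinite(y[0]):
            return n_spk, clips, i, y
        v_new = y[0]
        if v_prev < v_cross and v_new >= v_cross:
            t_spk = i * dt + dt * (v_cross - v_prev) / (v_new - v_prev)
            if t_spk - last_spike >= refractory and n_spk < spike_buf.shape[0]:
                spike_buf[n_spk] = t_spk
                n_spk += 1
                last_spike = t_spk
        v_prev = v_new
    return n_spk, clips, -1, y
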