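"""Synthetic test fixtures with known analytic structure.

These generators provide the oracle surface for the analysis code: upstroke
waveforms whose phase-plane geometry is known in closed form (logistic and
double-logistic voltage rises, exponential upstrokes with an exactly linear
phase plot) and inhomogeneous-Poisson spike trains with a stated rate
modulation.  All are parameterised and seedable; none is derived from
simulation output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ap import SpikeSegment

__all__ = [
    "logistic_upstroke",
    "double_logistic_upstroke",
    "linear_phase_segment",
    "inhomogeneous_poisson",
    "make_fixtures",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def logistic_upstroke(
    v0: float = -70.0,
    amp: float = 100.0,
    t_mid: float = 2.0,
    width: float = 0.3,
    dt: float = 0.001,
    t_end: float = 4.0,
) -> SpikeSegment:
    """Single logistic voltage rise: one acceleration phase (monophasic).

    ``v(t) = v0 + amp * sigma((t - t_mid)/width)`` with the analytic
    derivative attached; d²V/dt² changes sign exactly once, at ``t_mid``.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    s = _sigmoid((t - t_mid) / width)
    v = v0 + amp * s
    vdot = amp / width * s * (1.0 - s)
    return SpikeSegment(t=t, v=v, vdot=vdot, peak_index=len(t) - 1)


def double_logistic_upstroke(
    v0: float = -70.0,
    amp1: float = 25.0,
    t_mid1: float = 1.5,
    width1: float = 0.08,
    amp2: float = 80.0,
    t_mid2: float = 2.6,
    width2: float = 0.35,
    dt: float = 0.001,
    t_end: float = 4.5,
) -> SpikeSegment:
    """Two time-shifted logistic rises: two acceleration phases (biphasic).

    With well-separated midpoints the second derivative runs + - + -,
    i.e. three sign changes between threshold and peak — the waveform of an
    AP whose fast cooperative fraction opens before the main conductance.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    s1 = _sigmoid((t - t_mid1) / width1)
    s2 = _sigmoid((t - t_mid2) / width2)
    v = v0 + amp1 * s1 + amp2 * s2
    vdot = amp1 / width1 * s1 * (1.0 - s1) + amp2 / width2 * s2 * (1.0 - s2)
    return SpikeSegment(t=t, v=v, vdot=vdot, peak_index=len(t) - 1)


def linear_phase_segment(
    slope: float = 30.0,
    v_init_offset: float = 0.05,
    v0: float = -60.0,
    v_stop: float = 0.0,
    dt: float = 0.001,
) -> SpikeSegment:
    """Exponential upstroke ``dV/dt = slope * (V - v0)``: exactly linear phase plot.

    The threshold at criterion ``c`` is ``v0 + c/slope`` and the phase-plot
    slope is ``slope`` at every criterion — closed-form oracles for the
    threshold and onset-rapidness estimators.
    """
    if slope <= 0 or v_init_offset <= 0:
        raise ValueError("slope and v_init_offset must be > 0")
    t_end = np.log((v_stop - v0) / v_init_offset) / slope
    t = np.arange(0.0, t_end, dt)
    v = v0 + v_init_offset * np.exp(slope * t)
    vdot = slope * (v - v0)
    return SpikeSegment(t=t, v=v, vdot=vdot, peak_index=len(t) - 1)


def inhomogeneous_poisson(
    nu0: float,
    nu1: float,
    f: float,
    t_end: float,
    seed,
    phase: float = 0.0,
) -> np.ndarray:
    """Spike times (ms) of a Poisson process with rate ``nu0 + nu1 sin(2 pi f t + phase)``.

    Generated by thinning a homogeneous process at ``nu0 + nu1``; rates in
    Hz, times in ms.  Requires ``nu1 <= nu0`` so the rate stays nonnegative.
    """
    if nu1 > nu0:
        raise ValueError("need nu1 <= nu0 for a nonnegative rate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = (nu0 + nu1) * 1e-3  # spikes per ms
    n_bound = rng.poisson(lam * t_end)
    t = np.sort(rng.uniform(0.0, t_end, n_bound))
    rate = nu0 + nu1 * np.sin(2e-3 * np.pi * f * t + phase)
    keep = rng.uniform(0.0, nu0 + nu1, n_bound) < rate
    return t[keep]


def make_fixtures(kind: str, params: dict | None, seed: int, out_dir) -> list[Path]:
    """Write a named fixture family to CSV files; returns the paths written."""
    params = dict(params or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    def _write_segment(seg: SpikeSegment, name: str) -> None:
        df = pd.DataFrame({"t_ms": seg.t, "v_mV": seg.v, "vdot_mV_per_ms": seg.vdot})
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths.append(path)

    if kind == "logistic":
        _write_segment(logistic_upstroke(**params), "logistic_upstroke")
    elif kind == "double_logistic":
        _write_segment(double_logistic_upstroke(**params), "double_logistic_upstroke")
    elif kind == "linear_phase":
        _write_segment(linear_phase_segment(**params), "linear_phase_segment")
    elif kind == "poisson":
        defaults = {"nu0": 5.0, "nu1": 2.0, "f": 10.0, "t_end": 100_000.0}
        defaults.update(params)
        spikes = inhomogeneous_poisson(seed=seed, **defaults)
        path = out_dir / "poisson_spikes.csv"
        pd.DataFrame({"t_ms": spikes}).to_csv(path, index=False)
        paths.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return paths
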