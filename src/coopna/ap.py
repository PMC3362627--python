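"""Phase-plane analysis of simulated action potentials.

Quantities follow the standard experimental definitions: the *threshold* of
a spike is the voltage at which dV/dt first crosses a fixed criterion
(default 10 mV/ms) on the upstroke; *onset rapidness* is the slope of the
phase plot (dV/dt against V) at that crossing; the *waveform class* is read
from the sign changes of the second time-derivative of V between the
threshold crossing and the voltage peak — one acceleration phase (1 zero
crossing) marks a monophasic AP, two acceleration phases (3 zero crossings)
a biphasic one, the signature of a cooperative channel fraction opening
ahead of the main sodium conductance.

dV/dt is evaluated from the model right-hand side along the stored states
rather than by numerical differentiation of the sampled voltage, which
keeps the second-derivative zero-crossing count free of differentiation
noise.  A finite-difference fallback is available for traces that were not
produced by the simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neuron import CWBParams, Trajectory, detect_spikes, integrate, rheobase, rhs

__all__ = [
    "SpikeSegment",
    "APMetrics",
    "extract_spike_segments",
    "ap_threshold",
    "onset_rapidness",
    "classify_waveform",
    "spike_metrics",
    "threshold_variability",
    "sweep_pJ",
]

log = logging.getLogger(__name__)

DEFAULT_CRITERION = 10.0  # mV/ms


@dataclass
class SpikeSegment:
    """One action potential: time, voltage and model-derived dV/dt."""

    t: np.ndarray
    v: np.ndarray
    vdot: np.ndarray          # mV/ms, from the model RHS (or analytic, for fixtures)
    peak_index: int = field(default=-1)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.vdot)):
            raise ValueError("segment arrays must have equal length")
        if self.peak_index < 0:
            self.peak_index = int(np.argmax(self.v))

    @property
    def peak_vdot(self) -> float:
        return float(np.max(self.vdot[: self.peak_index + 1]))


@dataclass
class APMetrics:
    """Per-spike scalar metrics."""

    threshold_v: float        # mV
    onset_rapidness: float    # 1/ms
    peak_vdot: float          # mV/ms
    waveform_class: str       # "monophasic" | "biphasic"
    zero_crossings: int


def extract_spike_segments(
    traj: Trajectory,
    spikes,
    pre_ms: float = 3.0,
    post_ms: float = 3.0,
    params: CWBParams | None = None,
) -> list[SpikeSegment]:
    """Cut one window per spike and attach RHS-derived dV/dt.

    Windows that would run past the trajectory edges are skipped with a log
    entry.  ``params`` defaults to the parameters stored in the trajectory
    metadata.
    """
    params = params or traj.params
    dt = traj.dt
    states = traj.states()
    vdot_all = rhs(states, traj.i_input, params)[:, 0]
    segments: list[SpikeSegment] = []
    n = len(traj.t)
    for ts in np.atleast_1d(np.asarray(spikes, dtype=float)):
        i0 = int(round((ts - pre_ms - traj.t[0]) / dt))
        i1 = int(round((ts + post_ms - traj.t[0]) / dt)) + 1
        if i0 < 0 or i1 > n:
            log.warning("spike at %.3f ms: window exceeds trajectory, skipped", ts)
            continue
        sl = slice(i0, i1)
        segments.append(SpikeSegment(t=traj.t[sl], v=traj.v[sl], vdot=vdot_all[sl]))
    return segments


def _upstroke_crossing(seg: SpikeSegment, criterion: float) -> tuple[int, float]:
    """Index i and interpolation weight w of the first upward vdot crossing."""
    vd = seg.vdot[: seg.peak_index + 1]
    if criterion >= seg.peak_vdot:
        raise ValueError(
            f"criterion {criterion:g} mV/ms not reached (peak dV/dt = "
            f"{seg.peak_vdot:g} mV/ms)")
    idx = np.nonzero((vd[:-1] < criterion) & (vd[1:] >= criterion))[0]
    if len(idx) == 0:
        raise ValueError(f"dV/dt never crosses criterion {criterion:g} mV/ms upward")
    i = int(idx[0])
    w = (criterion - vd[i]) / (vd[i + 1] - vd[i])
    return i, float(w)


def ap_threshold(seg: SpikeSegment, criterion_vdot: float = DEFAULT_CRITERION) -> float:
    """Voltage at the first upward crossing of dV/dt = criterion (linear interp.)."""
    i, w = _upstroke_crossing(seg, criterion_vdot)
    return float(seg.v[i] + w * (seg.v[i + 1] - seg.v[i]))


def onset_rapidness(
    seg: SpikeSegment,
    criterion_vdot: float = DEFAULT_CRITERION,
    fit_halfwidth: float | None = None,
) -> float:
    """Phase-plot slope d(vdot)/dV at the criterion crossing (1/ms).

    Least-squares line over the contiguous phase-plot arc around the
    crossing with ``vdot`` within ``criterion ± fit_halfwidth`` (default
    halfwidth = criterion/2).
    """
    if fit_halfwidth is None:
        fit_halfwidth = criterion_vdot / 2.0
    ic, _ = _upstroke_crossing(seg, criterion_vdot)
    lo_v, hi_v = criterion_vdot - fit_halfwidth, criterion_vdot + fit_halfwidth
    i0 = ic
    while i0 > 0 and seg.vdot[i0 - 1] >= lo_v and seg.vdot[i0 - 1] <= seg.vdot[i0]:
        i0 -= 1
    i1 = ic + 1
    last = seg.peak_index
    while i1 < last and seg.vdot[i1 + 1] <= hi_v and seg.vdot[i1 + 1] >= seg.vdot[i1]:
        i1 += 1
    v = seg.v[i0 : i1 + 1]
    vd = seg.vdot[i0 : i1 + 1]
    if len(v) < 5:
        raise ValueError(
            f"only {len(v)} samples in the phase-plot fit window; "
            "use a smaller integration step or a wider fit window")
    slope = np.polyfit(v, vd, 1)[0]
    return float(slope)


def _lobes(a: np.ndarray, tol: float) -> list[int]:
    """Signs of successive excursions of ``a``, ignoring lobes below ``tol``.

    A lobe is a maximal run of one sign; lobes whose peak magnitude is below
    the noise tolerance are discarded, and adjacent surviving lobes of equal
    sign merge.
    """
    signs = np.sign(a)
    lobes: list[tuple[int, float]] = []  # (sign, peak |a|)
    cur_sign = 0
    cur_peak = 0.0
    for s, mag in zip(signs, np.abs(a)):
        if s == 0:
            continue
        if s == cur_sign:
            cur_peak = max(cur_peak, mag)
        else:
            if cur_sign != 0:
                lobes.append((cur_sign, cur_peak))
            cur_sign, cur_peak = int(s), mag
    if cur_sign != 0:
        lobes.append((cur_sign, cur_peak))
    merged: list[list] = []
    for s, peak in lobes:
        if peak < tol:
            continue
        if merged and merged[-1][0] == s:
            merged[-1][1] = max(merged[-1][1], peak)
        else:
            merged.append([s, peak])
    return [s for s, _ in merged]


def classify_waveform(
    seg: SpikeSegment,
    criterion_vdot: float = DEFAULT_CRITERION,
    excursion_tol: float | None = None,
) -> tuple[str, int]:
    """Mono- vs biphasic classification from second-derivative zero crossings.

    Counts sign changes of d²V/dt² (the time derivative of the RHS-based
    dV/dt) between the threshold crossing and the voltage peak.  Excursions
    whose peak magnitude is below ``excursion_tol`` (default 1% of the
    maximum |d²V/dt²| in the window) are treated as noise.  One crossing
    marks a monophasic upstroke, three (or more, odd) a biphasic one.
    """
    ic, _ = _upstroke_crossing(seg, criterion_vdot)
    i_peak = seg.peak_index
    if i_peak - ic < 3:
        raise ValueError("upstroke window too short to classify")
    accel = np.gradient(seg.vdot[ic : i_peak + 1], seg.t[ic : i_peak + 1])
    if excursion_tol is None:
        excursion_tol = 0.01 * np.max(np.abs(accel))
    signs = _lobes(accel, excursion_tol)
    crossings = max(len(signs) - 1, 0)
    if crossings % 2 == 0:
        # upstroke starts accelerating and ends decelerating; an even count
        # means a boundary lobe fell below tolerance
        crossings += 1
    return ("biphasic" if crossings >= 3 else "monophasic", crossings)


def spike_metrics(
    seg: SpikeSegment,
    criterion_vdot: float = DEFAULT_CRITERION,
    fit_halfwidth: float | None = None,
) -> APMetrics:
    """All scalar metrics for one spike segment."""
    cls, nz = classify_waveform(seg, criterion_vdot)
    return APMetrics(
        threshold_v=ap_threshold(seg, criterion_vdot),
        onset_rapidness=onset_rapidness(seg, criterion_vdot, fit_halfwidth),
        peak_vdot=seg.peak_vdot,
        waveform_class=cls,
        zero_crossings=nz,
    )


def metrics_table(segments, criterion_vdot: float = DEFAULT_CRITERION) -> pd.DataFrame:
    rows = []
    for j, seg in enumerate(segments):
        m = spike_metrics(seg, criterion_vdot)
        rows.append(
            {
                "spike": j,
                "threshold_mV": m.threshold_v,
                "onset_rapidness_per_ms": m.onset_rapidness,
                "peak_dvdt_mV_per_ms": m.peak_vdot,
                "waveform": m.waveform_class,
                "zero_crossings": m.zero_crossings,
                "criterion_mV_per_ms": criterion_vdot,
            }
        )
    return pd.DataFrame(rows)


def threshold_variability(
    traj: Trajectory,
    criterion_vdot: float = DEFAULT_CRITERION,
    min_spikes: int = 50,
    pre_ms: float = 3.0,
    post_ms: float = 3.0,
) -> tuple[float, int]:
    """Standard deviation of per-spike thresholds under fluctuating input.

    Returns ``(sd_threshold_mV, n_spikes)``; raises if fewer than
    ``min_spikes`` usable spikes are found.
    """
    spikes = detect_spikes(traj)
    segs = extract_spike_segments(traj, spikes, pre_ms=pre_ms, post_ms=post_ms)
    thresholds = []
    for seg in segs:
        try:
            thresholds.append(ap_threshold(seg, criterion_vdot))
        except ValueError:
            continue
    if len(thresholds) < min_spikes:
        raise ValueError(
            f"only {len(thresholds)} spikes with a threshold crossing "
            f"(need >= {min_spikes})")
    return float(np.std(thresholds, ddof=1)), len(thresholds)


def _cell_metrics(
    params: CWBParams,
    i_factor: float,
    t_end: float,
    dt: float,
    criterion_vdot: float,
) -> dict:
    """Standardised step-current protocol for one (p, mu) cell."""
    i_rheo = rheobase(params, dt=dt)
    i_step = i_factor * i_rheo
    traj = integrate(params, i_step, t_end, dt=dt)
    spikes = detect_spikes(traj)
    if len(spikes) == 0:
        raise RuntimeError("no spike in the step protocol")
    # first spike from rest: cooperative availability at its resting value
    segs = extract_spike_segments(traj, spikes[:1], params=params)
    m = spike_metrics(segs[0], criterion_vdot)
    return {
        "i_step_uA_cm2": i_step,
        "threshold_mV": m.threshold_v,
        "onset_rapidness_per_ms": m.onset_rapidness,
        "peak_dvdt_mV_per_ms": m.peak_vdot,
        "waveform": m.waveform_class,
        "zero_crossings": m.zero_crossings,
    }


def sweep_pJ(
    base: CWBParams,
    p_grid,
    mu_grid,
    i_factor: float = 1.2,
    t_end: float = 300.0,
    dt: float = 0.01,
    criterion_vdot: float = DEFAULT_CRITERION,
    cell_hook=None,
) -> pd.DataFrame:
    """Step-current AP metrics over a (p, mu) grid.

    Each cell uses a constant current at ``i_factor`` times its own rheobase
    and reports the metrics of a steady-state spike.  Failed cells are
    logged and returned with NaN metrics.  ``cell_hook(p, mu, row)`` is
    called after each cell (used for checkpointing).
    """
    p_grid = np.atleast_1d(np.asarray(p_grid, dtype=float))
    mu_grid = np.atleast_1d(np.asarray(mu_grid, dtype=float))
    if len(p_grid) == 0 or len(mu_grid) == 0:
        raise ValueError("p_grid and mu_grid must be non-empty")
    rows = []
    for p in p_grid:
        for mu in mu_grid:
            params = base.replace(p=float(p), coop=base.coop.with_mu(float(mu)))
            row = {"p": float(p), "mu_mV": float(mu),
                   "criterion_mV_per_ms": criterion_vdot}
            try:
                row.update(_cell_metrics(params, i_factor, t_end, dt, criterion_vdot))
            except Exception as exc:  # noqa: BLE001 - cell marked missing
                log.warning("sweep cell p=%g mu=%g failed: %s", p, mu, exc)
                row.update(
                    {k: np.nan for k in (
                        "i_step_uA_cm2", "threshold_mV", "onset_rapidness_per_ms",
                        "peak_dvdt_mV_per_ms")}
                )
                row["waveform"] = "missing"
                row["zero_crossings"] = -1
            rows.append(row)
            if cell_hook is not None:
                cell_hook(float(p), float(mu), row)
    return pd.DataFrame(rows)
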