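"""Patch-clamp sweep metrics: peak currents, densities, I–V curves, APD80.

Sweeps enter as tidy CSV tables (sweep_id, time_ms, command_mV,
current_pA) with the cell's membrane capacitance supplied separately.
Current densities are peak (or steady-state) currents divided by
capacitance, pA/pF, making cells of different size comparable.  The fast
and slow inward components recorded in one prestep/step protocol are
separated by a configurable time split after step onset (default 10 ms):
the fast sodium-like transient peaks within a few ms, the L-type
calcium-like component tens of ms later.  APD80 runs from the point of
maximal upstroke velocity to the 80%-repolarization crossing, linearly
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .synth import StepProtocol


@dataclass
class SweepSet:
    """A set of voltage-clamp sweeps plus per-cell capacitance."""

    data: pd.DataFrame           # sweep_id, time_ms, command_mV, current_pA
    cm_pF: float
    protocol: StepProtocol | None = None

    def __post_init__(self):
        if not self.cm_pF > 0:
            raise ValueError("cm_pF must be > 0")
        required = {"sweep_id", "time_ms", "command_mV", "current_pA"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"sweep table needs columns {sorted(required)}")
        ivals = []
        for _, grp in self.data.groupby("sweep_id"):
            t = grp["time_ms"].to_numpy()
            ivals.append(float(np.median(np.diff(np.sort(t)))))
        if ivals and (max(ivals) - min(ivals)) > 1e-9:
            raise ValueError("all sweeps must share one sample interval")
        self._sample_interval = ivals[0] if ivals else float("nan")

    @property
    def sample_interval(self) -> float:
        return self._sample_interval

    def sweep(self, sweep_id) -> pd.DataFrame:
        grp = self.data[self.data["sweep_id"] == sweep_id]
        if grp.empty:
            raise ValueError(f"no sweep {sweep_id!r}")
        return grp.sort_values("time_ms")

    @property
    def sweep_ids(self) -> list:
        return sorted(self.data["sweep_id"].unique().tolist())


@dataclass(frozen=True)
class IVPoint:
    voltage_mV: float
    current_pA: float
    current_density_pA_pF: float


@dataclass
class ApMetrics:
    resting_potential_mV: float
    peak_mV: float
    apd80_ms: float
    has_ap: bool = True

    @property
    def amplitude_mV(self) -> float:
        return self.peak_mV - self.resting_potential_mV

    def to_dict(self) -> dict:
        return asdict(self)


def _step_bounds(sweep: pd.DataFrame) -> tuple[int, int, float]:
    """Index of step onset/offset and the step level, from the command trace.

    The test step is the last segment whose command differs from the one
    before it (holding → [prestep] → step [→ post])."""
    cmd = sweep["command_mV"].to_numpy()
    changes = np.nonzero(np.diff(cmd) != 0)[0] + 1
    if len(changes) == 0:
        raise ValueError("no voltage step found in command trace")
    # segments between change points; the longest non-initial segment whose
    # level differs from its predecessor is the test step
    seg_starts = np.r_[0, changes]
    seg_ends = np.r_[changes, len(cmd)]
    # test step: the segment holding the sweep's extreme-duration step is
    # protocol-dependent; take the segment following the last level change
    # before any return to holding.  Robust simple rule: the segment with
    # the maximal |level − holding| among non-initial segments, first wins.
    holding = cmd[0]
    best = None
    for s, e in zip(seg_starts[1:], seg_ends[1:]):
        level = cmd[s]
        if level == holding and best is not None:
            continue
        score = (e - s)  # prefer the long test step over the short prestep
        if best is None or score > best[0]:
            best = (score, s, e, level)
    _, s, e, level = best
    return int(s), int(e), float(level)


def _smooth(x: np.ndarray, w: int = 7) -> np.ndarray:
    """Savitzky-Golay (order 2): suppresses noise without flattening the
    brief fast-inward peak the way a boxcar would."""
    from scipy.signal import savgol_filter

    if w <= 2 or len(x) < w:
        return x
    return savgol_filter(x, w, 2)


def peak_inward(sweeps: SweepSet, sweep_id=None, split_time_ms: float = 10.0,
                baseline_ms: float = 50.0, smooth_samples: int = 5
                ) -> tuple[float, float]:
    """Fast and slow inward peak currents (pA, baseline-subtracted).

    ``fast`` is the most negative current within ``split_time_ms`` after
    step onset; ``slow`` the most negative current after the split, within
    the step.  Baseline is the mean holding current over the
    ``baseline_ms`` immediately preceding step onset.
    """
    if sweep_id is None:
        sweep_id = sweeps.sweep_ids[0]
    sw = sweeps.sweep(sweep_id)
    s, e, _ = _step_bounds(sw)
    if (e - s) * sweeps.sample_interval < 50:
        raise ValueError("step segment shorter than 50 ms")
    cur = sw["current_pA"].to_numpy()
    t = sw["time_ms"].to_numpy()
    pre = cur[max(0, s - int(baseline_ms / sweeps.sample_interval)):s]
    baseline = float(pre.mean()) if len(pre) else 0.0
    raw = cur[s:e] - baseline
    step_t = t[s:e] - t[s]
    fast_win = step_t <= split_time_ms
    slow_win = step_t > split_time_ms
    # light smoothing preserves the ms-scale fast peak; the slow component
    # tolerates a much wider window, which tames the noise floor over the
    # long search interval
    fast_cur = _smooth(raw, smooth_samples)
    slow_w = max(smooth_samples, int(round(20.0 / sweeps.sample_interval)) | 1)
    slow_cur = _smooth(raw, slow_w)
    fast = float(fast_cur[fast_win].min()) if fast_win.any() else 0.0
    slow = float(slow_cur[slow_win].min()) if slow_win.any() else 0.0
    return fast, slow


def density(peak_pA: float, cm_pF: float) -> float:
    """Capacitance-normalized current density, pA/pF."""
    if not cm_pF > 0:
        raise ValueError("cm_pF must be > 0")
    return peak_pA / cm_pF


def iv_curve(sweeps: SweepSet, window_ms: float = 100.0,
             mode: str = "steady", baseline_ms: float = 50.0) -> list[IVPoint]:
    """I–V relation over a step-protocol sweep set.

    ``mode="steady"``: current averaged over the terminal ``window_ms`` of
    each step (steady-state outward component).  ``mode="peak"``: extreme
    baseline-subtracted current within the step.  Points are ordered by
    step voltage.
    """
    if len(sweeps.sweep_ids) < 3:
        raise ValueError("need >= 3 steps for an I-V curve")
    pts = []
    for sid in sweeps.sweep_ids:
        sw = sweeps.sweep(sid)
        s, e, level = _step_bounds(sw)
        dt = sweeps.sample_interval
        nwin = int(round(window_ms / dt))
        if nwin > e - s:
            raise ValueError("window exceeds step duration")
        cur = sw["current_pA"].to_numpy()
        pre = cur[max(0, s - int(baseline_ms / dt)):s]
        baseline = float(pre.mean()) if len(pre) else 0.0
        if mode == "steady":
            i_val = float(cur[e - nwin:e].mean()) - baseline
        elif mode == "peak":
            seg = cur[s:e] - baseline
            i_val = float(seg[np.argmax(np.abs(seg))])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        pts.append(IVPoint(level, i_val, density(i_val, sweeps.cm_pF)))
    return sorted(pts, key=lambda p: p.voltage_mV)


def iv_table(points: list[IVPoint]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in points])


def apd80(time_ms: np.ndarray, vm_mV: np.ndarray, stim_time_ms: float,
          min_amplitude_mV: float = 20.0) -> ApMetrics:
    """Action-potential metrics from a current-clamp trace.

    Resting potential = pre-stimulus mean; the AP peak is the maximum after
    the stimulus; APD80 runs from the point of maximal upstroke velocity to
    the first crossing of peak − 0.8 × amplitude, linearly interpolated.
    The threshold is relative, so APD80 is invariant to voltage offset and
    amplitude scaling.  A trace with no depolarization above
    ``min_amplitude_mV`` yields a "no AP" result, not an exception.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    vm = np.asarray(vm_mV, dtype=float)
    pre = vm[time_ms < stim_time_ms]
    if len(pre) == 0:
        raise ValueError("no pre-stimulus samples")
    resting = float(pre.mean())
    after = time_ms >= stim_time_ms
    idx_after = np.nonzero(after)[0]
    i_peak = idx_after[np.argmax(vm[after])]
    peak = float(vm[i_peak])
    amp = peak - resting
    if amp < min_amplitude_mV:
        return ApMetrics(resting, peak, float("nan"), has_ap=False)
    # maximal upstroke velocity between stimulus and peak
    i0 = idx_after[0]
    dv = np.diff(vm[i0:i_peak + 1])
    i_up = i0 + (int(np.argmax(dv)) if len(dv) else 0)
    t_up = float(time_ms[i_up]) + 0.5 * (time_ms[1] - time_ms[0])
    thr = peak - 0.8 * amp
    seg = vm[i_peak:]
    below = np.nonzero(seg < thr)[0]
    if len(below) == 0:
        return ApMetrics(resting, peak, float("nan"), has_ap=True)
    j = int(below[0])
    if j == 0:
        t_cross = float(time_ms[i_peak])
    else:
        v0, v1 = seg[j - 1], seg[j]
        frac = (v0 - thr) / (v0 - v1) if v1 != v0 else 0.0
        t_cross = float(time_ms[i_peak + j - 1]
                        + frac * (time_ms[i_peak + j] - time_ms[i_peak + j - 1]))
    return ApMetrics(resting, peak, t_cross - t_up, has_ap=True)


def density_table(sweeps: SweepSet, split_time_ms: float = 10.0) -> pd.DataFrame:
    """Per-component density table for the inward-current protocol."""
    fast, slow = peak_inward(sweeps, split_time_ms=split_time_ms)
    rows = [
        {"component": "fast_inward", "peak_pA": fast, "cm_pF": sweeps.cm_pF,
         "density_pA_per_pF": density(fast, sweeps.cm_pF)},
        {"component": "slow_inward", "peak_pA": slow, "cm_pF": sweeps.cm_pF,
         "density_pA_per_pF": density(slow, sweeps.cm_pF)},
    ]
    return pd.DataFrame(rows)
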