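"""Synthetic inputs with known ground truth.

Everything the analysis consumes can be generated here: propagating calcium
waves sampled at a slow frame clock, spontaneous per-cell fluorescence
traces, striated/unstriated cell images, and voltage/current-clamp sweep
tables.  Each generator returns the artifact together with a truth record
holding the exact generating parameters, so recovery tests can compare the
measured quantities against analytic values.

The defaults encode the experimental conditions the toolkit targets:
Δt = 110 ms frame interval, ~300 µm cell clusters, spontaneous firing near
1 s period (irregular cells > 5 s), exponential calcium decay with
τ = 408 ms (so the analytic CaT50 = τ·ln 2 ≈ 283 ms), membrane capacitance
uniform in 12–30 pF, and current-density scales of 7.66 / 4.35 / 15.07
pA/pF for the fast-inward, slow-inward and outward components.

Key modelling choices (see docs/methods.md): transients rise
instantaneously and decay mono-exponentially, which makes CaT50 analytic;
wavefronts are planar by default (target waves optional); noise is additive
Gaussian; each beat's start phase relative to the frame clock is drawn
uniformly in [0, Δt), which is exactly the assumption behind the
frame-censored capture-probability model.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import FrameStack, RoiSet

LN2 = math.log(2.0)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class TransientTruth:
    """Generating parameters of one calcium transient train.

    ``cat50_ms`` is the analytic peak-to-half-decay duration τ·ln 2 implied
    by the instantaneous-rise / mono-exponential-decay waveform.
    """

    period_ms: float = 1000.0
    tau_decay_ms: float = 408.0
    amplitude: float = 400.0
    baseline: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not self.period_ms > 0:
            raise ValueError("period_ms must be > 0")
        if not self.tau_decay_ms > 0:
            raise ValueError("tau_decay_ms must be > 0")

    @property
    def cat50_ms(self) -> float:
        return self.tau_decay_ms * LN2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cat50_ms"] = self.cat50_ms
        return d


@dataclass
class WaveMovieTruth:
    """Ground truth of one propagating-wave movie."""

    cv_true: float                      # mm/s (≡ µm/ms)
    activation_true: np.ndarray         # per-pixel onset within a beat, ms; NaN outside
    cluster_mask: np.ndarray            # bool
    cluster_length_um: float            # maximal caliper length of the mask
    traversal_time_ms: float            # activation-time span across the cluster
    beat_onsets_ms: np.ndarray          # absolute wave-start time of each beat
    frames_per_beat: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "cv_true": self.cv_true,
            "cluster_length_um": self.cluster_length_um,
            "traversal_time_ms": self.traversal_time_ms,
            "beat_onsets_ms": self.beat_onsets_ms.tolist(),
            "frames_per_beat": self.frames_per_beat,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CellImageTruth:
    """Generating parameters of one synthetic cell image (stadium shape)."""

    length_um: float
    width_um: float
    orientation_deg: float = 0.0
    striation_period_um: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not (self.length_um >= self.width_um > 0):
            raise ValueError("need length_um >= width_um > 0")
        if self.striation_period_um is not None and not (
            1.0 <= self.striation_period_um <= 3.0
        ):
            raise ValueError("striation_period_um must lie in [1.0, 3.0] µm")

    # analytic stadium geometry -------------------------------------------
    @property
    def area_um2(self) -> float:
        w, L = self.width_um, self.length_um
        return w * (L - w) + math.pi * (w / 2) ** 2

    @property
    def perimeter_um(self) -> float:
        w, L = self.width_um, self.length_um
        return 2 * (L - w) + math.pi * w

    @property
    def circularity(self) -> float:
        return 4 * math.pi * self.area_um2 / self.perimeter_um**2

    @property
    def aspect_ratio(self) -> float:
        return self.length_um / self.width_um

    @property
    def feret_um(self) -> float:
        return self.length_um

    def descriptor_truth(self) -> dict:
        return {
            "area_um2": self.area_um2,
            "aspect_ratio": self.aspect_ratio,
            "circularity": self.circularity,
            "fractal_dimension": 1.0,  # smooth outline
            "feret_um": self.feret_um,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["descriptor_truth"] = self.descriptor_truth()
        return d


@dataclass(frozen=True)
class EphysTruth:
    """Peak current-density scales (pA/pF) and capacitance of one cell.

    Peak currents scale linearly with ``cm_pF`` by construction, so the
    densities are capacitance-invariant: density_truth = peak current / cm.
    """

    g_fast_in: float = 7.66    # pA/pF, fast inward (Na-like) at the 0 mV step
    g_slow_in: float = 4.35    # pA/pF, slow inward (L-type Ca-like)
    g_out: float = 15.07       # pA/pF, outward (Kv-like) plateau at +60 mV
    cm_pF: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not self.cm_pF > 0:
            raise ValueError("cm_pF must be > 0")

    def density_truth(self) -> dict:
        return {
            "fast_in": -self.g_fast_in,
            "slow_in": -self.g_slow_in,
            "out": self.g_out,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["density_truth"] = self.density_truth()
        return d


# ---------------------------------------------------------------------------
# wave movies


def _ellipse_mask(ny: int, nx: int, a_px: float, b_px: float) -> np.ndarray:
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    return ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0


def _max_caliper_um(mask: np.ndarray, pixel_size: float) -> float:
    """Maximal point-to-point distance across a mask, in µm (convex hull)."""
    from scipy.spatial import ConvexHull

    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear degenerate masks
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max())) * pixel_size


def gen_wave_movie(
    grid: tuple[int, int] = (32, 96),
    pixel_size: float = 5.0,
    cv: float = 20.0,
    frame_interval: float = 110.0,
    n_beats: int = 1,
    transient: TransientTruth | None = None,
    noise_sd: float = 20.0,
    seed: int = 0,
    cluster_length_um: float = 300.0,
    cluster_width_um: float = 100.0,
    wavefront: str = "planar",
    frames_per_beat: int | None = None,
) -> tuple[FrameStack, WaveMovieTruth]:
    """Simulate a calcium wave crossing an elliptical cell cluster.

    The wave enters the cluster at a uniformly random phase within the frame
    interval and propagates at ``cv`` mm/s (≡ µm/ms) along the cluster's
    major axis (``wavefront="planar"``) or radially from its centre
    (``"target"``).  Each pixel's fluorescence is baseline plus an
    instantaneous-rise, exponential-decay transient starting at its true
    onset time, sampled at ``frame_interval``, with additive Gaussian noise.

    Returns the movie and a truth record with the exact per-pixel onsets.
    """
    ny, nx = grid
    if ny <= 0 or nx <= 0:
        raise ValueError("grid dimensions must be positive")
    if not cv > 0:
        raise ValueError("cv (mm/s) must be > 0")
    if not frame_interval > 0:
        raise ValueError("frame_interval (ms) must be > 0")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    transient = transient or TransientTruth(seed=seed)
    a_px = cluster_length_um / 2.0 / pixel_size
    b_px = cluster_width_um / 2.0 / pixel_size
    if 2 * a_px > nx or 2 * b_px > ny:
        raise ValueError("grid does not cover the cluster mask")
    mask = _ellipse_mask(ny, nx, a_px, b_px)

    xx_um = np.arange(nx) * pixel_size
    yy_um = np.arange(ny) * pixel_size
    X, Y = np.meshgrid(xx_um, yy_um)
    if wavefront == "planar":
        dist = X - X[mask].min()
    elif wavefront == "target":
        cyx = ((ny - 1) / 2.0 * pixel_size, (nx - 1) / 2.0 * pixel_size)
        dist = np.hypot(Y - cyx[0], X - cyx[1])
    else:
        raise ValueError(f"unknown wavefront {wavefront!r}")
    onset = np.where(mask, dist / cv, np.nan)   # ms, cv in µm/ms
    onset = onset - np.nanmin(onset)
    t_traverse = float(np.nanmax(onset))

    tau = transient.tau_decay_ms
    if frames_per_beat is None:
        frames_per_beat = int(math.ceil((frame_interval + t_traverse + 4 * tau)
                                        / frame_interval))
    n_frames = n_beats * frames_per_beat

    rng = _rng(seed)
    phases = rng.uniform(0.0, frame_interval, size=n_beats)
    beat_onsets = phases + np.arange(n_beats) * frames_per_beat * frame_interval

    t_frames = np.arange(n_frames) * frame_interval
    frames = np.full((n_frames, ny, nx), transient.baseline, dtype=float)
    on_flat = onset[mask]
    for t0 in beat_onsets:
        # (frames, mask-pixels) elapsed time since this beat's onset
        dt_el = t_frames[:, None] - (t0 + on_flat[None, :])
        sig = np.where(dt_el >= 0, np.exp(-np.maximum(dt_el, 0.0) / tau), 0.0)
        frames[:, mask] += transient.amplitude * sig
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    stack = FrameStack(frames, frame_interval, pixel_size)
    truth = WaveMovieTruth(
        cv_true=cv,
        activation_true=onset,
        cluster_mask=mask,
        cluster_length_um=_max_caliper_um(mask, pixel_size),
        traversal_time_ms=t_traverse,
        beat_onsets_ms=beat_onsets,
        frames_per_beat=frames_per_beat,
        seed=seed,
    )
    return stack, truth


def single_frame_outcomes(truth: WaveMovieTruth, frame_interval: float) -> list[bool]:
    """Ground-truth capture outcome per beat.

    A beat is captured in a single frame iff the first and last pixel onsets
    fall within the same frame interval, i.e. no frame boundary lies inside
    the activation-time span.
    """
    out = []
    for t0 in truth.beat_onsets_ms:
        first = t0
        last = t0 + truth.traversal_time_ms
        out.append(math.floor(first / frame_interval)
                   == math.floor(last / frame_interval))
    return out


# ---------------------------------------------------------------------------
# spontaneous traces


def gen_spontaneous_traces(
    n_cells: int = 97,
    period_mean: float = 1000.0,
    period_sd: float = 80.0,
    tau_decay: float = 408.0,
    tau_sd: float = 43.0,
    irregular_fraction: float = 17 / 97,
    duration_s: float = 30.0,
    frame_interval: float = 110.0,
    noise_sd: float = 1.0,
    amplitude: float = 50.0,
    baseline: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[TransientTruth]]:
    """Simulate per-cell spontaneous calcium traces as a tidy table.

    Regular cells fire with Gaussian-jittered periods around ``period_mean``;
    a fraction fire irregularly with inter-event intervals > 5000 ms.
    Per-cell decay constants are drawn N(``tau_decay``, ``tau_sd``) to give a
    realistic population spread of CaT50; each truth record carries the
    analytic CaT50 = τ·ln 2 of its own cell.

    Returns a DataFrame (id, time_ms, value) and the truth list.
    """
    if not 0 <= irregular_fraction <= 1:
        raise ValueError("irregular_fraction must be in [0, 1]")
    duration_ms = duration_s * 1000.0
    if duration_ms < 2 * period_mean:
        raise ValueError("duration too short to contain one full transient cycle")
    rng = _rng(seed)
    n_irregular = int(round(irregular_fraction * n_cells))
    kinds = ["irregular"] * n_irregular + ["regular"] * (n_cells - n_irregular)
    rng.shuffle(kinds)

    times = np.arange(0.0, duration_ms, frame_interval)
    rows = []
    truths: list[TransientTruth] = []
    for cell, kind in enumerate(kinds):
        tau = max(50.0, rng.normal(tau_decay, tau_sd))
        if kind == "regular":
            period = period_mean
            t = rng.uniform(100.0, 100.0 + period)
            peaks = []
            while t < duration_ms:
                peaks.append(t)
                t += max(period / 4, rng.normal(period, period_sd))
        else:
            period = 7000.0
            t = rng.uniform(100.0, 2000.0)
            peaks = []
            while t < duration_ms:
                peaks.append(t)
                t += rng.uniform(5500.0, 9000.0)
        trace = np.full_like(times, baseline)
        for tp in peaks:
            el = times - tp
            trace += np.where(el >= 0, amplitude * np.exp(-np.maximum(el, 0) / tau), 0)
        if noise_sd > 0:
            trace = trace + rng.normal(0, noise_sd, size=trace.shape)
        rows.append(pd.DataFrame({"id": cell, "time_ms": times, "value": trace}))
        truths.append(TransientTruth(period_ms=period, tau_decay_ms=tau,
                                     amplitude=amplitude, baseline=baseline,
                                     seed=seed))
    return pd.concat(rows, ignore_index=True), truths


def gen_single_transient(
    tau_decay: float,
    frame_interval: float = 110.0,
    duration_ms: float = 5000.0,
    onset_ms: float = 300.0,
    amplitude: float = 50.0,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, TransientTruth]:
    """One isolated instantaneous-rise / exponential-decay transient.

    Convenience for convergence tests: the analytic CaT50 is τ·ln 2.
    """
    times = np.arange(0.0, duration_ms, frame_interval)
    el = times - onset_ms
    trace = baseline + np.where(el >= 0, amplitude * np.exp(-np.maximum(el, 0) / tau_decay), 0)
    if noise_sd > 0:
        trace = trace + _rng(seed).normal(0, noise_sd, size=trace.shape)
    truth = TransientTruth(period_ms=duration_ms, tau_decay_ms=tau_decay,
                           amplitude=amplitude, baseline=baseline, seed=seed)
    return trace, truth


# ---------------------------------------------------------------------------
# cell images


def gen_cell_image(
    truth: CellImageTruth,
    pixel_size: float = 0.2,
    noise_sd: float = 0.02,
    margin_um: float = 5.0,
    foreground: float = 0.6,
    background: float = 0.05,
    modulation: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a rotated stadium-shaped cell, optionally striated.

    When ``truth.striation_period_um`` is set, the intensity inside the mask
    is modulated sinusoidally along the major axis at that period (the
    sarcomere-banding analogue).  The returned mask is the exact generating
    footprint.  Periods below 4 pixels are rejected (aliasing).
    """
    if truth.striation_period_um is not None:
        if truth.striation_period_um / pixel_size < 4:
            raise ValueError(
                "striation period below 4 pixels would alias; decrease pixel_size"
            )
    half = truth.length_um / 2 + margin_um
    n = int(math.ceil(2 * half / pixel_size))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x_um = (xx - c) * pixel_size
    y_um = (yy - c) * pixel_size
    # rotate coordinates into the cell frame (major axis along +x)
    th = math.radians(truth.orientation_deg)
    xr = x_um * math.cos(th) + y_um * math.sin(th)
    yr = -x_um * math.sin(th) + y_um * math.cos(th)
    seg = (truth.length_um - truth.width_um) / 2.0  # half-length of the core segment
    dx = np.maximum(np.abs(xr) - seg, 0.0)
    mask = np.hypot(dx, yr) <= truth.width_um / 2.0

    image = np.full((n, n), background)
    inten = foreground * np.ones_like(image)
    if truth.striation_period_um is not None:
        inten *= 1.0 + modulation * np.sin(2 * math.pi * xr / truth.striation_period_um)
    image[mask] = inten[mask]
    if noise_sd > 0:
        image = image + _rng(truth.seed).normal(0, noise_sd, size=image.shape)
    return np.clip(image, 0.0, None), mask


# ---------------------------------------------------------------------------
# geometry fixtures for morphometry oracles


def disk_mask(radius_px: int, pad: int = 4) -> np.ndarray:
    n = 2 * radius_px + 2 * pad + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def square_mask(side_px: int, pad: int = 4) -> np.ndarray:
    n = side_px + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    m[pad:pad + side_px, pad:pad + side_px] = True
    return m


def koch_snowflake_mask(level: int = 5, image_size: int = 1024) -> np.ndarray:
    """Rasterized Koch snowflake (boundary dimension log 4 / log 3 ≈ 1.2619)."""
    from skimage.draw import polygon

    def subdivide(pts: np.ndarray) -> np.ndarray:
        out = []
        for i in range(len(pts)):
            a, b = pts[i], pts[(i + 1) % len(pts)]
            v = b - a
            p1 = a + v / 3
            p2 = a + v * 2 / 3
            rot = np.array([[math.cos(-math.pi / 3), -math.sin(-math.pi / 3)],
                            [math.sin(-math.pi / 3), math.cos(-math.pi / 3)]])
            tip = p1 + rot @ (p2 - p1)
            out.extend([a, p1, tip, p2])
        return np.array(out)

    r = 0.42 * image_size
    ang = np.array([math.pi / 2, math.pi / 2 + 2 * math.pi / 3,
                    math.pi / 2 + 4 * math.pi / 3])
    pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    for _ in range(level):
        pts = subdivide(pts)
    pts += image_size / 2.0
    rr, cc = polygon(pts[:, 1], pts[:, 0], shape=(image_size, image_size))
    mask = np.zeros((image_size, image_size), dtype=bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# ephys sweeps


@dataclass(frozen=True)
class StepProtocol:
    """A holding / prestep / test-step voltage-clamp protocol."""

    name: str
    step_levels_mV: tuple[float, ...]
    step_ms: float
    prestep_mV: float | None = None
    prestep_ms: float = 0.0
    holding_mV: float = -80.0
    holding_ms: float = 50.0
    post_ms: float = 50.0

    def __post_init__(self):
        if self.step_ms <= 0 or self.holding_ms < 0 or self.post_ms < 0:
            raise ValueError("protocol durations must be positive and ordered")
        if self.prestep_mV is not None and self.prestep_ms <= 0:
            raise ValueError("prestep duration must be > 0 when a prestep is set")


#: fast (Na-like) / slow (Ca-like) inward protocol: −30 mV prestep then 0 mV step
PROTOCOL_INWARD = StepProtocol("inward", (0.0,), 300.0,
                               prestep_mV=-30.0, prestep_ms=150.0)
#: I–V protocol: steps −30 … +60 mV in 15 mV increments, 2.5 s each
PROTOCOL_IV = StepProtocol("iv", tuple(float(v) for v in range(-30, 61, 15)), 2500.0)
#: long outward-current step protocol: −40 … +60 mV, 5 s steps
PROTOCOL_OUTWARD_STEP = StepProtocol(
    "outward_step", tuple(float(v) for v in range(-40, 61, 10)), 5000.0)

TAU_FAST_MS = 1.2     # fast inward α-function time constant: peaks ~1 ms
                      # after onset and is fully inactivated before the
                      # 10 ms fast/slow split
SLOW_DELAY_MS = 5.0   # slow inward onset delay
TAU_SLOW_MS = 25.0    # slow inward α-function time constant (peak > 15 ms)
TAU_OUT_MS = 300.0    # outward plateau activation
E_K_MV = -85.0


def _alpha(t: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak α-function (t/τ)·exp(1 − t/τ), zero for t < 0."""
    x = np.maximum(t, 0.0) / tau
    return np.where(t >= 0, x * np.exp(1.0 - x), 0.0)


def _w_fast(v: float) -> float:
    return math.exp(-((v - 0.0) / 30.0) ** 2)


def _w_slow(v: float) -> float:
    return math.exp(-((v - 0.0) / 25.0) ** 2)


def _w_out(v: float) -> float:
    # delayed-rectifier-like activation: closed at and below 0 mV, so the
    # outward component does not contaminate the inward-current protocol
    return max(0.0, v / 60.0)


def gen_ephys_sweeps(
    truth: EphysTruth,
    protocol: StepProtocol = PROTOCOL_INWARD,
    sample_interval: float = 0.5,
    noise_sd: float = 2.0,
    leak_pA: float = 10.0,
    seed: int = 0,
    mode: str = "cardiac",
    g_lin_pA_per_pF_mV: float = 0.1,
    e_rev_mV: float = E_K_MV,
) -> pd.DataFrame:
    """Simulate voltage-clamp sweeps for a step protocol.

    ``mode="cardiac"`` composes three phenomenological components: a brief
    fast inward transient (peak ~1.5 ms after step onset), a delayed slow
    inward transient (peak ~30 ms), and an outward current rising to a
    plateau.  All amplitudes scale linearly with ``truth.cm_pF``, so
    densities are capacitance-invariant.  ``mode="linear"`` produces an
    ideal ohmic conductance I = g·cm·(V − E_rev) for closed-form I–V tests.

    Returns a tidy table (sweep_id, time_ms, command_mV, current_pA).
    """
    if sample_interval > 2.0:
        raise ValueError("sample_interval > 2 ms cannot resolve the fast component")
    if mode not in ("cardiac", "linear"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = _rng(seed)
    cm = truth.cm_pF
    total_ms = (protocol.holding_ms + protocol.prestep_ms
                + protocol.step_ms + protocol.post_ms)
    t = np.arange(0.0, total_ms, sample_interval)
    step_on = protocol.holding_ms + protocol.prestep_ms
    step_off = step_on + protocol.step_ms
    frames = []
    for i, v in enumerate(protocol.step_levels_mV):
        cmd = np.full_like(t, protocol.holding_mV)
        if protocol.prestep_mV is not None:
            cmd[(t >= protocol.holding_ms) & (t < step_on)] = protocol.prestep_mV
        in_step = (t >= step_on) & (t < step_off)
        cmd[in_step] = v
        cur = np.full_like(t, leak_pA)
        ts = t - step_on
        if mode == "cardiac":
            comp = (-truth.g_fast_in * _w_fast(v) * _alpha(ts, TAU_FAST_MS)
                    - truth.g_slow_in * _w_slow(v) * _alpha(ts - SLOW_DELAY_MS, TAU_SLOW_MS)
                    + truth.g_out * _w_out(v) * np.where(ts >= 0, 1 - np.exp(-np.maximum(ts, 0) / TAU_OUT_MS), 0))
            cur = cur + np.where(in_step, cm * comp, 0.0)
        else:
            cur = cur + np.where(in_step, g_lin_pA_per_pF_mV * cm * (v - e_rev_mV), 0.0)
        if noise_sd > 0:
            cur = cur + rng.normal(0, noise_sd, size=cur.shape)
        frames.append(pd.DataFrame({
            "sweep_id": i, "time_ms": t, "command_mV": cmd, "current_pA": cur,
        }))
    return pd.concat(frames, ignore_index=True)


def gen_ap_trace(
    resting_mV: float = -50.0,
    peak_mV: float = 25.0,
    apd80_ms: float = 50.0,
    stim_time_ms: float = 50.0,
    upstroke_ms: float = 2.0,
    duration_ms: float = 400.0,
    sample_interval: float = 0.2,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a stimulus-evoked action potential with known APD80.

    The upstroke is a half-cosine (maximal dV/dt exactly at its midpoint)
    and repolarization is linear, with the slope chosen so that the
    80%-repolarization crossing occurs ``apd80_ms`` after the point of
    maximal upstroke velocity.  Returns a table (time_ms, vm_mV).
    """
    amp = peak_mV - resting_mV
    if amp <= 0:
        raise ValueError("peak must exceed resting potential")
    t = np.arange(0.0, duration_ms, sample_interval)
    vm = np.full_like(t, resting_mV)
    t_up_mid = stim_time_ms + upstroke_ms / 2.0        # max dV/dt
    t_peak = stim_time_ms + upstroke_ms
    rise = (t >= stim_time_ms) & (t < t_peak)
    vm[rise] = resting_mV + amp * 0.5 * (
        1 - np.cos(math.pi * (t[rise] - stim_time_ms) / upstroke_ms))
    # linear repolarization: crossing of (peak − 0.8·amp) at t_up_mid + apd80
    t_cross = t_up_mid + apd80_ms
    if t_cross <= t_peak:
        raise ValueError("apd80 too short for the chosen upstroke duration")
    slope = 0.8 * amp / (t_cross - t_peak)             # mV/ms downwards
    fall = t >= t_peak
    vm[fall] = np.maximum(peak_mV - slope * (t[fall] - t_peak), resting_mV)
    if noise_sd > 0:
        vm = vm + _rng(seed).normal(0, noise_sd, size=vm.shape)
    return pd.DataFrame({"time_ms": t, "vm_mV": vm})


def wave_roi(truth: WaveMovieTruth, name: str = "cluster") -> RoiSet:
    """RoiSet with the movie's cluster mask as label 1."""
    return RoiSet(truth.cluster_mask.astype(np.int64), {1: name})
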