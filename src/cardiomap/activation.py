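"""Adaptive-threshold activation maps, propagation events, synchronization.

The activation-map rule is per-pixel adaptive: a pixel activates at the
first frame (within the beat window) whose intensity exceeds its own
temporal mean brightness by a defined percentage θ.  Because the threshold
is relative to each pixel's mean, the map is invariant to global intensity
scaling and tolerant of spatially non-uniform staining — unlike a fixed
global threshold.  θ has no universally correct value; it is a mandatory,
logged parameter (default 0.10).

A propagation event across a cluster is classified by the number of frames
its activation spans: ``single_frame`` events (span 1) are the censored
observations feeding the frame-limited conduction-velocity bound in
:mod:`cardiomap.cvbound`; ``multi_frame`` events admit direct gradient CV
estimation (:func:`estimate_cv`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io import FrameStack, RoiSet
from .synth import _max_caliper_um

logger = logging.getLogger(__name__)

NEVER = -1  # sentinel frame index for pixels that never cross threshold


@dataclass
class ActivationMap:
    """Per-pixel activation times for one beat.

    ``frames`` holds the 0-based activation frame index (−1 = never
    activated); ``times_ms`` re-zeroes to the earliest activated pixel and
    uses NaN for never-activated pixels, keeping the "activated at t = 0"
    and "never activated" cases distinct.
    """

    frames: np.ndarray           # int frame indices, NEVER sentinel
    theta: float
    frame_interval: float        # ms
    beat_index: int = 0

    @property
    def activated(self) -> np.ndarray:
        return self.frames != NEVER

    @property
    def n_activated(self) -> int:
        return int(self.activated.sum())

    @property
    def first_frame(self) -> int:
        act = self.frames[self.activated]
        return int(act.min()) if act.size else NEVER

    @property
    def times_ms(self) -> np.ndarray:
        t = np.full(self.frames.shape, np.nan)
        if self.n_activated:
            t[self.activated] = (self.frames[self.activated] - self.first_frame
                                 ) * self.frame_interval
        return t

    @property
    def is_empty(self) -> bool:
        return self.n_activated == 0


@dataclass
class PropagationEvent:
    """One wave crossing of a cluster, as seen by the frame clock."""

    cluster_length_um: float
    frames_spanned: int
    frame_interval_ms: float
    beat_index: int = 0

    def __post_init__(self):
        if self.frames_spanned < 1:
            raise ValueError("frames_spanned must be >= 1")

    @property
    def outcome(self) -> str:
        return "single_frame" if self.frames_spanned == 1 else "multi_frame"


def activation_map(stack: FrameStack, theta: float = 0.10,
                   beat_window: tuple[int, int] | None = None,
                   beat_index: int = 0, prefilter: bool = False,
                   mode: str = "raw") -> ActivationMap:
    """Adaptive-threshold activation map for one beat window.

    Per pixel, the activation frame is the first frame in the window where
    intensity exceeds (1 + θ) × that pixel's temporal mean brightness (the
    mean is over the full recording, which is stable across beats).  With
    ``mode="dff"`` the threshold applies to the ΔF/F-normalized stack
    instead; this changes nothing for uniform staining but can help when
    baseline brightness varies strongly across pixels.

    An empty map (no pixel crosses threshold) is flagged, not an error.
    """
    if not theta > 0:
        raise ValueError("theta must be > 0")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = np.asarray(stack.frames, dtype=float)
    if prefilter:
        logger.info("applying 3x3 spatial median prefilter")
        frames = ndimage.median_filter(frames, size=(1, 3, 3))
    mean = frames.mean(axis=0)
    if mode == "dff":
        frames = (frames - mean) / np.maximum(mean, 1e-12)
        thr = theta * np.ones_like(mean)
        mean_like = np.zeros_like(mean)
        above = frames > thr
    elif mode == "raw":
        above = frames > (1.0 + theta) * mean
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = beat_window if beat_window is not None else (0, stack.n_frames)
    if not (0 <= lo < hi <= stack.n_frames):
        raise ValueError(f"beat_window {lo, hi} outside stack")
    win = above[lo:hi]
    any_cross = win.any(axis=0)
    first = win.argmax(axis=0) + lo
    out = np.where(any_cross, first, NEVER)
    amap = ActivationMap(out, theta, stack.frame_interval, beat_index)
    logger.info("activation_map: theta=%.3g window=(%d,%d) activated=%d/%d",
                theta, lo, hi, amap.n_activated, out.size)
    return amap


def split_beats(stack: FrameStack, prominence_fraction: float = 0.3) -> list[tuple[int, int]]:
    """Split a multi-beat movie into per-beat frame windows.

    Beats are located as peaks of the global mean-intensity trace; window
    boundaries sit midway between successive peaks.
    """
    trace = stack.frames.mean(axis=(1, 2))
    rng_amp = trace.max() - trace.min()
    if rng_amp <= 0:
        return [(0, stack.n_frames)]
    peaks, _ = signal.find_peaks(trace, prominence=prominence_fraction * rng_amp)
    if len(peaks) <= 1:
        return [(0, stack.n_frames)]
    bounds = [0] + [int((a + b) // 2) for a, b in zip(peaks[:-1], peaks[1:])] + [stack.n_frames]
    return list(zip(bounds[:-1], bounds[1:]))


def map_beats(stack: FrameStack, theta: float = 0.10, **kwargs) -> list[ActivationMap]:
    """Activation map for every beat window of a multi-beat movie."""
    return [activation_map(stack, theta, beat_window=w, beat_index=i, **kwargs)
            for i, w in enumerate(split_beats(stack))]


def classify_event(amap: ActivationMap, roi: RoiSet, label: int,
                   pixel_size: float) -> PropagationEvent:
    """Classify one wave crossing of a cluster as single- or multi-frame.

    ``frames_spanned`` = (max − min activation frame within the cluster) + 1;
    the cluster length is the maximal caliper (Feret) length of its mask.
    """
    mask = roi.mask(label)
    act = amap.frames[mask]
    act = act[act != NEVER]
    if act.size < 2:
        raise ValueError("fewer than 2 activated pixels in cluster; nothing to classify")
    spanned = int(act.max() - act.min() + 1)
    length = _max_caliper_um(mask, pixel_size)
    return PropagationEvent(length, spanned, amap.frame_interval, amap.beat_index)


def synchronization(amap: ActivationMap, groups: RoiSet,
                    tolerance_ms: float | None = None,
                    reference: str | None = None):
    """Per-group activation-time offsets and a synchronized verdict.

    The offset of each named group is |median activation time − median of
    the reference group| (reference defaults to the first named group).
    Synchronized iff every participating group's offset is within the
    tolerance (default: one frame interval).  A group with no activated
    pixels is reported as non-participating and forces the flag false.
    """
    import pandas as pd

    if len(groups.names) < 1:
        raise ValueError("need at least one named group")
    if tolerance_ms is None:
        tolerance_ms = amap.frame_interval
    times = amap.times_ms
    rows = []
    medians: dict[str, float] = {}
    for label, name in groups.names.items():
        vals = times[groups.mask(label)]
        vals = vals[np.isfinite(vals)]
        med = float(np.median(vals)) if vals.size else np.nan
        medians[name] = med
        rows.append({"group": name, "n_pixels": int(groups.mask(label).sum()),
                     "n_activated": int(vals.size), "median_time_ms": med})
    ref = reference if reference is not None else rows[0]["group"]
    if ref not in medians:
        raise ValueError(f"reference group {ref!r} not in RoiSet")
    table = pd.DataFrame(rows)
    table["offset_ms"] = [abs(m - medians[ref]) if np.isfinite(m) else np.nan
                          for m in table["median_time_ms"]]
    participating = table["n_activated"] > 0
    synchronized = bool(participating.all()
                        and (table.loc[participating, "offset_ms"] <= tolerance_ms).all())
    return table, synchronized


def space_time_plot(stack: FrameStack, path_pixels: np.ndarray) -> np.ndarray:
    """Space–time image: row i is path pixel i's time series, row-normalized to [0, 1]."""
    path_pixels = np.asarray(path_pixels)
    if path_pixels.ndim != 2 or path_pixels.shape[0] < 2:
        raise ValueError("path needs >= 2 (row, col) pixels")
    ny, nx = stack.frames.shape[1:]
    r, c = path_pixels[:, 0], path_pixels[:, 1]
    if (r < 0).any() or (r >= ny).any() or (c < 0).any() or (c >= nx).any():
        raise ValueError("path outside image")
    img = stack.frames[:, r, c].T.astype(float)   # (position, time)
    lo = img.min(axis=1, keepdims=True)
    span = img.max(axis=1, keepdims=True) - lo
    span[span == 0] = 1.0
    return (img - lo) / span


def line_path(start: tuple[int, int], end: tuple[int, int]) -> np.ndarray:
    """Integer pixel path between two (row, col) points."""
    from skimage.draw import line

    rr, cc = line(*start, *end)
    return np.column_stack([rr, cc])


def estimate_cv(amap: ActivationMap, pixel_size: float,
                mask: np.ndarray | None = None) -> float:
    """Conduction velocity (mm/s) from the activation-map time gradient.

    Fits a plane t(x, y) = a·x + b·y + c to the activated pixels' times by
    least squares; CV = 1 / |(a, b)| in µm/ms ≡ mm/s.  Frame quantization
    averages out over the fit, so waves spanning ≥ 3 frames are recovered
    accurately; sub-frame waves have no usable gradient (returns inf when
    all pixels share one frame).
    """
    sel = amap.activated if mask is None else (amap.activated & mask)
    if sel.sum() < 3:
        raise ValueError("need >= 3 activated pixels for a gradient fit")
    t = (amap.frames[sel] - amap.first_frame) * amap.frame_interval
    yy, xx = np.nonzero(sel)
    A = np.column_stack([xx * pixel_size, yy * pixel_size, np.ones_like(xx, dtype=float)])
    coef, *_ = np.linalg.lstsq(A, t.astype(float), rcond=None)
    grad = float(np.hypot(coef[0], coef[1]))   # ms/µm
    return np.inf if grad == 0 else 1.0 / grad


def plot_activation_map(amap: ActivationMap, ax=None, cmap: str = "viridis"):
    """Render the activation-time map (ms); NaN pixels are left blank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(amap.times_ms, cmap=cmap, interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="activation time (ms)")
    ax.set_title(f"activation map (theta={amap.theta:g}, beat {amap.beat_index})")
    return ax


def plot_space_time(stp: np.ndarray, frame_interval: float, pixel_size: float, ax=None):
    """Render a space–time plot (position vs time, normalized intensity)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = (0, stp.shape[1] * frame_interval, stp.shape[0] * pixel_size, 0)
    ax.imshow(stp, aspect="auto", cmap="magma", extent=extent)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("position along path (µm)")
    return ax
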