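"""Calcium-trace and LFP burst analysis.

Fluorescence traces (mean ROI gray value per frame) are converted to dF/F
against a slowly varying baseline estimated by asymmetric least squares
(AsLS): a smoothness-penalized fit whose weights suppress points above the
current estimate, so positive transients (bursts) do not drag the baseline
up.  Bursts are maximal runs of dF/F above ``3 x std`` (a robust std, since
the plain one is inflated by the bursts themselves) and are summarized by
duration, peak and area under curve.

LFP channels (typically a culture-edge and a culture-center electrode) are
band-passed, notch-filtered at the mains harmonics, rectified, and burst
initiation times are extracted with a persistence rule: a threshold
crossing counts only if the trace stays above threshold for 10 ms, and no
new initiation registers until the trace falls below threshold again.
Matching initiations across the two channels yields per-burst delays and
the fraction of bursts that initiate at the center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import butter, iirnotch, sosfiltfilt, filtfilt
from scipy.sparse.linalg import spsolve

__all__ = [
    "FluorescenceTrace",
    "BurstEvent",
    "LfpTrace",
    "baseline",
    "dff",
    "detect_bursts",
    "segment_baseline_profile",
    "lfp_preprocess",
    "burst_initiation_time",
    "initiation_delay",
]


@dataclass
class FluorescenceTrace:
    """Raw mean-ROI fluorescence sampled at a uniform frame interval (s)."""

    values: np.ndarray
    frame_interval: float = 0.2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values < 0):
            raise ValueError("fluorescence values must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval


@dataclass
class BurstEvent:
    onset: float  # s
    offset: float  # s
    duration: float  # s
    peak_dff: float
    auc: float  # dF/F * s

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("burst offset must follow onset")


@dataclass
class LfpTrace:
    """Extracellular field potential (uV) at a uniform sample rate (Hz)."""

    values: np.ndarray
    sample_rate: float = 6000.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


def baseline(
    trace: FluorescenceTrace | np.ndarray,
    smoothness: float = 1e7,
    asymmetry: float = 0.01,
    iterations: int = 10,
) -> np.ndarray:
    """Asymmetric-least-squares baseline of a fluorescence trace.

    Iteratively minimizes ``sum w_i (y_i - z_i)^2 + lam * sum (D2 z)^2``
    with weights ``w_i = p`` where ``y_i > z_i`` and ``1 - p`` otherwise,
    so the fit hugs the lower envelope of the signal.
    """
    y = trace.values if isinstance(trace, FluorescenceTrace) else np.asarray(trace, float)
    n = len(y)
    if n < 10:
        raise ValueError("trace must have at least 10 samples")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    if not 0.0 < asymmetry < 1.0:
        raise ValueError("asymmetry must lie in (0, 1)")
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothness * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(iterations):
        W = sp.diags(w, format="csc")
        z = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def dff(trace: FluorescenceTrace | np.ndarray, F0: np.ndarray) -> np.ndarray:
    """dF/F = (R - F0) / F0, elementwise."""
    R = trace.values if isinstance(trace, FluorescenceTrace) else np.asarray(trace, float)
    F0 = np.asarray(F0, dtype=float)
    bad = np.where(F0 <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive baseline at sample index {bad[0]}")
    return (R - F0) / F0


def robust_std(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation (consistent with sigma for normals)."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def detect_bursts(
    dff_series: np.ndarray,
    frame_interval: float = 0.2,
    threshold_sigma: float = 3.0,
    min_duration_s: float = 1.0,
) -> tuple[list[BurstEvent], dict]:
    """Threshold-crossing burst detection on a dF/F series.

    The threshold is ``threshold_sigma`` times the robust std of the whole
    series; maximal supra-threshold runs of at least ``min_duration_s``
    become bursts with duration (frames x frame interval), peak dF/F and
    trapezoidal AUC.  The duration floor exists because a 3-sigma
    threshold on a Gaussian noise floor is statistically guaranteed to be
    crossed by isolated frames (~0.1% of them), while network bursts last
    tens of seconds; runs shorter than the floor are treated as noise.
    Returns the events plus a summary with the total active-time fraction
    and the threshold used.
    """
    x = np.asarray(dff_series, dtype=float).ravel()
    if len(x) < 10:
        raise ValueError("series must have at least 10 samples")
    sigma = robust_std(x)
    if sigma == 0:
        warnings.warn("zero-variance dF/F series: no bursts detectable", stacklevel=2)
        return [], {"threshold": 0.0, "active_time_fraction": 0.0, "n_bursts": 0}
    thr = threshold_sigma * sigma
    min_frames = max(int(np.ceil(min_duration_s / frame_interval)), 1)
    above = x > thr
    events: list[BurstEvent] = []
    active_frames = 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in edges.reshape(-1, 2):  # [start, stop) runs
        if stop - start < min_frames:
            continue
        active_frames += stop - start
        seg = x[start:stop]
        duration = (stop - start) * frame_interval
        auc = float(np.trapezoid(seg, dx=frame_interval)) if stop - start > 1 else float(
            seg[0] * frame_interval
        )
        events.append(
            BurstEvent(
                onset=start * frame_interval,
                offset=stop * frame_interval,
                duration=duration,
                peak_dff=float(seg.max()),
                auc=auc,
            )
        )
    summary = {
        "threshold": thr,
        "active_time_fraction": active_frames / len(x),
        "n_bursts": len(events),
    }
    return events, summary


def bursts_to_frame(events: list[BurstEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset_s": e.onset,
                "offset_s": e.offset,
                "duration_s": e.duration,
                "peak_dff": e.peak_dff,
                "auc": e.auc,
            }
            for e in events
        ],
        columns=["onset_s", "offset_s", "duration_s", "peak_dff", "auc"],
    )


def segment_baseline_profile(traces: list[FluorescenceTrace], **baseline_kwargs) -> np.ndarray:
    """Normalized inactive-period baseline brightness per culture segment.

    For each segment trace the burst mask (3-sigma on dF/F) is computed and
    the mean raw fluorescence over the *inactive* frames taken; the means
    are divided by the maximum across segments, giving values in (0, 1].
    """
    if not traces:
        raise ValueError("no segment traces given")
    means = []
    for tr in traces:
        F0 = baseline(tr, **baseline_kwargs)
        series = dff(tr, F0)
        sigma = robust_std(series)
        # small absolute floor: numerically flat segments are all-inactive
        inactive = series <= max(3.0 * sigma, 1e-6)
        if not inactive.any():
            raise ValueError("a segment has no inactive frames")
        means.append(float(tr.values[inactive].mean()))
    means = np.asarray(means)
    return means / means.max()


def lfp_preprocess(
    trace: LfpTrace,
    band: tuple = (100.0, 3000.0),
    notch_fundamental: float = 60.0,
    notch_q: float = 60.0,
) -> LfpTrace:
    """Band-pass plus mains-harmonic notch filtering of a raw LFP trace.

    The band upper edge is capped just below Nyquist; notches are applied
    at every harmonic of the fundamental up to the band edge.  The notch
    quality factor is high (narrow notches) because ~50 cascaded harmonics
    otherwise accumulate visible passband ripple.
    """
    fs = trace.sample_rate
    nyq = fs / 2.0
    hi = min(band[1], 0.99 * nyq)
    sos = butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, trace.values)
    f = notch_fundamental
    while f < hi:
        b, a = iirnotch(f, notch_q, fs=fs)
        x = filtfilt(b, a, x)
        f += notch_fundamental
    return LfpTrace(x, fs)


def burst_initiation_time(
    trace: LfpTrace,
    threshold: float,
    persistence: float = 0.010,
) -> np.ndarray:
    """Burst initiation times (s) under the persistence rule.

    A sample is an initiation when the (already rectified/processed) trace
    is at or above ``threshold`` for the whole window ``[t, t +
    persistence]``; after one registers, the trace must fall below
    threshold before another can.
    """
    x = np.abs(trace.values)
    fs = trace.sample_rate
    n_persist = int(round(persistence * fs))
    if n_persist < 1:
        raise ValueError("persistence must cover at least one sample")
    above = x >= threshold
    times = []
    armed = True
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            if armed and i + n_persist < n and above[i : i + n_persist + 1].all():
                times.append(i / fs)
                armed = False
        else:
            armed = True
        i += 1
    return np.asarray(times)


def auto_threshold(trace: LfpTrace, window: float = 0.1) -> float:
    """Std of the quietest ``window``-second segment of the trace.

    Automates the manual silent-segment selection: the contiguous window
    with minimal variance is taken as noise, and its std is the activity
    threshold for that electrode.
    """
    x = trace.values
    w = int(round(window * trace.sample_rate))
    if w < 2 or w > len(x):
        raise ValueError("window does not fit the trace")
    c1 = np.cumsum(np.insert(x, 0, 0.0))
    c2 = np.cumsum(np.insert(x * x, 0, 0.0))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = s2 / w - (s1 / w) ** 2
    return float(np.sqrt(max(var.min(), 0.0)))


def initiation_delay(
    edge: LfpTrace,
    center: LfpTrace,
    edge_threshold: float | None = None,
    center_threshold: float | None = None,
    persistence: float = 0.010,
    pairing_window: float = 5.0,
) -> tuple[np.ndarray, float, dict]:
    """Per-burst initiation delay between an edge and a center electrode.

    Initiation times are detected on both channels, matched greedily to the
    nearest partner within ``pairing_window`` seconds, and the delay is
    ``edge time - center time`` (positive = center leads).  The
    center-leading fraction counts strictly positive delays over all
    matched non-tied bursts; exact ties are excluded from both numerator
    and denominator.  Unmatched initiations are reported in the info dict.
    """
    thr_e = auto_threshold(edge) if edge_threshold is None else edge_threshold
    thr_c = auto_threshold(center) if center_threshold is None else center_threshold
    t_edge = burst_initiation_time(edge, thr_e, persistence)
    t_center = burst_initiation_time(center, thr_c, persistence)

    pairs = []
    used_c: set[int] = set()
    for i, te in enumerate(t_edge):
        if len(t_center) == 0:
            break
        order = np.argsort(np.abs(t_center - te))
        for j in order:
            if j in used_c:
                continue
            if abs(t_center[j] - te) <= pairing_window:
                pairs.append((i, int(j)))
                used_c.add(int(j))
            break
    delays = np.array([t_edge[i] - t_center[j] for i, j in pairs])
    non_tied = delays[delays != 0]
    frac = float((non_tied > 0).mean()) if len(non_tied) else np.nan
    info = {
        "n_edge": len(t_edge),
        "n_center": len(t_center),
        "n_matched": len(pairs),
        "n_ties": int((delays == 0).sum()),
        "edge_threshold": thr_e,
        "center_threshold": thr_c,
    }
    return delays, frac, info
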