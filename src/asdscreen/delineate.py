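"""ECG and phonocardiogram fiducial detection.

Detects R peaks and Q-wave onsets on the filtered ECG, S1/S2 bursts on a
Shannon-style smoothed energy envelope of the filtered PCG, and the
A2/P2 sub-components of S2 on a finer sub-envelope. All fiducials are
real-valued milliseconds on the shared clock (t = 0 at the start of both
channels), refined to sub-sample precision by parabolic interpolation.

Q onset uses the tangent method: the steepest point of the Q downstroke
is extrapolated back to the local baseline. S1 is the dominant envelope
peak in [R, R+200 ms]; S2 the dominant peak in [R+200 ms, R+0.6*RR];
onsets are the 10 %-of-peak-height crossings. A2 and P2 are the first and
second of the two dominant sub-envelope peaks inside the S2 window; when
only one peak is resolvable the split is zero and the fiducials coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import ECG_FS, PCG_FS, ArtifactMask, smoothed_envelope

__all__ = [
    "BeatAnnotation",
    "detect_r_peaks",
    "detect_q_onset",
    "pcg_envelope",
    "segment_s1_s2",
    "split_s2",
    "select_beats",
    "delineate_recording",
    "annotations_to_frame",
]

ANNOTATION_COLUMNS = [
    "q_onset_ms",
    "r_peak_ms",
    "s1_onset_ms",
    "s1_peak_ms",
    "s2_onset_ms",
    "a2_peak_ms",
    "p2_peak_ms",
    "rr_ms",
    "valid",
]

MIN_RR_MS = 200.0  # refractory period


@dataclass
class BeatAnnotation:
    """Per-beat fiducials (ms on the shared clock) with a validity flag."""

    q_onset_ms: float
    r_peak_ms: float
    s1_onset_ms: float
    s1_peak_ms: float
    s2_onset_ms: float
    a2_peak_ms: float
    p2_peak_ms: float
    rr_ms: float
    valid: bool = True

    def __post_init__(self):
        if self.valid:
            if not (
                self.q_onset_ms
                <= self.r_peak_ms
                < self.s1_peak_ms
                < self.a2_peak_ms
                <= self.p2_peak_ms
            ):
                raise ValueError("fiducials out of order for a valid beat")
            if self.rr_ms <= MIN_RR_MS:
                raise ValueError(f"rr_ms must exceed {MIN_RR_MS} ms")


def annotations_to_frame(annotations) -> pd.DataFrame:
    """List of BeatAnnotation -> DataFrame with the canonical columns."""
    rows = [{f.name: getattr(a, f.name) for f in dc_fields(a)} for a in annotations]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample vertex of the parabola through (i-1, i, i+1)."""
    if 0 < i < y.size - 1:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom < 0:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            return i + float(np.clip(delta, -1.0, 1.0))
    return float(i)


def detect_r_peaks(filtered_ecg: np.ndarray, fs: float = ECG_FS) -> np.ndarray:
    """R-peak times (ms) by derivative-energy detection with refractory.

    Squared derivative, integrated over 80 ms, thresholded adaptively;
    each detection is refined to the local ECG maximum with parabolic
    interpolation. Flat input yields an empty array.
    """
    x = np.asarray(filtered_ecg, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return np.array([])
    d = np.gradient(x)
    energy = d * d
    w = max(int(0.08 * fs), 1)
    energy = np.convolve(energy, np.ones(w) / w, mode="same")
    thr = 0.2 * np.percentile(energy, 99.9)
    if thr <= 0:
        return np.array([])
    peaks, _ = sps.find_peaks(energy, height=thr, distance=int(MIN_RR_MS / 1000 * fs))
    times = []
    half = int(0.05 * fs)
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        i = lo + int(np.argmax(x[lo:hi]))
        times.append(_parabolic_refine(x, i) / fs * 1000.0)
    times = np.asarray(sorted(times))
    # enforce refractory after refinement
    keep = []
    for t in times:
        if not keep or t - keep[-1] > MIN_RR_MS:
            keep.append(t)
    return np.asarray(keep)


def detect_q_onset(
    filtered_ecg: np.ndarray, r_peaks_ms: np.ndarray, fs: float = ECG_FS
) -> np.ndarray:
    """Q-wave onset per beat by the tangent method (NaN when undetectable).

    Within a 120 ms pre-R window: the local baseline is the median of the
    iso-electric segment 110-60 ms before R; the steepest point of the Q
    downstroke is extrapolated back to the baseline, locating the last
    sub-threshold-slope point before the QRS deflection.
    """
    x = np.asarray(filtered_ecg, dtype=float)
    r_peaks_ms = np.asarray(r_peaks_ms, dtype=float)
    out = np.full(r_peaks_ms.size, np.nan)
    g = np.gradient(x)
    for k, r in enumerate(r_peaks_ms):
        ri = int(round(r / 1000.0 * fs))
        w0 = ri - int(0.120 * fs)
        if w0 < 0:
            continue  # window truncated by recording start -> invalid
        base = np.median(x[ri - int(0.110 * fs) : ri - int(0.060 * fs)])
        lo, hi = ri - int(0.045 * fs), ri - int(0.006 * fs)
        if hi <= lo:
            continue
        trough = lo + int(np.argmin(x[lo:hi]))
        slo = max(trough - int(0.015 * fs), w0)
        if trough <= slo:
            continue
        i = slo + int(np.argmin(g[slo : trough + 1]))
        slope = g[i] * fs / 1000.0  # amplitude per ms
        if slope >= 0:
            continue
        t_i = i / fs * 1000.0
        onset = t_i + (base - x[i]) / slope
        if w0 / fs * 1000.0 <= onset < r:
            out[k] = onset
    return out


def pcg_envelope(
    filtered_pcg: np.ndarray, fs: float = PCG_FS, smooth_ms: float = 4.0
) -> np.ndarray:
    """Smoothed energy envelope of the PCG on the shared clock."""
    return smoothed_envelope(filtered_pcg, fs, smooth_ms=smooth_ms)


def _peak_in_window(env, lo, hi, fs):
    """(time_ms, height) of the envelope maximum in sample window [lo, hi)."""
    lo = max(lo, 0)
    hi = min(hi, env.size)
    if hi - lo < 3:
        return np.nan, 0.0
    i = lo + int(np.argmax(env[lo:hi]))
    return _parabolic_refine(env, i) / fs * 1000.0, float(env[i])


def _onset_at_fraction(env, peak_i, height, lo, fs, fraction=0.10):
    """Time of the last crossing below fraction*height before the peak."""
    level = fraction * height
    i = peak_i
    while i > lo and env[i] > level:
        i -= 1
    if env[i] > level:
        return lo / fs * 1000.0
    # linear interpolation between i and i+1
    if env[i + 1] == env[i]:
        return i / fs * 1000.0
    frac = (level - env[i]) / (env[i + 1] - env[i])
    return (i + frac) / fs * 1000.0


def segment_s1_s2(
    envelope: np.ndarray, r_peaks_ms: np.ndarray, fs: float = PCG_FS
) -> pd.DataFrame:
    """Per-beat S1 and S2 onset/peak times from the energy envelope.

    S1 is the dominant envelope peak in [R, R+200 ms]; S2 in
    [R+200 ms, R+0.6*RR]. Onsets are 10 %-of-peak-height crossings. Beats
    whose S1 or S2 peak falls below 15 % of the cohort-median S1 height
    are marked invalid (missing sound), not raised.
    """
    env = np.asarray(envelope, dtype=float)
    r = np.asarray(r_peaks_ms, dtype=float)
    n = r.size
    rr = np.diff(r)
    rr = np.append(rr, np.median(rr) if rr.size else 800.0)
    rows = []
    for k in range(n):
        ri = int(round(r[k] / 1000.0 * fs))
        s1_t, s1_h = _peak_in_window(env, ri, ri + int(0.200 * fs), fs)
        s2_lo = ri + int(0.200 * fs)
        s2_hi = ri + int(0.6 * rr[k] / 1000.0 * fs)
        s2_t, s2_h = _peak_in_window(env, s2_lo, s2_hi, fs)
        rows.append([s1_t, s1_h, s2_t, s2_h, rr[k]])
    df = pd.DataFrame(rows, columns=["s1_peak_ms", "s1_height", "s2_peak_ms",
                                     "s2_height", "rr_ms"])
    ref = np.nanmedian(df["s1_height"]) if n else 0.0
    df["valid"] = (df["s1_height"] >= 0.15 * ref) & (df["s2_height"] >= 0.15 * ref)
    df["valid"] &= df["s1_peak_ms"].notna() & df["s2_peak_ms"].notna()
    # onsets at 10% of peak height
    s1_on, s2_on = [], []
    for k in range(n):
        if not df.loc[k, "valid"]:
            s1_on.append(np.nan)
            s2_on.append(np.nan)
            continue
        ri = int(round(r[k] / 1000.0 * fs))
        p1 = int(round(df.loc[k, "s1_peak_ms"] / 1000.0 * fs))
        p2 = int(round(df.loc[k, "s2_peak_ms"] / 1000.0 * fs))
        s1_on.append(_onset_at_fraction(env, p1, df.loc[k, "s1_height"], ri, fs))
        s2_on.append(
            _onset_at_fraction(env, p2, df.loc[k, "s2_height"], ri + int(0.2 * fs), fs)
        )
    df["s1_onset_ms"] = s1_on
    df["s2_onset_ms"] = s2_on
    return df


def split_s2(
    filtered_pcg: np.ndarray,
    s2_window_ms: tuple,
    fs: float = PCG_FS,
    smooth_ms: float = 0.75,
    min_prominence_frac: float = 0.06,
    min_separation_ms: float = 2.0,
):
    """A2 and P2 peak times within one S2 window.

    A finer sub-envelope (lighter smoothing than the segmentation
    envelope) is peak-picked; the two most prominent maxima, ordered in
    time, are A2 then P2. With a single resolvable peak the split is zero
    and both fiducials coincide. Returns ``(a2_ms, p2_ms)``.
    """
    lo_ms, hi_ms = s2_window_ms
    lo = max(int(round(lo_ms / 1000.0 * fs)), 0)
    hi = min(int(round(hi_ms / 1000.0 * fs)), len(filtered_pcg))
    if hi - lo < 8:
        raise ValueError("empty or degenerate S2 window")
    seg = np.asarray(filtered_pcg[lo:hi], dtype=float)
    env = smoothed_envelope(seg, fs, smooth_ms=smooth_ms)
    top = float(np.max(env))
    if top <= 0:
        raise ValueError("no signal in S2 window")
    peaks, props = sps.find_peaks(
        env,
        prominence=min_prominence_frac * top,
        distance=max(int(min_separation_ms / 1000.0 * fs), 1),
        height=0.25 * top,
    )
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(env))])
        heights = env[peaks]
    else:
        heights = props["peak_heights"]
    if peaks.size > 2:
        keep = np.sort(np.argsort(heights)[-2:])
        peaks = peaks[keep]
    times = np.array([(lo + _parabolic_refine(env, p)) / fs * 1000.0 for p in peaks])
    if times.size == 1:
        return float(times[0]), float(times[0])
    return float(times[0]), float(times[1])


def _refine_peak_fine(pcg, t_ms, fs, half_ms=15.0, smooth_ms=0.75):
    """Re-locate an envelope peak on the finer sub-envelope near ``t_ms``.

    The 4 ms segmentation envelope slightly displaces the peak of an
    asymmetric (fast-attack, slow-decay) burst; re-picking on the fine
    envelope removes that bias.
    """
    lo = max(int(round((t_ms - half_ms) / 1000.0 * fs)), 0)
    hi = min(int(round((t_ms + half_ms) / 1000.0 * fs)), len(pcg))
    if hi - lo < 5:
        return t_ms
    env = smoothed_envelope(np.asarray(pcg[lo:hi], dtype=float), fs, smooth_ms)
    i = int(np.argmax(env))
    return (lo + _parabolic_refine(env, i)) / fs * 1000.0


def delineate_recording(
    filtered_ecg: np.ndarray,
    filtered_pcg: np.ndarray,
    ecg_fs: float = ECG_FS,
    pcg_fs: float = PCG_FS,
) -> pd.DataFrame:
    """Full fiducial extraction: one row per beat, canonical columns."""
    r = detect_r_peaks(filtered_ecg, ecg_fs)
    if r.size == 0:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    q = detect_q_onset(filtered_ecg, r, ecg_fs)
    env = pcg_envelope(filtered_pcg, pcg_fs)
    seg = segment_s1_s2(env, r, pcg_fs)
    refined = [
        _refine_peak_fine(filtered_pcg, t, pcg_fs) if np.isfinite(t) else t
        for t in seg["s1_peak_ms"]
    ]
    seg["s1_peak_ms"] = refined
    a2 = np.full(r.size, np.nan)
    p2 = np.full(r.size, np.nan)
    for k in range(r.size):
        if not seg.loc[k, "valid"]:
            continue
        win = (seg.loc[k, "s2_onset_ms"] - 20.0, seg.loc[k, "s2_onset_ms"] + 120.0)
        try:
            a2[k], p2[k] = split_s2(filtered_pcg, win, pcg_fs)
        except ValueError:
            continue
    df = pd.DataFrame(
        {
            "q_onset_ms": q,
            "r_peak_ms": r,
            "s1_onset_ms": seg["s1_onset_ms"],
            "s1_peak_ms": seg["s1_peak_ms"],
            "s2_onset_ms": seg["s2_onset_ms"],
            "a2_peak_ms": a2,
            "p2_peak_ms": p2,
            "rr_ms": seg["rr_ms"],
        }
    )
    df["valid"] = (
        seg["valid"]
        & df["q_onset_ms"].notna()
        & df["a2_peak_ms"].notna()
        & (df["q_onset_ms"] < df["r_peak_ms"])
        & (df["r_peak_ms"] < df["s1_peak_ms"])
        & (df["s1_peak_ms"] < df["a2_peak_ms"])
        & (df["a2_peak_ms"] <= df["p2_peak_ms"] + 1e-9)
        & (df["rr_ms"] > MIN_RR_MS)
    )
    return df


def select_beats(
    annotations: pd.DataFrame,
    artifact_mask: ArtifactMask | None = None,
    resp_flags: np.ndarray | None = None,
    n_required: int = 30,
) -> pd.DataFrame:
    """Earliest run of ``n_required`` consecutive clean end-expiration beats.

    A beat qualifies when it is valid, its span avoids artifact windows,
    and it is end-expiration-flagged. If no run of ``n_required`` exists,
    the longest qualifying run is returned with a warning; zero
    qualifying beats raises (subject excluded).
    """
    df = annotations.reset_index(drop=True)
    ok = df["valid"].to_numpy(dtype=bool).copy()
    if resp_flags is not None:
        ok &= np.asarray(resp_flags, dtype=bool)
    if artifact_mask is not None:
        for k in range(len(df)):
            if not ok[k]:
                continue
            start = df.loc[k, "q_onset_ms"] - 10.0
            end = df.loc[k, "p2_peak_ms"] + 50.0
            if np.isnan(start) or np.isnan(end):
                ok[k] = False
            elif not artifact_mask.is_clean(start, end):
                ok[k] = False
    if not ok.any():
        raise ValueError("no qualifying beats; subject excluded")
    # enumerate runs
    runs = []
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    for a, b in runs:
        if b - a >= n_required:
            return df.iloc[a : a + n_required]
    a, b = max(runs, key=lambda r: r[1] - r[0])
    warnings.warn(
        f"only {b - a} consecutive qualifying beats available "
        f"(requested {n_required}); returning the longest run",
        stacklevel=2,
    )
    return df.iloc[a:b]
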