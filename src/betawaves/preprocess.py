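"""LFP preprocessing: missing-electrode interpolation, band-pass + Hilbert
amplitude/phase extraction, beta-burst detection, and spectral / spatial
summaries.

Array movies are ``[nx, ny, nt]`` with frame-rate and electrode-pitch
metadata; this applies equally to simulated proxy-LFP and to real
multielectrode recordings converted to the same layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["PhaseMovie", "BurstEvent", "interpolate_missing",
           "analytic_signal", "detect_bursts", "detect_bursts_movie",
           "spectral_summary", "spatial_correlation"]

EDGE_MS = 200.0  # Hilbert edge-artifact margin excluded from statistics


@dataclass
class PhaseMovie:
    """Instantaneous amplitude and phase maps of a band-passed LFP movie."""

    amplitude: np.ndarray          # [nx, ny, nt], a.u. (z-scored input)
    phase: np.ndarray              # [nx, ny, nt], radians in (-pi, pi]
    frame_rate_hz: float
    pitch_um: float = 400.0
    band_hz: tuple = (13.0, 30.0)
    valid_mask: np.ndarray | None = None   # [nx, ny] True where electrode ok
    filtered: np.ndarray | None = None     # band-passed z-scored LFP
    edge_ms: float = EDGE_MS

    def __post_init__(self):
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude/phase shape mismatch")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.amplitude.shape[:2], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.amplitude.shape[2]

    @property
    def edge_frames(self) -> int:
        return int(round(self.edge_ms * self.frame_rate_hz / 1000.0))

    def interior(self) -> slice:
        """Frame slice with Hilbert edge artifacts trimmed."""
        e = self.edge_frames
        return slice(e, self.n_frames - e if e else self.n_frames)


@dataclass
class BurstEvent:
    electrode: tuple | None
    onset_ms: float
    offset_ms: float
    duration_ms: float
    mean_amplitude: float


def interpolate_missing(movie: np.ndarray, valid_mask: np.ndarray) -> np.ndarray:
    """Replace missing-electrode traces by the mean of their valid
    4-neighbors (applied to the raw movie, before any filtering).

    Raises if a missing electrode has no valid neighbor.
    """
    movie = np.asarray(movie, dtype=float)
    valid = np.asarray(valid_mask, dtype=bool)
    if valid.all():
        return movie.copy()
    out = movie.copy()
    nx, ny = valid.shape
    for x, y in zip(*np.nonzero(~valid)):
        acc, n = 0.0, 0
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            xx, yy = x + dx, y + dy
            if 0 <= xx < nx and 0 <= yy < ny and valid[xx, yy]:
                acc = acc + movie[xx, yy]
                n += 1
        if n == 0:
            raise ValueError(f"missing electrode {(x, y)} has no valid "
                             "4-neighbor to interpolate from")
        out[x, y] = acc / n
    return out


def analytic_signal(lfp: np.ndarray, frame_rate_hz: float, *,
                    band_hz=(13.0, 30.0), order=3, pitch_um=400.0,
                    valid_mask=None, edge_ms=EDGE_MS) -> PhaseMovie:
    """Band-pass (zero-phase Butterworth), z-score, Hilbert-transform.

    Each channel is filtered forward-backward with a third-order Butterworth
    band-pass, z-score normalized, and Hilbert transformed to instantaneous
    amplitude and phase.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim == 2:  # single trace(s): promote to [1, n_ch, nt]-like handling
        lfp = lfp[None]
    if frame_rate_hz <= 2 * band_hz[1]:
        raise ValueError("frame rate must exceed twice the band upper edge")
    nt = lfp.shape[-1]
    min_len = int(3 * frame_rate_hz / band_hz[0])
    if nt < min_len:
        raise ValueError(f"trace too short for stable filtering: {nt} < {min_len}")
    if valid_mask is not None:
        lfp = interpolate_missing(lfp, valid_mask)
    sos = signal.butter(order, band_hz, btype="bandpass",
                        fs=frame_rate_hz, output="sos")
    filt = signal.sosfiltfilt(sos, lfp, axis=-1)
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (filt - filt.mean(axis=-1, keepdims=True)) / sd
    analytic = signal.hilbert(z, axis=-1)
    return PhaseMovie(
        amplitude=np.abs(analytic), phase=np.angle(analytic),
        frame_rate_hz=frame_rate_hz, pitch_um=pitch_um, band_hz=tuple(band_hz),
        valid_mask=valid_mask, filtered=z, edge_ms=edge_ms,
    )


def detect_bursts(amplitude: np.ndarray, frame_rate_hz: float, *,
                  percentile=75.0, threshold=None,
                  electrode=None) -> list[BurstEvent]:
    """Beta bursts of one amplitude trace: maximal runs strictly above the
    trace's own amplitude percentile (default 75th).

    An onset is a time point at which the amplitude exceeds the threshold;
    termination is the earliest following sub-threshold point.  A run still
    open at the end of the trace is closed there.
    """
    a = np.asarray(amplitude, dtype=float)
    if threshold is None:
        if np.ptp(a) == 0:
            warnings.warn("constant amplitude trace: no bursts detectable")
            return []
        threshold = np.percentile(a, percentile)  # linear-interpolation quantile
    above = a > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    onsets = list(np.nonzero(edges == 1)[0] + 1)
    offsets = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(len(a))
    ms = 1000.0 / frame_rate_hz
    return [
        BurstEvent(electrode=electrode, onset_ms=i0 * ms, offset_ms=i1 * ms,
                   duration_ms=(i1 - i0) * ms,
                   mean_amplitude=float(a[i0:i1].mean()))
        for i0, i1 in zip(onsets, offsets)
    ]


def detect_bursts_movie(movie: PhaseMovie, *, percentile=75.0) -> pd.DataFrame:
    """Per-electrode burst table of a phase movie (edge frames excluded;
    threshold computed per electrode)."""
    sl = movie.interior()
    t0 = sl.start * 1000.0 / movie.frame_rate_hz
    rows = []
    nx, ny = movie.amplitude.shape[:2]
    for x in range(nx):
        for y in range(ny):
            if not movie.valid_mask[x, y]:
                continue
            for ev in detect_bursts(movie.amplitude[x, y, sl],
                                    movie.frame_rate_hz,
                                    percentile=percentile, electrode=(x, y)):
                rows.append({
                    "x": x, "y": y, "onset_ms": ev.onset_ms + t0,
                    "offset_ms": ev.offset_ms + t0,
                    "duration_ms": ev.duration_ms,
                    "mean_amplitude": ev.mean_amplitude,
                })
    return pd.DataFrame(rows, columns=["x", "y", "onset_ms", "offset_ms",
                                       "duration_ms", "mean_amplitude"])


def spectral_summary(lfp: np.ndarray, frame_rate_hz: float, *,
                     band_hz=(13.0, 30.0), welch_window_s=1.0,
                     spectrogram=False) -> dict:
    """Welch power spectra of the channel traces plus the peak frequency in
    the requested band.

    ``lfp`` is [..., nt]; leading axes are treated as channels/trials.
    Returns freqs, mean and sd of the per-channel spectra, per-channel peak
    frequencies, and optionally a short-time Fourier spectrogram of the first
    channel (256 ms window, 90% overlap).
    """
    lfp = np.asarray(lfp, dtype=float)
    traces = lfp.reshape(-1, lfp.shape[-1])
    nper = min(int(welch_window_s * frame_rate_hz), traces.shape[-1])
    freqs, psd = signal.welch(traces, fs=frame_rate_hz, window="hann",
                              nperseg=nper, noverlap=nper // 2, axis=-1)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    peaks = freqs[in_band][np.argmax(psd[:, in_band], axis=1)]
    out = {
        "freqs_hz": freqs,
        "psd_mean": psd.mean(axis=0),
        "psd_sd": psd.std(axis=0),
        "psd": psd,
        "peak_hz": peaks,
        "peak_hz_mean": float(peaks.mean()),
    }
    if spectrogram:
        nseg = min(int(0.256 * frame_rate_hz), traces.shape[-1])
        f_s, t_s, sxx = signal.spectrogram(
            traces[0], fs=frame_rate_hz, window="hann", nperseg=nseg,
            noverlap=int(0.9 * nseg))
        out["spectrogram"] = {"freqs_hz": f_s, "t_s": t_s, "sxx": sxx}
    return out


def spatial_correlation(movie: np.ndarray, frame_rate_hz: float, *,
                        band_hz=(13.0, 30.0), prefiltered=False,
                        valid_mask=None):
    """Mean equal-time Pearson correlation of band-passed traces versus
    electrode distance (pitch units).

    Returns ``(distances, mean_correlation, pair_counts)`` with one entry per
    distinct pair distance on the grid.
    """
    movie = np.asarray(movie, dtype=float)
    nx, ny, nt = movie.shape
    if nx * ny < 2:
        raise ValueError("need at least two channels")
    if prefiltered:
        z = movie.reshape(-1, nt)
    else:
        pm = analytic_signal(movie, frame_rate_hz, band_hz=band_hz,
                             valid_mask=valid_mask)
        z = pm.filtered.reshape(-1, nt)
    corr = np.corrcoef(z)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pos = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    iu = np.triu_indices(nx * ny, k=0)
    d = np.round(dist[iu], 6)
    c = corr[iu]
    uniq = np.unique(d)
    mean_c = np.array([c[d == u].mean() for u in uniq])
    counts = np.array([(d == u).sum() for u in uniq])
    return uniq, mean_c, counts
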