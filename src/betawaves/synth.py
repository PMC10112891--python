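"""Ground-truth-labeled surrogate array data.

Generators for (i) phase-pattern movies with known planar / radial /
synchronized / random segments on a 10x10, 400 um-pitch grid, (ii) bursty
amplitude traces with known burst intervals, and (iii) single-channel
Gaussian traces with a prescribed power spectrum.  Every generator returns
its exact ground truth next to the data, so the analysis stages can be
tested without running network simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import PhaseMovie
from .waves import _CODE

__all__ = ["PatternSpec", "make_pattern_movie", "make_burst_trace",
           "make_linear_surrogate"]


@dataclass
class PatternSegment:
    kind: str                  # planar | radial | synchronized | random
    duration_ms: float
    freq_hz: float = 20.0
    wavevector: tuple = (0.5, 0.0)   # rad per grid unit (planar)
    source: tuple | None = None      # radial source position (grid units)
    kappa: float = 0.5               # radial wavenumber, rad per grid unit
    phase_noise_sd: float = 0.0      # rad, i.i.d. per electrode and frame
    amplitude_noise_sd: float = 0.0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")
        if self.freq_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.phase_noise_sd < 0 or self.amplitude_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if self.kind == "planar" and np.max(np.abs(self.wavevector)) > np.pi:
            raise ValueError("wavevector exceeds pi rad per grid unit "
                             "(spatial aliasing)")


@dataclass
class PatternSpec:
    segments: list
    grid: tuple = (10, 10)
    frame_rate_hz: float = 1000.0
    pitch_um: float = 400.0
    seed: int = 0
    random_phase_tau_ms: float = 20.0  # OU smoothing of 'random' phases

    def __post_init__(self):
        self.segments = [
            s if isinstance(s, PatternSegment) else PatternSegment(**s)
            for s in self.segments
        ]
        nyq = self.frame_rate_hz / 2
        for s in self.segments:
            if s.freq_hz >= nyq:
                raise ValueError("segment frequency at or above Nyquist")


def make_pattern_movie(spec: PatternSpec):
    """Build a phase movie from the segment list.

    Phases: planar Phi = 2 pi f t - k.x, radial Phi = 2 pi f t - kappa
    |x - x0|, synchronized Phi = 2 pi f t, random = temporally smoothed
    i.i.d. phases per electrode; all plus optional i.i.d. phase noise.  The
    band-limited LFP is reconstructed as A cos Phi.

    Returns ``(PhaseMovie, labels, truth)`` where ``labels`` holds the
    ground-truth frame labels (codes of waves.LABELS) and ``truth`` is a
    per-segment table with onset/offset frames and the closed-form wave
    speed where defined.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny = spec.grid
    fr = spec.frame_rate_hz
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    frames = []
    labels = []
    rows = []
    carrier = 0.0  # running oscillation phase, keeps continuity
    start = 0
    for seg in spec.segments:
        nf = int(round(seg.duration_ms * fr / 1000.0))
        t = np.arange(nf)
        osc = carrier + 2 * np.pi * seg.freq_hz * (t + 1) / fr
        carrier = osc[-1] if nf else carrier
        if seg.kind == "planar":
            kx, ky = seg.wavevector
            spatial = -(kx * xs + ky * ys)
            phi = spatial[..., None] + osc[None, None, :]
            speed = (2 * np.pi * seg.freq_hz / np.hypot(kx, ky)
                     * spec.pitch_um * 1e-4) if np.hypot(kx, ky) else np.nan
        elif seg.kind == "radial":
            x0, y0 = seg.source if seg.source is not None \
                else ((nx - 1) / 2, (ny - 1) / 2)
            spatial = -seg.kappa * np.hypot(xs - x0, ys - y0)
            phi = spatial[..., None] + osc[None, None, :]
            speed = (2 * np.pi * seg.freq_hz / seg.kappa
                     * spec.pitch_um * 1e-4) if seg.kappa else np.nan
        elif seg.kind == "synchronized":
            phi = np.broadcast_to(osc, (nx, ny, nf)).copy()
            speed = np.nan
        elif seg.kind == "random":
            # complex OU per electrode; its angle is a temporally smooth,
            # marginally uniform phase field
            e = np.exp(-1000.0 / (fr * spec.random_phase_tau_ms))
            sd = np.sqrt(1 - e * e)
            z = rng.normal(size=(nx, ny, 2)) @ np.array([1.0, 1j])
            phi = np.empty((nx, ny, nf))
            for k in range(nf):
                z = z * e + sd * (rng.normal(size=(nx, ny))
                                  + 1j * rng.normal(size=(nx, ny)))
                phi[..., k] = np.angle(z)
            speed = np.nan
        else:
            raise ValueError(f"unknown pattern kind {seg.kind!r}")
        if seg.phase_noise_sd:
            phi = phi + rng.normal(0.0, seg.phase_noise_sd, size=phi.shape)
        frames.append(phi)
        labels.append(np.full(nf, _CODE[seg.kind], dtype=np.int64))
        rows.append({"kind": seg.kind, "start_frame": start,
                     "stop_frame": start + nf, "freq_hz": seg.freq_hz,
                     "speed_cm_s": speed})
        start += nf
    phase = (np.concatenate(frames, axis=2) + np.pi) % (2 * np.pi) - np.pi
    labels = np.concatenate(labels)
    amp = np.ones_like(phase)
    noise_sds = [s.amplitude_noise_sd for s in spec.segments]
    if any(noise_sds):
        pos = 0
        for seg, row in zip(spec.segments, rows):
            nf = row["stop_frame"] - row["start_frame"]
            if seg.amplitude_noise_sd:
                amp[..., pos:pos + nf] += rng.normal(
                    0.0, seg.amplitude_noise_sd, size=(nx, ny, nf))
            pos += nf
        amp = np.clip(amp, 0.05, None)
    movie = PhaseMovie(amplitude=amp, phase=phase, frame_rate_hz=fr,
                       pitch_um=spec.pitch_um, edge_ms=0.0)
    movie.lfp = amp * np.cos(phase)
    return movie, labels, pd.DataFrame(rows)


def make_burst_trace(onsets_ms, durations_ms, *, total_ms=None,
                     frame_rate_hz=1000.0, snr=10.0, baseline_sd=1.0,
                     seed=0):
    """Amplitude trace with rectangular supra-threshold bursts at known
    times over a noisy baseline.

    Returns ``(trace, events)``; ``events`` is a table of the true burst
    intervals.  Overlapping bursts raise.
    """
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    durations_ms = np.broadcast_to(
        np.asarray(durations_ms, dtype=float), onsets_ms.shape).copy()
    if np.any(durations_ms <= 0):
        raise ValueError("burst durations must be positive")
    order = np.argsort(onsets_ms)
    onsets_ms, durations_ms = onsets_ms[order], durations_ms[order]
    ends = onsets_ms + durations_ms
    if np.any(onsets_ms[1:] < ends[:-1]):
        raise ValueError("bursts overlap")
    if total_ms is None:
        total_ms = (ends.max() if len(ends) else 0.0) + 500.0
    n = int(round(total_ms * frame_rate_hz / 1000.0))
    rng = np.random.default_rng(seed)
    # smooth positive baseline (Rayleigh-like envelope of band noise)
    w = rng.normal(size=n) + 1j * rng.normal(size=n)
    kernel = np.exp(-np.arange(0, 5 * 20) / 20.0)
    kernel /= np.sqrt((kernel**2).sum())
    smooth = np.convolve(w, kernel, mode="same")
    trace = baseline_sd * np.abs(smooth) / np.sqrt(2)
    rows = []
    for t0, dur in zip(onsets_ms, durations_ms):
        i0 = int(round(t0 * frame_rate_hz / 1000.0))
        i1 = int(round((t0 + dur) * frame_rate_hz / 1000.0))
        if i1 > n:
            raise ValueError("burst extends past the trace end")
        trace[i0:i1] += snr * baseline_sd
        rows.append({"onset_ms": i0 * 1000.0 / frame_rate_hz,
                     "offset_ms": i1 * 1000.0 / frame_rate_hz,
                     "duration_ms": (i1 - i0) * 1000.0 / frame_rate_hz})
    return trace, pd.DataFrame(rows, columns=["onset_ms", "offset_ms",
                                              "duration_ms"])


def make_linear_surrogate(freqs_hz, psd_one_sided, duration_ms, *,
                          frame_rate_hz=1000.0, seed=0):
    """Stationary Gaussian trace with the prescribed one-sided power
    spectral density (units^2/Hz), via spectral factorization in the
    frequency domain.

    The PSD is interpolated onto the FFT grid; a zero spectrum yields a zero
    trace.
    """
    psd = np.asarray(psd_one_sided, dtype=float)
    if np.any(psd < 0):
        raise ValueError("spectrum must be nonnegative")
    n = int(round(duration_ms * frame_rate_hz / 1000.0))
    f_grid = np.fft.rfftfreq(n, d=1.0 / frame_rate_hz)
    s = np.interp(f_grid, np.asarray(freqs_hz, dtype=float), psd,
                  left=psd[0], right=psd[-1])
    rng = np.random.default_rng(seed)
    amp = np.sqrt(s * frame_rate_hz * n / 4.0)
    x = amp * (rng.normal(size=len(f_grid)) + 1j * rng.normal(size=len(f_grid)))
    x[0] = np.sqrt(s[0] * frame_rate_hz * n / 2.0) * rng.normal()
    if n % 2 == 0:
        x[-1] = np.sqrt(s[-1] * frame_rate_hz * n / 2.0) * rng.normal()
    return np.fft.irfft(x, n=n)
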