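"""Signal analysis: slow/fast decomposition, zero-crossing rate by phase,
Welch spectra, envelopes and synchrony measures.

All measures operate on uniformly sampled series.  The node output is split
at a cut-off (15 Hz by default) into a slow oscillation (SO, low-pass) and a
fast oscillation (FO, high-pass), both zero-phase filtered and z-scored.
Frequency modulation is indexed by the zero-crossing rate of the FO within
each positive/negative phase of the SO; amplitude modulation by the
correlation of the FO analytic-signal envelope with the SO.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "DecomposedSignal", "PhaseSegment", "SpectrumEstimate", "SpectralPeak",
    "decompose", "zero_crossing_rate", "phase_segments", "zcr_by_phase",
    "welch_psd", "spectral_peak", "envelope", "plv",
]

DEFAULT_CUTOFF_HZ = 15.0
#: FO variance below this fraction of the input variance marks a stop-band
#: ("degenerate") fast component that must not be z-scored.
DEGENERATE_FO_RATIO = 1e-4
#: SO half-phases shorter than this are merged into their neighbours.
MIN_SEGMENT_DURATION_S = 0.05


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        raise ValueError("cannot z-score a constant signal")
    return (x - np.mean(x)) / sd


@dataclass
class DecomposedSignal:
    """Slow (SO) and fast (FO) components of one node output, z-scored."""

    SO: np.ndarray
    FO: np.ndarray
    fs: float
    fc: float
    fo_degenerate: bool = False  # True when FO power was numerically nil

    def __post_init__(self) -> None:
        if len(self.SO) != len(self.FO):
            raise ValueError("SO and FO must have equal length")


@dataclass(frozen=True)
class PhaseSegment:
    """One half-phase (sign run) of the SO signal, half-open [start, end)."""

    sign: int  # +1 for SO >= 0, -1 for SO < 0
    start_index: int
    end_index: int
    duration: float  # seconds

    def __len__(self) -> int:
        return self.end_index - self.start_index


@dataclass
class SpectrumEstimate:
    freqs: np.ndarray
    power: np.ndarray
    fs: float
    window_length: int
    overlap_fraction: float


@dataclass(frozen=True)
class SpectralPeak:
    freq: float
    power: float
    fwhm: float


def decompose(x: Sequence[float], fs: float, fc: float = DEFAULT_CUTOFF_HZ,
              order: int = 4) -> DecomposedSignal:
    """Split ``x`` into SO (low-pass) and FO (high-pass) at ``fc``.

    Zero-phase (forward-backward) Butterworth filtering of the given order,
    then z-scoring.  If the high-pass residue carries less than
    ``DEGENERATE_FO_RATIO`` of the input variance, the FO is flagged
    degenerate and returned un-normalized instead of amplifying numerical
    residue to unit variance.
    """
    x = np.asarray(x, dtype=np.float64)
    min_len = int(np.ceil(10 * fs / fc))
    if len(x) < min_len:
        raise ValueError(
            f"input too short: need >= {min_len} samples (10 cycles at "
            f"{fc} Hz), got {len(x)}")
    sos_lo = sps.butter(order, fc, btype="low", fs=fs, output="sos")
    sos_hi = sps.butter(order, fc, btype="high", fs=fs, output="sos")
    so_raw = sps.sosfiltfilt(sos_lo, x)
    fo_raw = sps.sosfiltfilt(sos_hi, x)
    var_in = np.var(x)
    degenerate = bool(var_in > 0
                      and np.var(fo_raw) < DEGENERATE_FO_RATIO * var_in)
    return DecomposedSignal(
        SO=_zscore(so_raw),
        FO=fo_raw - np.mean(fo_raw) if degenerate else _zscore(fo_raw),
        fs=fs, fc=fc, fo_degenerate=degenerate)


def zero_crossing_rate(fo_segment: Sequence[float], fs: float) -> float:
    """Zero-crossing rate (1/s) over a segment of duration T:

    ``(1 / 2T) * #{t : FO(t) * FO(t+1) < 0}``.

    Strict inequality: a sample landing exactly on zero contributes no
    crossing.  For a pure sine observed over an integer number of
    half-periods this equals its frequency.
    """
    x = np.asarray(fo_segment, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("empty segment")
    T = len(x) / fs
    crossings = int(np.count_nonzero(x[:-1] * x[1:] < 0))
    return crossings / (2.0 * T)


def phase_segments(SO: Sequence[float], fs: float,
                   min_duration: float = MIN_SEGMENT_DURATION_S
                   ) -> List[PhaseSegment]:
    """Tile the SO series into alternating sign runs (SO >= 0 vs SO < 0).

    Runs shorter than ``min_duration`` (spurious micro-segments from noise
    near zero crossings) are merged into their neighbours, shortest first.
    """
    so = np.asarray(SO, dtype=np.float64)
    if len(so) == 0:
        return []
    signs = np.where(so >= 0, 1, -1)
    # run-length boundaries
    change = np.flatnonzero(signs[1:] != signs[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(so)]))
    runs = [(int(signs[s]), int(s), int(e)) for s, e in zip(starts, ends)]

    min_len = int(round(min_duration * fs))
    while len(runs) > 1:
        lengths = [e - s for _, s, e in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_len:
            break
        # merge run i into a neighbour; the merged stretch takes the
        # neighbour's sign, and equal-signed runs are then coalesced
        sign, s, e = runs.pop(i)
        if i > 0:
            runs[i - 1] = (runs[i - 1][0], runs[i - 1][1], e)
        else:
            runs[0] = (runs[0][0], s, runs[0][2])
        # coalesce adjacent equal signs
        j = 0
        while j < len(runs) - 1:
            if runs[j][0] == runs[j + 1][0]:
                runs[j] = (runs[j][0], runs[j][1], runs[j + 1][2])
                runs.pop(j + 1)
            else:
                j += 1
    return [PhaseSegment(sign=sg, start_index=s, end_index=e,
                         duration=(e - s) / fs)
            for sg, s, e in runs]


def zcr_by_phase(dec: DecomposedSignal,
                 min_segments: int = 5,
                 min_duration: float = MIN_SEGMENT_DURATION_S
                 ) -> Tuple[float, float]:
    """Mean FO zero-crossing rate over positive vs negative SO phases.

    Returns ``(zcr_positive, zcr_negative)``; each is the per-segment zcr
    averaged within its sign class.  Requires at least ``min_segments``
    segments of each sign.
    """
    segs = phase_segments(dec.SO, dec.fs, min_duration=min_duration)
    pos = [s for s in segs if s.sign > 0]
    neg = [s for s in segs if s.sign < 0]
    if len(pos) < min_segments or len(neg) < min_segments:
        raise ValueError(
            f"need >= {min_segments} segments of each sign, got "
            f"{len(pos)} positive / {len(neg)} negative")
    zp = float(np.mean([zero_crossing_rate(
        dec.FO[s.start_index:s.end_index], dec.fs) for s in pos]))
    zn = float(np.mean([zero_crossing_rate(
        dec.FO[s.start_index:s.end_index], dec.fs) for s in neg]))
    return zp, zn


def welch_psd(x: Sequence[float], fs: float, window_length: int = 16384,
              overlap: float = 0.25) -> SpectrumEstimate:
    """Averaged Hanning-windowed periodogram (Welch) with the given
    fractional overlap between successive windows."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < window_length:
        raise ValueError(
            f"signal shorter ({len(x)}) than window ({window_length})")
    freqs, power = sps.welch(
        x, fs=fs, window="hann", nperseg=window_length,
        noverlap=int(round(overlap * window_length)), detrend="constant")
    return SpectrumEstimate(freqs=freqs, power=power, fs=fs,
                            window_length=window_length,
                            overlap_fraction=overlap)


def spectral_peak(spec: SpectrumEstimate, band: Tuple[float, float],
                  min_prominence_ratio: float = 5.0) -> Optional[SpectralPeak]:
    """Dominant spectral peak inside ``band`` with its FWHM, or ``None``.

    The candidate is the arg-max within the band; it counts as a peak only
    when its power exceeds ``min_prominence_ratio`` times the median in-band
    power (otherwise the band is considered peak-free, e.g. flat noise).
    FWHM is measured at half the peak height above the median baseline, with
    linear interpolation between bins; it may extend past the band edges.
    """
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi <= spec.fs / 2 + 1e-9):
        raise ValueError(f"band {band} outside [0, fs/2]")
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not np.any(mask):
        raise ValueError(f"no frequency bins in band {band}")
    f_band = spec.freqs[mask]
    p_band = spec.power[mask]
    baseline = float(np.median(p_band))
    i = int(np.argmax(p_band))
    peak_p = float(p_band[i])
    if baseline > 0 and peak_p < min_prominence_ratio * baseline:
        return None
    if peak_p <= 0:
        return None
    peak_f = float(f_band[i])

    half = baseline + 0.5 * (peak_p - baseline)
    # walk outwards over the full spectrum for the half-height crossings
    gidx = int(np.flatnonzero(mask)[i])
    freqs, power = spec.freqs, spec.power

    def _cross(direction: int) -> float:
        j = gidx
        while 0 < j < len(power) - 1:
            k = j + direction
            if power[k] < half:
                # linear interpolation between bins j and k
                frac = (power[j] - half) / (power[j] - power[k])
                return float(freqs[j] + frac * (freqs[k] - freqs[j]))
            j = k
        return float(freqs[j])

    fwhm = _cross(+1) - _cross(-1)
    return SpectralPeak(freq=peak_f, power=peak_p, fwhm=float(fwhm))


def envelope(FO: Sequence[float], fs: float,
             fc: float = DEFAULT_CUTOFF_HZ, order: int = 4) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal, low-pass
    smoothed (zero-phase) below ``fc``."""
    fo = np.asarray(FO, dtype=np.float64)
    env = np.abs(sps.hilbert(fo))
    sos = sps.butter(order, fc, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, env)


def plv(x: Sequence[float], y: Sequence[float]) -> float:
    """Phase-locking value in [0, 1]: magnitude of the mean unit phasor of
    the instantaneous (Hilbert) phase difference."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    phx = np.angle(sps.hilbert(x))
    phy = np.angle(sps.hilbert(y))
    return float(np.abs(np.mean(np.exp(1j * (phx - phy)))))
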