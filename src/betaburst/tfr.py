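"""Time-frequency decomposition and spectrogram smoothing.

Beta bursts are detected as local maxima of a smoothed Morlet spectrogram.
This module computes that spectrogram: a wavelet decomposition at 1-Hz
intervals from 1 to 40 Hz using 5-cycle Morlet wavelets, followed by a
two-dimensional Gaussian filter with standard deviations of 1 Hz along the
frequency axis and 6 ms along the time axis.

The spectrogram time axis is kept at the signal sampling rate (the 6-ms
smoothing SD implies fine temporal resolution; no decimation). Samples
within half a wavelet support of either recording edge are flagged
unreliable per frequency and excluded from downstream peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import morlet as _mne_morlet
from mne.time_frequency import tfr_array_morlet

__all__ = ["ContinuousSignal", "Spectrogram", "morlet_tfr", "smooth_spectrogram"]

DEFAULT_FREQS = np.arange(1.0, 41.0)  # 1..40 Hz at 1-Hz intervals
DEFAULT_N_CYCLES = 5


@dataclass
class ContinuousSignal:
    """A uniformly sampled single-channel neural time course.

    Parameters
    ----------
    samples : ndarray
        Real-valued signal in arbitrary physical units (typically uV).
    fs : float
        Sampling rate in Hz, > 0.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class Spectrogram:
    """Time x frequency power with explicit axes.

    ``power`` is ``[n_freqs, n_times]`` and nonnegative; ``edge_samples``
    gives, per frequency, the number of samples at each end that lie within
    half a wavelet length of the recording edge (unreliable for detection).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    smoothed: bool = False
    edge_samples: np.ndarray = field(default=None)  # per-frequency edge margin

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError(
                f"power shape {self.power.shape} does not match "
                f"({self.freqs.size} freqs, {self.times.size} times)"
            )
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.edge_samples is None:
            self.edge_samples = np.zeros(self.freqs.size, dtype=int)

    def reliable_mask(self) -> np.ndarray:
        """Boolean [n_freqs, n_times] mask of samples outside edge margins."""
        n_t = self.times.size
        mask = np.ones((self.freqs.size, n_t), dtype=bool)
        for i, m in enumerate(self.edge_samples):
            m = int(min(m, n_t))
            if m > 0:
                mask[i, :m] = False
                mask[i, n_t - m:] = False
        return mask


def _wavelet_half_lengths(fs, freqs, n_cycles):
    """Half-support (in samples) of each Morlet wavelet at the given fs."""
    Ws = _mne_morlet(fs, np.atleast_1d(freqs), n_cycles=n_cycles, zero_mean=True)
    return np.array([w.size // 2 for w in Ws], dtype=int)


def morlet_tfr(signal: ContinuousSignal, freqs=None, n_cycles: int = DEFAULT_N_CYCLES) -> Spectrogram:
    """Morlet-wavelet power spectrogram of a continuous signal.

    Power is the squared magnitude of the complex wavelet transform with
    unit-energy (L2) wavelets. Defaults follow the analysis convention:
    frequencies 1..40 Hz at 1-Hz intervals, 5-cycle wavelets. Downstream
    burst selection thresholds on the power / row-median ratio, so results
    are invariant to the wavelet normalisation.

    Raises
    ------
    ValueError
        If any frequency reaches the Nyquist rate or the signal is shorter
        than the longest wavelet.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    nyq = signal.fs / 2.0
    if np.any(freqs >= nyq):
        bad = freqs[freqs >= nyq]
        raise ValueError(
            f"frequencies {bad} reach or exceed the Nyquist rate {nyq} Hz "
            f"(fs = {signal.fs} Hz)"
        )
    half = _wavelet_half_lengths(signal.fs, freqs, n_cycles)
    if signal.samples.size <= 2 * half.max():
        raise ValueError(
            f"signal of {signal.samples.size} samples is shorter than the "
            f"longest wavelet ({2 * half.max() + 1} samples at {freqs[np.argmax(half)]} Hz)"
        )
    data = signal.samples[np.newaxis, np.newaxis, :]
    power = tfr_array_morlet(
        data, sfreq=signal.fs, freqs=freqs, n_cycles=n_cycles,
        zero_mean=True, output="power",
    )[0, 0]
    return Spectrogram(
        power=power, freqs=freqs, times=signal.times, fs=signal.fs,
        smoothed=False, edge_samples=half,
    )


def smooth_spectrogram(spec: Spectrogram, sd_f: float = 1.0, sd_t: float = 0.006) -> Spectrogram:
    """Smooth a raw spectrogram with a 2-D Gaussian filter.

    Standard deviations default to 1 Hz along the frequency axis and 6 ms
    along the time axis, expressed in bin units as ``sd_f / freq_step`` and
    ``sd_t * fs``. The kernel is truncated at +/-4 SD and normalised to
    unit sum; boundaries are handled by reflect padding.
    """
    from scipy.ndimage import gaussian_filter

    if spec.smoothed:
        raise ValueError("spectrogram is already smoothed")
    if not (sd_f > 0 and sd_t > 0):
        raise ValueError("smoothing SDs must be > 0")
    freq_step = float(np.median(np.diff(spec.freqs))) if spec.freqs.size > 1 else 1.0
    sigma = (sd_f / freq_step, sd_t * spec.fs)
    sm = gaussian_filter(spec.power, sigma=sigma, mode="reflect", truncate=4.0)
    return Spectrogram(
        power=sm, freqs=spec.freqs, times=spec.times, fs=spec.fs,
        smoothed=True, edge_samples=spec.edge_samples.copy(),
    )
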