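"""Transient beta-burst detection on smoothed spectrograms.

A burst is a cell of the smoothed time-frequency power matrix that is a
strict local maximum within its 5x5 neighbourhood (found by comparing
against a grey dilation whose 5x5 structuring element is all ones with a
zero centre) and whose power is at least ``threshold_factor`` (default 6)
times the median power across all time points at that frequency. Retained
peak times serve as point-event times for rate statistics and as impulse
regressors in the BOLD GLM.

Because both the dilation comparison and the median-ratio threshold are
homogeneous in signal scale, detection is invariant to multiplying the
input signal by any positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter

from .tfr import ContinuousSignal, Spectrogram, morlet_tfr, smooth_spectrogram

__all__ = [
    "BurstEvent",
    "DetectionConfig",
    "dilate",
    "find_peaks",
    "threshold_peaks",
    "detect_bursts",
    "surrogate_events",
]


@dataclass(frozen=True)
class BurstEvent:
    """One detected burst: peak time (s), frequency (Hz), power and
    power / row-median ratio."""

    time: float
    freq: float
    peak_power: float
    median_ratio: float


def _default_footprint():
    fp = np.ones((5, 5), dtype=bool)
    fp[2, 2] = False
    return fp


@dataclass
class DetectionConfig:
    """Burst-detection parameters.

    beta_band defaults to the conventional 13-30 Hz; threshold_factor is
    the power / row-median ratio a peak must reach (default 6). The
    structuring element is 5x5 ones with a zero centre, so peak candidacy
    requires strict superiority over all in-bounds neighbours.
    """

    beta_band: tuple = (13.0, 30.0)
    threshold_factor: float = 6.0
    freqs: np.ndarray = None
    n_cycles: int = 5
    sd_f: float = 1.0
    sd_t: float = 0.006
    min_separation: float = 0.0
    median_on_smoothed: bool = True

    def __post_init__(self):
        lo, hi = self.beta_band
        if not (lo < hi):
            raise ValueError(f"beta_band must be an interval, got {self.beta_band}")
        if not self.threshold_factor > 0:
            raise ValueError("threshold_factor must be > 0")


def dilate(power: np.ndarray) -> np.ndarray:
    """Grey dilation with a 5x5 structuring element whose centre is zero.

    Each output cell is the maximum of the input over the 5x5 neighbourhood
    *excluding* the centre cell; out-of-bounds neighbours are ignored.
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 2 or power.size == 0:
        raise ValueError("power must be a non-empty 2-D matrix")
    return maximum_filter(
        power, footprint=_default_footprint(), mode="constant", cval=-np.inf
    )


def find_peaks(smoothed: Spectrogram):
    """Candidate peaks of a smoothed spectrogram.

    A cell is a peak iff its power strictly exceeds the centre-excluded
    dilation at that cell; plateaus of exactly tied values therefore yield
    no peaks. Returns an ``(n, 2)`` int array of ``(freq_bin, time_bin)``
    sorted by time (then frequency).
    """
    if not smoothed.smoothed:
        raise ValueError("find_peaks requires a smoothed spectrogram")
    is_peak = smoothed.power > dilate(smoothed.power)
    fbin, tbin = np.nonzero(is_peak)
    order = np.lexsort((fbin, tbin))
    return np.column_stack([fbin[order], tbin[order]])


def threshold_peaks(candidates, smoothed: Spectrogram, factor: float = 6.0):
    """Keep candidates whose power is >= factor x the median power across
    all time points at the peak frequency (medians include edge-flagged
    samples; computed on the smoothed spectrogram)."""
    if not factor > 0:
        raise ValueError("threshold factor must be > 0")
    candidates = np.asarray(candidates, dtype=int).reshape(-1, 2)
    if candidates.size == 0:
        return candidates
    row_medians = np.median(smoothed.power, axis=1)
    vals = smoothed.power[candidates[:, 0], candidates[:, 1]]
    keep = vals >= factor * row_medians[candidates[:, 0]]
    return candidates[keep]


def detect_bursts(signal: ContinuousSignal, config: DetectionConfig = None):
    """Detect beta bursts in a continuous signal.

    Pipeline: Morlet spectrogram -> 2-D Gaussian smoothing -> 5x5
    centre-excluded dilation peak picking -> median-ratio thresholding,
    restricted to peaks whose frequency lies in ``config.beta_band`` and
    whose time is outside the per-frequency edge-unreliable margins.

    Returns a list of :class:`BurstEvent` sorted by time.
    """
    if config is None:
        config = DetectionConfig()
    spec = morlet_tfr(signal, freqs=config.freqs, n_cycles=config.n_cycles)
    sm = smooth_spectrogram(spec, sd_f=config.sd_f, sd_t=config.sd_t)
    cands = find_peaks(sm)
    cands = threshold_peaks(cands, sm, factor=config.threshold_factor)
    if cands.size == 0:
        return []
    lo, hi = config.beta_band
    in_band = (sm.freqs[cands[:, 0]] >= lo) & (sm.freqs[cands[:, 0]] <= hi)
    cands = cands[in_band]
    # drop edge-unreliable samples (per-frequency half-wavelet margin)
    n_t = sm.times.size
    margins = sm.edge_samples[cands[:, 0]]
    ok = (cands[:, 1] >= margins) & (cands[:, 1] < n_t - margins)
    cands = cands[ok]

    row_medians = np.median(sm.power, axis=1)
    events = []
    for fbin, tbin in cands:
        p = sm.power[fbin, tbin]
        med = row_medians[fbin]
        events.append(
            BurstEvent(
                time=float(sm.times[tbin]),
                freq=float(sm.freqs[fbin]),
                peak_power=float(p),
                median_ratio=float(p / med) if med > 0 else np.inf,
            )
        )
    events.sort(key=lambda e: (e.time, e.freq))
    if config.min_separation > 0 and events:
        kept = [events[0]]
        for ev in events[1:]:
            if ev.time - kept[-1].time >= config.min_separation:
                kept.append(ev)
            elif ev.peak_power > kept[-1].peak_power:
                kept[-1] = ev
        events = kept
    return events


def surrogate_events(n: int, duration: float, min_gap: float = 0.0, seed=None):
    """Uniformly placed surrogate ("fake") event times respecting a minimum
    gap, for null control analyses of event-related regressors.

    Uses the order-statistics construction: draw n uniform points on the
    interval shrunk by the total gap, sort, then re-inflate with the gaps,
    so the marginal rate is n / duration.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    if min_gap < 0 or n * min_gap >= duration:
        raise ValueError(
            f"cannot place {n} events with min_gap {min_gap} s in {duration} s"
        )
    rng = np.random.default_rng(seed)
    slack = duration - (n - 1) * min_gap
    pts = np.sort(rng.uniform(0.0, slack, size=n))
    return pts + min_gap * np.arange(n)
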