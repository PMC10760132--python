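"""Streaming, causal detectors for slow-oscillation up-states and spindles.

Both detectors are strictly online: each output depends only on samples
already seen, state is carried across arbitrary chunk boundaries, and the
same recording produces the same events for any chunk partition.

The slow-oscillation trigger implements threshold-then-peak logic: the
causally band-passed signal rising through a positive threshold (+35 uV by
default) arms the detector, and the first subsequent local maximum (smoothed
first difference changing sign from + to -) fires the trigger. The detector
re-arms only after the signal falls back below threshold, so one up-state
yields at most one trigger.

The spindle detector band-passes 11-16 Hz, tracks a moving RMS, and confirms
a spindle when the RMS stays above threshold for a minimum duration. It keeps
"time of the last spindle" queryable at any sample, which the cueing engine
uses for the refractory gate.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class DetectorConfig:
    """Online detection settings (amplitudes in uV, durations in s)."""

    rate: float = 512.0
    so_threshold: float = 35.0
    so_band: tuple[float, float] = (0.5, 4.0)
    so_filter_order: int = 2
    so_smooth_samples: int = 3
    spindle_band: tuple[float, float] = (11.0, 16.0)
    spindle_rms_window: float = 0.3
    spindle_threshold: float = 10.0
    spindle_adaptive: bool = False
    spindle_adaptive_k: float = 3.0
    spindle_adaptive_window: float = 60.0
    spindle_min_duration: float = 0.4
    latency_budget: int = 16  # samples between true local max and trigger

    def __post_init__(self) -> None:
        if self.so_threshold <= 0:
            raise ValueError("so_threshold must be positive")
        nyq = self.rate / 2.0
        for band in (self.so_band, self.spindle_band):
            if not (0.0 < band[0] < band[1] < nyq):
                raise ValueError(f"band {band} outside (0, {nyq}) or not increasing")


@dataclass(frozen=True)
class SOEvent:
    crossing_time: float
    peak_time: float
    peak_value: float      # uV, causally filtered
    trigger_time: float    # when the online system acts (>= peak_time)


@dataclass(frozen=True)
class SpindleEvent:
    onset_time: float
    offset_time: float
    peak_rms: float


class CausalBandpass:
    """Stateful Butterworth band-pass; chunking-invariant by construction."""

    def __init__(self, band: tuple[float, float], rate: float, order: int = 2):
        nyq = rate / 2.0
        if not (0.0 < band[0] < band[1] < nyq):
            raise ValueError(f"band {band} outside (0, {nyq})")
        self.sos = signal.butter(order, band, btype="bandpass", fs=rate,
                                 output="sos")
        self._zi = np.zeros((self.sos.shape[0], 2))

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=float)
        if chunk.size == 0:
            return chunk
        out, self._zi = signal.sosfilt(self.sos, chunk, zi=self._zi)
        return out

    def group_delay(self, freq: float, rate: float) -> float:
        """Group delay (s) of the cascaded filter at ``freq`` Hz."""
        b, a = signal.sos2tf(self.sos)
        w, gd = signal.group_delay((b, a), w=[freq], fs=rate)
        return float(gd[0]) / rate


def _as_1d(chunk: np.ndarray, channel: int = 0) -> np.ndarray:
    """Accept (samples,) or (channels, samples) chunks; pick one channel."""
    chunk = np.asarray(chunk, dtype=float)
    return chunk[channel] if chunk.ndim == 2 else chunk


def causal_filter(chunks: Iterable[np.ndarray], band: tuple[float, float],
                  rate: float, order: int = 2,
                  channel: int = 0) -> Iterator[np.ndarray]:
    """Filter a chunk stream causally; yields one filtered chunk per input."""
    filt = CausalBandpass(band, rate, order)
    for c in chunks:
        yield filt.process(_as_1d(c, channel))


class SODetector:
    """Threshold-then-peak up-state trigger over an already-filtered stream."""

    _ARMED, _PEAKSEEK, _REARM = 0, 1, 2

    def __init__(self, config: DetectorConfig):
        self.cfg = config
        self._state = self._ARMED
        self._n = 0                     # absolute sample index of next sample
        self._prev = 0.0
        self._dbuf = [0.0] * config.so_smooth_samples
        self._dpos = 0
        self._sdiff_prev = 0.0
        self._cross_n = 0
        self._max_val = -np.inf
        self._max_n = 0

    def process(self, filtered_chunk: np.ndarray) -> list[SOEvent]:
        """Consume filtered samples; return events triggered in this chunk."""
        cfg = self.cfg
        thr = cfg.so_threshold
        rate = cfg.rate
        k = cfg.so_smooth_samples
        events: list[SOEvent] = []
        state = self._state
        prev = self._prev
        dbuf = self._dbuf
        dpos = self._dpos
        sdiff_prev = self._sdiff_prev
        n = self._n
        for x in np.asarray(filtered_chunk, dtype=float):
            d = x - prev
            dbuf[dpos] = d
            dpos = (dpos + 1) % k
            sdiff = sum(dbuf) / k
            if state == self._ARMED:
                if prev < thr <= x:
                    state = self._PEAKSEEK
                    self._cross_n = n
                    self._max_val = x
                    self._max_n = n
            elif state == self._PEAKSEEK:
                if x > self._max_val:
                    self._max_val = x
                    self._max_n = n
                if sdiff_prev > 0.0 and sdiff <= 0.0:
                    events.append(SOEvent(
                        crossing_time=self._cross_n / rate,
                        peak_time=self._max_n / rate,
                        peak_value=self._max_val,
                        trigger_time=n / rate))
                    state = self._REARM
            else:  # _REARM: hysteresis until the signal drops below threshold
                if x < thr:
                    state = self._ARMED
            sdiff_prev = sdiff
            prev = x
            n += 1
        self._state = state
        self._prev = prev
        self._dpos = dpos
        self._sdiff_prev = sdiff_prev
        self._n = n
        return events


def detect_so_upstate(filtered_chunks: Iterable[np.ndarray],
                      config: DetectorConfig) -> Iterator[SOEvent]:
    """Generator form of :class:`SODetector` over a filtered chunk stream."""
    det = SODetector(config)
    for chunk in filtered_chunks:
        yield from det.process(chunk)


class SpindleDetector:
    """Band-limited moving-RMS spindle detector with last-spindle bookkeeping.

    ``last_spindle_time(t)`` returns the most recent moment, at or before
    ``t``, at which a confirmed spindle was ongoing (its running offset); it
    never looks ahead of the samples already processed.
    """

    def __init__(self, config: DetectorConfig):
        self.cfg = config
        self._bp = CausalBandpass(config.spindle_band, config.rate)
        m = max(1, int(round(config.spindle_rms_window * config.rate)))
        self._ma_b = np.ones(m) / m
        self._ma_zi = np.zeros(m - 1)
        self._min_run = max(1, int(round(config.spindle_min_duration * config.rate)))
        self._n = 0
        self._run = 0
        self._in_spindle = False
        self._onset_n = 0
        self._peak_rms = 0.0
        # confirmed spindles: parallel sorted lists (confirm_n, running offset_n)
        self._confirm_ns: list[int] = []
        self._offset_ns: list[int] = []
        self.events: list[SpindleEvent] = []
        if config.spindle_adaptive:
            w = int(round(config.spindle_adaptive_window * config.rate))
            self._ring = np.zeros(w)
            self._ring_n = 0
            self._ring_sum = 0.0
            self._ring_sumsq = 0.0

    def process(self, chunk: np.ndarray) -> list[SpindleEvent]:
        cfg = self.cfg
        x = self._bp.process(np.asarray(chunk, dtype=float))
        msq, self._ma_zi = signal.lfilter(self._ma_b, 1.0, x * x, zi=self._ma_zi)
        rms = np.sqrt(np.maximum(msq, 0.0))
        new: list[SpindleEvent] = []
        n = self._n
        for r in rms:
            thr = self._threshold(r)
            if r >= thr:
                self._run += 1
                if self._run == self._min_run:
                    self._in_spindle = True
                    self._onset_n = n - self._min_run + 1
                    self._peak_rms = r
                    self._confirm_ns.append(n)
                    self._offset_ns.append(n)
                if self._in_spindle:
                    self._peak_rms = max(self._peak_rms, r)
                    self._offset_ns[-1] = n
            else:
                if self._in_spindle:
                    # the causal moving RMS reports its window's trailing
                    # edge; shift both bounds to the window center
                    lag = cfg.spindle_rms_window / 2.0
                    ev = SpindleEvent(onset_time=self._onset_n / cfg.rate - lag,
                                      offset_time=n / cfg.rate - lag,
                                      peak_rms=self._peak_rms)
                    new.append(ev)
                    self.events.append(ev)
                    self._in_spindle = False
                self._run = 0
            n += 1
        self._n = n
        return new

    def _threshold(self, r: float) -> float:
        cfg = self.cfg
        if not cfg.spindle_adaptive:
            return cfg.spindle_threshold
        w = self._ring.size
        i = self._ring_n % w
        old = self._ring[i]
        self._ring[i] = r
        self._ring_sum += r - old
        self._ring_sumsq += r * r - old * old
        self._ring_n += 1
        m = min(self._ring_n, w)
        if m < int(cfg.rate):  # <1 s of history: fall back to the fixed value
            return cfg.spindle_threshold
        mean = self._ring_sum / m
        var = max(self._ring_sumsq / m - mean * mean, 0.0)
        return mean + cfg.spindle_adaptive_k * np.sqrt(var)

    def last_spindle_time(self, t: float) -> float:
        """Most recent spindle time at or before ``t`` (-inf if none)."""
        n = int(t * self.cfg.rate)
        i = bisect.bisect_right(self._confirm_ns, n) - 1
        if i < 0:
            return -np.inf
        return min(self._offset_ns[i], n) / self.cfg.rate


def detect_spindles(chunks: Iterable[np.ndarray],
                    config: DetectorConfig,
                    channel: int = 0) -> Iterator[SpindleEvent]:
    """Generator form of :class:`SpindleDetector` over a raw chunk stream."""
    det = SpindleDetector(config)
    for chunk in chunks:
        yield from det.process(_as_1d(chunk, channel))


def events_to_tsv(events, path) -> None:
    """Serialize detector events (SO or spindle) to a 3-column TSV."""
    with open(path, "w") as fh:
        fh.write("time\tkind\tvalue\n")
        for e in events:
            if isinstance(e, SOEvent):
                fh.write(f"{e.peak_time:.6f}\tSO\t{e.peak_value:.3f}\n")
            else:
                fh.write(f"{e.onset_time:.6f}\tspindle\t{e.peak_rms:.3f}\n")
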