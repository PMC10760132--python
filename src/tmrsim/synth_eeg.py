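"""Synthetic sleep EEG with planted slow oscillations, spindles and a hypnogram.

The generator produces the ground truth against which the online detectors and
the closed-loop cueing engine are validated: every slow oscillation (SO) and
spindle is planted at a known time with a known amplitude, on top of 1/f
background activity, and the hypnogram is the generator's own stage sequence
rather than a scored one.

Conventions: amplitudes are in microvolts, times in seconds from recording
start (0-based), and all randomness flows through a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal

STAGES = ("W", "N1", "N2", "N3", "REM")
NREM_CUEABLE = ("N2", "N3")


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hypnogram:
    """Sleep-stage sequence in fixed-length scoring epochs (30 s by default)."""

    stages: tuple[str, ...]
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_epochs * self.epoch_length

    def stage_at(self, t: float) -> str:
        """Stage label at time ``t`` seconds (clamped to the last epoch)."""
        if t < 0:
            raise ValueError("time must be >= 0")
        i = min(int(t / self.epoch_length), self.n_epochs - 1)
        return self.stages[i]

    def epochs_of(self, stages: Sequence[str]) -> np.ndarray:
        """Indices of epochs whose label is in ``stages``."""
        want = set(stages)
        return np.array([i for i, s in enumerate(self.stages) if s in want], dtype=int)

    def segments(self) -> list[tuple[float, float, str]]:
        """Maximal same-stage runs as (start_s, end_s, stage)."""
        out: list[tuple[float, float, str]] = []
        start = 0
        for i in range(1, self.n_epochs + 1):
            if i == self.n_epochs or self.stages[i] != self.stages[start]:
                out.append((start * self.epoch_length, i * self.epoch_length,
                            self.stages[start]))
                start = i
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch_index\tstage\n")
            for i, s in enumerate(self.stages):
                fh.write(f"{i}\t{s}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, epoch_length: float = 30.0) -> "Hypnogram":
        stages = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("epoch_index"):
                raise ValueError("expected header 'epoch_index\\tstage'")
            for line in fh:
                if line.strip():
                    stages.append(line.split("\t")[1].strip())
        return cls(tuple(stages), epoch_length)


@dataclass(frozen=True)
class HypnogramParams:
    """Semi-Markov stage-progression settings for a daytime nap.

    Dwell ranges are in scoring epochs (inclusive). ``rem_allowed_after_min``
    gates REM entries: daytime naps rarely reach REM before ~60 min.
    ``force_stage`` pins the whole hypnogram to one stage (e.g. an all-wake
    control recording).
    """

    epoch_length: float = 30.0
    initial_wake_epochs: tuple[int, int] = (2, 6)
    dwell: dict = field(default_factory=lambda: {
        "W": (1, 3), "N1": (1, 4), "N2": (6, 18), "N3": (6, 18), "REM": (4, 10),
    })
    # transition probabilities out of each stage (renormalized after gating)
    transitions: dict = field(default_factory=lambda: {
        "W": {"N1": 1.0},
        "N1": {"N2": 0.85, "W": 0.15},
        "N2": {"N3": 0.70, "N1": 0.10, "W": 0.08, "REM": 0.12},
        "N3": {"N2": 0.80, "N1": 0.10, "W": 0.10},
        "REM": {"N1": 0.50, "N2": 0.50},
    })
    rem_allowed_after_min: float = 60.0
    force_stage: str | None = None


def generate_hypnogram(duration_min: float,
                       params: HypnogramParams | None = None,
                       seed: int | None = None) -> Hypnogram:
    """Generate a nap hypnogram as a first-order stage progression.

    The sequence starts in wake, descends W -> N1 -> N2 -> N3, and can return
    to lighter stages or REM according to ``params.transitions``. Deterministic
    for a fixed ``(params, seed)``.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    p = params or HypnogramParams()
    n_epochs = int(round(duration_min * 60.0 / p.epoch_length))
    if p.force_stage is not None:
        return Hypnogram((p.force_stage,) * n_epochs, p.epoch_length)

    rng = np.random.default_rng(seed)
    stages: list[str] = []
    cur = "W"
    dwell_left = int(rng.integers(p.initial_wake_epochs[0],
                                  p.initial_wake_epochs[1] + 1))
    while len(stages) < n_epochs:
        stages.append(cur)
        dwell_left -= 1
        if dwell_left <= 0:
            elapsed_min = len(stages) * p.epoch_length / 60.0
            opts = dict(p.transitions[cur])
            if elapsed_min < p.rem_allowed_after_min:
                opts.pop("REM", None)
            names = sorted(opts)
            probs = np.array([opts[k] for k in names], dtype=float)
            probs /= probs.sum()
            cur = names[int(rng.choice(len(names), p=probs))]
            lo, hi = p.dwell[cur]
            dwell_left = int(rng.integers(lo, hi + 1))
    return Hypnogram(tuple(stages[:n_epochs]), p.epoch_length)


# ---------------------------------------------------------------------------
# Planted events and EEG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth event written into the synthetic trace."""

    kind: str                 # "SO" | "spindle"
    peak_time: float          # s; SO positive peak / spindle envelope center
    amplitude: float          # uV (SO peak; spindle envelope peak)
    duration: float           # s
    frequency: float | None = None  # Hz, spindles only
    onset_time: float = 0.0   # s, waveform start

    def __post_init__(self) -> None:
        if self.kind not in ("SO", "spindle"):
            raise ValueError("kind must be 'SO' or 'spindle'")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class EEGParams:
    """Event densities, morphology and background settings.

    Densities are conventional adult NREM values (the generator's only
    authority for them); everything is config-exposed. The spindle
    ``refractory_floor`` guarantees planted inter-onset gaps so the protocol's
    spindle-refractory gate is exercised on both sides.
    """

    rate: float = 512.0
    channel_labels: tuple[str, ...] = ("Fz",)
    # background
    pink_rms: float = 12.0            # uV, broadband 1/f
    pink_exponent: float = 1.0
    delta_rms: dict = field(default_factory=lambda: {"N2": 6.0, "N3": 14.0})
    # slow oscillations
    so_rate_per_min: dict = field(default_factory=lambda: {"N2": 3.0, "N3": 7.0})
    so_amp_range: tuple[float, float] = (45.0, 110.0)
    so_duration: float = 1.25
    so_min_gap: float = 2.0           # s between SO onsets
    # spindles
    spindle_rate_per_min: dict = field(default_factory=lambda: {"N2": 2.5, "N3": 1.2})
    spindle_amp_range: tuple[float, float] = (20.0, 45.0)
    spindle_freq_range: tuple[float, float] = (11.0, 16.0)
    spindle_dur_range: tuple[float, float] = (0.5, 2.0)
    refractory_floor: float = 3.0     # s between spindle onsets


@dataclass
class SyntheticRecording:
    """Multichannel-capable synthetic EEG plus its ground truth."""

    data: np.ndarray                  # (n_channels, n_samples) uV
    rate: float
    channel_labels: tuple[str, ...]
    planted: list[PlantedEvent]
    hypnogram: Hypnogram
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel count mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str = "Fz") -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def planted_of(self, kind: str) -> list[PlantedEvent]:
        return [e for e in self.planted if e.kind == kind]


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _place_events(rng: np.random.Generator, segments, rates: dict,
                  min_gap: float, duration: float,
                  total: float) -> list[float]:
    """Poisson placement of event onsets inside stage segments, honoring a
    global minimum inter-onset gap."""
    onsets: list[float] = []
    for (t0, t1, stage) in segments:
        rate = rates.get(stage, 0.0)
        if rate <= 0:
            continue
        span = t1 - t0 - duration
        if span <= 0:
            continue
        n = rng.poisson(rate * (t1 - t0) / 60.0)
        onsets.extend(t0 + rng.uniform(0.0, span, size=n))
    onsets.sort()
    kept: list[float] = []
    for t in onsets:
        if not kept or t - kept[-1] >= min_gap:
            if t + duration <= total:
                kept.append(t)
    return kept


def generate_eeg(hypnogram: Hypnogram,
                 params: EEGParams | None = None,
                 seed: int | None = None) -> SyntheticRecording:
    """Synthesize a recording for ``hypnogram`` with planted SOs and spindles.

    SOs are single-cycle biphasic waves (trough then positive peak) and
    spindles are Hann-windowed sinusoid bursts; both are planted only inside
    N2/N3 epochs. The background is 1/f noise plus a stage-dependent delta
    component, so N3 carries more low-frequency power than wake.
    """
    if hypnogram.n_epochs == 0:
        raise ValueError("hypnogram is empty")
    p = params or EEGParams()
    rng = np.random.default_rng(seed)
    n = int(round(hypnogram.duration * p.rate))
    t_total = n / p.rate
    segs = hypnogram.segments()

    x = p.pink_rms * _pink_noise(n, p.pink_exponent, rng)

    # stage-dependent slow (0.5-2 Hz) background
    delta = _pink_noise(n, 0.0, rng)
    sos = signal.butter(2, [0.5, 2.0], btype="bandpass", fs=p.rate, output="sos")
    delta = signal.sosfiltfilt(sos, delta)
    delta /= delta.std()
    gain = np.zeros(n)
    for (t0, t1, stage) in segs:
        g = p.delta_rms.get(stage, 0.0)
        if g > 0:
            gain[int(t0 * p.rate):int(t1 * p.rate)] = g
    x += gain * delta

    planted: list[PlantedEvent] = []

    # slow oscillations: -A*sin(2*pi*t/D) over one cycle -> trough then peak
    for onset in _place_events(rng, segs, p.so_rate_per_min, p.so_min_gap,
                               p.so_duration, t_total):
        amp = rng.uniform(*p.so_amp_range)
        i0 = int(round(onset * p.rate))
        m = int(round(p.so_duration * p.rate))
        tt = np.arange(m) / p.rate
        x[i0:i0 + m] += -amp * np.sin(2 * np.pi * tt / p.so_duration)
        peak = onset + 0.75 * p.so_duration
        planted.append(PlantedEvent("SO", peak_time=peak, amplitude=amp,
                                    duration=p.so_duration, onset_time=onset))

    # spindles: Hann-windowed 11-16 Hz bursts with a refractory floor
    for onset in _place_events(rng, segs, p.spindle_rate_per_min,
                               p.refractory_floor,
                               max(p.spindle_dur_range), t_total):
        amp = rng.uniform(*p.spindle_amp_range)
        freq = rng.uniform(*p.spindle_freq_range)
        dur = rng.uniform(*p.spindle_dur_range)
        m = int(round(dur * p.rate))
        tt = np.arange(m) / p.rate
        burst = amp * signal.windows.hann(m) * np.sin(2 * np.pi * freq * tt)
        i0 = int(round(onset * p.rate))
        x[i0:i0 + m] += burst[:max(0, n - i0)]
        planted.append(PlantedEvent("spindle", peak_time=onset + dur / 2.0,
                                    amplitude=amp, duration=dur,
                                    frequency=freq, onset_time=onset))

    planted.sort(key=lambda e: e.onset_time)
    data = np.tile(x, (len(p.channel_labels), 1))
    return SyntheticRecording(data=data, rate=p.rate,
                              channel_labels=p.channel_labels,
                              planted=planted, hypnogram=hypnogram, seed=seed)


def stream(recording: SyntheticRecording, chunk_size: int) -> Iterator[np.ndarray]:
    """Yield consecutive (n_channels, <=chunk_size) sample blocks.

    This is the only interface the online stages consume; it provides no
    lookahead, and concatenating the chunks reproduces the batch data exactly.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    n = recording.n_samples
    for i in range(0, n, chunk_size):
        yield recording.data[:, i:i + chunk_size]


# ---------------------------------------------------------------------------
# Offline oracle and I/O
# ---------------------------------------------------------------------------

def offline_so_peak(recording: SyntheticRecording, around: float,
                    band: tuple[float, float] = (0.5, 4.0),
                    half_window: float = 0.5,
                    channel: str = "Fz") -> tuple[float, float]:
    """Zero-phase band-pass + windowed argmax: the offline SO-peak oracle.

    Returns (peak_time, peak_value) of the filtered trace within
    ``around +/- half_window`` seconds.
    """
    sos = signal.butter(2, band, btype="bandpass", fs=recording.rate, output="sos")
    filt = signal.sosfiltfilt(sos, recording.channel(channel))
    i0 = max(0, int((around - half_window) * recording.rate))
    i1 = min(recording.n_samples, int((around + half_window) * recording.rate))
    k = i0 + int(np.argmax(filt[i0:i1]))
    return k / recording.rate, float(filt[k])


def save_recording(recording: SyntheticRecording, prefix: str | Path) -> None:
    """Write ``<prefix>.bin`` (float32 samples) + ``<prefix>.json`` sidecar and
    ``<prefix>.hypnogram.tsv``."""
    prefix = Path(prefix)
    recording.data.astype(np.float32).tofile(prefix.with_suffix(".bin"))
    side = {
        "rate": recording.rate,
        "channel_labels": list(recording.channel_labels),
        "n_samples": recording.n_samples,
        "seed": recording.seed,
        "epoch_length": recording.hypnogram.epoch_length,
        "planted": [
            {"kind": e.kind, "peak_time": e.peak_time, "amplitude": e.amplitude,
             "duration": e.duration, "frequency": e.frequency,
             "onset_time": e.onset_time}
            for e in recording.planted
        ],
    }
    prefix.with_suffix(".json").write_text(json.dumps(side, indent=1))
    recording.hypnogram.to_tsv(str(prefix) + ".hypnogram.tsv")


def load_recording(prefix: str | Path) -> SyntheticRecording:
    prefix = Path(prefix)
    side = json.loads(prefix.with_suffix(".json").read_text())
    raw = np.fromfile(prefix.with_suffix(".bin"), dtype=np.float32)
    data = raw.reshape(len(side["channel_labels"]), side["n_samples"])
    hyp = Hypnogram.from_tsv(str(prefix) + ".hypnogram.tsv",
                             epoch_length=side["epoch_length"])
    planted = [PlantedEvent(kind=d["kind"], peak_time=d["peak_time"],
                            amplitude=d["amplitude"], duration=d["duration"],
                            frequency=d["frequency"], onset_time=d["onset_time"])
               for d in side["planted"]]
    return SyntheticRecording(data=data.astype(float), rate=side["rate"],
                              channel_labels=tuple(side["channel_labels"]),
                              planted=planted, hypnogram=hyp, seed=side["seed"])
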