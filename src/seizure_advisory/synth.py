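"""Synthetic chronic intracranial EEG records.

Generates long-duration multichannel iEEG-like signals with seizure events,
a planted pre-ictal signature, antiepileptic-drug (AED) pharmacokinetic
confounds, and an error-prone patient diary, so that the whole advisory
pipeline is testable without any recorded patient data.

Model summary
-------------
* Seizure onsets: homogeneous Poisson process thinned by a hard refractory
  (dead-time) rule so consecutive events are at least ``refractory`` seconds
  apart.  The base intensity is dead-time corrected so the *thinned* process
  has the requested monthly rate.
* Background: independent 1/f-shaped Gaussian noise per channel, unit
  variance.
* Pre-ictal signature: on the signature channels, the band-limited component
  of the background in ``signature_band`` is multiplied by a gain ramping
  linearly from 1 at ``onset - preictal_horizon`` up to a peak at onset.  The
  peak gain is calibrated so the epoch-level mean-absolute-amplitude feature
  of that band shifts by ``effect_size`` interictal standard deviations.
* Ictal interval: a high-amplitude rhythmic burst on all channels for
  ``ictal_duration`` seconds after each onset.
* AED levels: superposed first-order decay curves from periodic dosing;
  optional couplings let the (normalized) level linearly modulate band
  components of chosen channels.
* Diary: each true event is logged independently with ``diary_report_prob``;
  spurious entries arrive as a Poisson process at ``diary_false_rate``.

All times are seconds from the record start; intervals are half-open
``[start, end)``.  A month is 30 days throughout.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

MONTH_SECONDS = 30.0 * 86400.0

# Stream ids so each sub-simulation has its own reproducible substream.
_STREAM_EVENTS = 0
_STREAM_SIGNALS = 1
_STREAM_DIARY = 2


class InfeasibleRateError(ValueError):
    """Requested seizure rate cannot be honored under the refractory gap."""


@dataclass(frozen=True)
class AedCoupling:
    """Linear coupling of the normalized AED level onto one channel band."""

    channel: int
    band: tuple[float, float]
    coefficient: float


@dataclass(frozen=True)
class SimulationConfig:
    duration: float
    seizure_rate: float = 4.0            # expected events / 30-day month
    sampling_rate: float = 400.0         # samples / s
    n_channels: int = 16
    refractory: float = 8 * 3600.0       # min inter-event gap, s
    preictal_horizon: float = 1800.0     # s before onset carrying the signature
    effect_size: float = 0.0             # standardized feature shift at onset
    signature_channels: tuple[int, ...] = (0, 1)
    signature_band: tuple[float, float] = (30.0, 70.0)   # Hz
    feature_epoch: float = 13.8          # s; epoch the effect size is standardized to
    ictal_duration: float = 60.0         # s
    ictal_amplitude: float = 8.0         # multiples of background SD
    aed_halflife: float = 12 * 3600.0    # s
    aed_dose_interval: float = 12 * 3600.0
    aed_dose: float = 1.0                # concentration units per dose
    aed_coupling: tuple[AedCoupling, ...] = ()
    diary_report_prob: float = 1.0
    diary_false_rate: float = 0.0        # spurious entries / month
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.seizure_rate < 0:
            raise ValueError("seizure_rate must be non-negative")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        if not self.preictal_horizon < self.refractory:
            raise ValueError("preictal_horizon must be smaller than refractory")
        if not 0.0 <= self.diary_report_prob <= 1.0:
            raise ValueError("diary_report_prob must lie in [0, 1]")
        if self.diary_false_rate < 0:
            raise ValueError("diary_false_rate must be non-negative")
        if self.aed_halflife <= 0:
            raise ValueError("aed_halflife must be positive")
        if self.sampling_rate <= 0 or self.n_channels < 1:
            raise ValueError("invalid sampling_rate / n_channels")
        lo, hi = self.signature_band
        if not 0 <= lo < hi <= self.sampling_rate / 2:
            raise ValueError("signature_band must lie inside (0, Nyquist]")
        for ch in self.signature_channels:
            if not 0 <= ch < self.n_channels:
                raise ValueError(f"signature channel {ch} out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def desk_scale(cls, seed: int = 0, effect_size: float = 2.0,
                   duration: float = 30 * 86400.0,
                   seizure_rate: float = 8.0) -> "SimulationConfig":
        """Reduced-sampling preset for desk-scale Monte-Carlo studies.

        30-day, 4-channel records at 0.2 samples/s with 240-s analysis
        epochs; the signature sits in the fifth of the six scaled analysis
        bands on channels 0 and 1.  See docs/methods.md for the rationale.
        """
        return cls(
            duration=duration,
            seizure_rate=seizure_rate,
            sampling_rate=0.2,
            n_channels=4,
            preictal_horizon=1800.0,
            effect_size=effect_size,
            signature_channels=(0, 1),
            signature_band=(0.015, 0.035),
            feature_epoch=240.0,
            ictal_duration=240.0,
            ictal_amplitude=8.0,
            seed=seed,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["aed_coupling"] = [dataclasses.asdict(c) for c in self.aed_coupling]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["aed_coupling"] = tuple(
            AedCoupling(c["channel"], tuple(c["band"]), c["coefficient"])
            for c in d.get("aed_coupling", ())
        )
        for key in ("signature_channels", "signature_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class DiaryLog:
    """Patient-reported event times with provenance flags."""

    times: np.ndarray                 # sorted, seconds
    is_true_report: np.ndarray        # bool, aligned with times

    def __post_init__(self) -> None:
        if len(self.times) != len(self.is_true_report):
            raise ValueError("provenance flags must align with entries")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("diary times must be sorted")


@dataclass
class SyntheticRecord:
    signals: np.ndarray               # (n_channels, n_samples)
    true_events: np.ndarray           # sorted onset times, s
    aed_times: np.ndarray
    aed_levels: np.ndarray
    diary: DiaryLog
    config: SimulationConfig

    @property
    def duration(self) -> float:
        return self.config.duration

    @property
    def sampling_rate(self) -> float:
        return self.config.sampling_rate


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# Seizure times


def simulate_seizure_times(config: SimulationConfig,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Poisson onsets thinned to honor the refractory gap.

    The base intensity is dead-time corrected, ``lam = r / (1 - r * tau)``,
    so the retained process has the requested long-run rate ``r``.
    """
    if rng is None:
        rng = _rng(config, _STREAM_EVENTS)
    if config.seizure_rate == 0:
        return np.empty(0)
    rate_s = config.seizure_rate / MONTH_SECONDS
    saturation = rate_s * config.refractory
    if saturation >= 1.0:
        raise InfeasibleRateError(
            f"rate {config.seizure_rate}/month cannot be honored with a "
            f"{config.refractory:.0f}-s refractory gap"
        )
    lam = rate_s / (1.0 - saturation)
    expected = lam * config.duration
    n = rng.poisson(expected)
    candidates = np.sort(rng.uniform(0.0, config.duration, size=n))
    kept: list[float] = []
    last = -math.inf
    for t in candidates:
        if t - last >= config.refractory:
            kept.append(t)
            last = t
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# AED levels


def aed_level_at(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Closed-form superposition of exponential decays from periodic dosing.

    Doses of ``aed_dose`` at 0, dt, 2*dt, ...; each decays with the configured
    half-life.  Evaluated with a geometric-series sum, so arbitrary time
    grids are cheap.
    """
    t = np.asarray(t, dtype=float)
    lam = math.log(2.0) / config.aed_halflife
    dt = config.aed_dose_interval
    k = np.floor(t / dt)                       # index of last dose at or before t
    r = math.exp(-lam * dt)
    # sum_{j=0..k} exp(-lam (t - j dt)) = exp(-lam (t - k dt)) * (1-r^(k+1))/(1-r)
    tail = np.exp(-lam * (t - k * dt))
    series = (1.0 - r ** (k + 1.0)) / (1.0 - r)
    out = config.aed_dose * tail * series
    return np.where(t < 0, 0.0, out)


def simulate_aed_levels(config: SimulationConfig,
                        sample_interval: float = 60.0) -> tuple[np.ndarray, np.ndarray]:
    """AED concentration sampled on a regular grid; strictly positive."""
    times = np.arange(0.0, config.duration, sample_interval)
    return times, aed_level_at(config, times)


# ---------------------------------------------------------------------------
# Signals


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n: int,
                      fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f power spectrum per channel."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])       # amplitude ~ f^-1/2 -> power ~ 1/f
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * shape
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _band_component(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase Butterworth band-pass component (same filters as the
    feature bank)."""
    from .features import FilterSpec

    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = FilterSpec("band", band[0], band[1]).gain_squared(freqs, fs)
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * gain, n=n, axis=-1)


def _epoch_mean_abs(x: np.ndarray, samples_per_epoch: int) -> np.ndarray:
    n_ep = x.shape[-1] // samples_per_epoch
    trimmed = x[..., : n_ep * samples_per_epoch]
    return np.abs(trimmed.reshape(*x.shape[:-1], n_ep, samples_per_epoch)).mean(axis=-1)


def simulate_signals(events: np.ndarray, config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Background noise + pre-ictal band-power ramp + ictal bursts + AED drift."""
    events = np.asarray(events, dtype=float)
    if events.size and (events.min() < 0 or events.max() >= config.duration):
        raise ValueError("events must lie within [0, duration)")
    if rng is None:
        rng = _rng(config, _STREAM_SIGNALS)
    fs = config.sampling_rate
    n = config.n_samples
    x = _one_over_f_noise(rng, config.n_channels, n, fs)
    t = np.arange(n) / fs

    # Pre-ictal signature: multiplicative gain on the in-band component.
    if config.effect_size != 0.0 and events.size and config.signature_channels:
        chans = np.asarray(config.signature_channels)
        band = _band_component(x[chans], fs, config.signature_band)
        spe = max(1, int(round(config.feature_epoch * fs)))
        feat = _epoch_mean_abs(band, spe)          # per-channel epoch features
        mu0 = feat.mean(axis=1)
        sd0 = feat.std(axis=1)
        # gain that moves the mean-abs-amplitude feature by effect_size SDs
        peak_gain = 1.0 + config.effect_size * sd0 / np.where(mu0 > 0, mu0, 1.0)
        ramp = np.zeros(n)
        h = config.preictal_horizon
        for onset in events:
            i0 = max(0, int(math.ceil((onset - h) * fs)))
            i1 = min(n, int(math.ceil(onset * fs)))
            if i1 > i0:
                ramp[i0:i1] = np.maximum(ramp[i0:i1], (t[i0:i1] - (onset - h)) / h)
        x[chans] += (peak_gain[:, None] - 1.0) * ramp[None, :] * band

    # Ictal bursts: rhythmic high-amplitude activity on every channel.
    if events.size:
        f_ictal = math.sqrt(config.signature_band[0] * config.signature_band[1])
        for onset in events:
            i0 = int(math.ceil(onset * fs))
            i1 = min(n, int(math.ceil((onset + config.ictal_duration) * fs)))
            if i1 > i0:
                seg = t[i0:i1] - onset
                burst = config.ictal_amplitude * np.sin(2 * np.pi * f_ictal * seg)
                x[:, i0:i1] += burst[None, :]

    # AED-coupled slow drift of band components.
    if config.aed_coupling:
        levels = aed_level_at(config, t)
        norm = levels / levels.mean() - 1.0
        for cpl in config.aed_coupling:
            comp = _band_component(x[cpl.channel], fs, cpl.band)
            x[cpl.channel] += cpl.coefficient * norm * comp
    return x


# ---------------------------------------------------------------------------
# Diary


def simulate_diary(true_events: np.ndarray, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> DiaryLog:
    if rng is None:
        rng = _rng(config, _STREAM_DIARY)
    true_events = np.asarray(true_events, dtype=float)
    reported = true_events[rng.random(len(true_events)) < config.diary_report_prob]
    n_false = rng.poisson(config.diary_false_rate * config.duration / MONTH_SECONDS)
    spurious = rng.uniform(0.0, config.duration, size=n_false)
    times = np.concatenate([reported, spurious])
    flags = np.concatenate([np.ones(len(reported), bool), np.zeros(n_false, bool)])
    order = np.argsort(times, kind="stable")
    return DiaryLog(times=times[order], is_true_report=flags[order])


# ---------------------------------------------------------------------------
# Full record


def simulate_record(config: SimulationConfig) -> SyntheticRecord:
    """Deterministic under a fixed config (seed included in the config)."""
    events = simulate_seizure_times(config)
    signals = simulate_signals(events, config)
    aed_times, aed_levels = simulate_aed_levels(config)
    diary = simulate_diary(events, config)
    return SyntheticRecord(signals=signals, true_events=events,
                           aed_times=aed_times, aed_levels=aed_levels,
                           diary=diary, config=config)


# ---------------------------------------------------------------------------
# Writers (European Data Format + CSV + JSON)


def _edf_field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(path, signals: np.ndarray, sampling_rate: float,
              channel_names: list[str] | None = None,
              physical_dim: str = "uV") -> None:
    """Minimal EDF (16-bit) writer for continuous multichannel signals.

    Chooses the shortest integer data-record duration that makes the
    per-record sample count integral; a trailing partial record is dropped.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n = signals.shape
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    record_dur = None
    for d in range(1, 61):
        if abs(sampling_rate * d - round(sampling_rate * d)) < 1e-9:
            record_dur = d
            break
    if record_dur is None:
        raise ValueError("sampling_rate incompatible with integral EDF records")
    spr = int(round(sampling_rate * record_dur))
    n_records = n // spr
    if n_records < 1:
        raise ValueError("signal shorter than one EDF data record")

    phys_min = float(np.floor(signals.min() - 1.0))
    phys_max = float(np.ceil(signals.max() + 1.0))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_ch)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field(str(record_dur), 8),
        _edf_field(str(n_ch), 4),
    ])
    header += b"".join(_edf_field(name, 16) for name in channel_names)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(physical_dim, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{phys_min:g}", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{phys_max:g}", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_edf_field(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    digital = np.round((signals - phys_min) * scale + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            f.write(block.tobytes())


def write_events_csv(path, times: np.ndarray, kind: str = "seizure") -> None:
    import pandas as pd

    pd.DataFrame({"time_s": np.asarray(times, dtype=float),
                  "kind": kind}).to_csv(path, index=False)


def write_diary_csv(path, diary: DiaryLog) -> None:
    import pandas as pd

    kinds = np.where(diary.is_true_report, "true-report", "spurious")
    pd.DataFrame({"time_s": diary.times, "kind": kinds}).to_csv(path, index=False)


def read_events_csv(path) -> np.ndarray:
    import pandas as pd

    return np.sort(pd.read_csv(path)["time_s"].to_numpy(dtype=float))
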