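"""The 288-feature bank: epoch segmentation, band filters, analyzers.

Architecture: every channel is passed through each of six band-pass filters,
and each filtered channel-epoch is reduced to a scalar by each of three
analyzers, giving ``n_channels x 6 x 3`` features (288 for 16 channels).
Features are computed on non-overlapping epochs (13.8 s by default, the
granularity of the device's advisory raster).

Filters are order-8 Butterworth band-passes applied with zero phase: the
squared magnitude response is applied in the frequency domain, which equals
the steady state of a forward-backward recursive filter while costing
O(N log N) on record-length signals.  The first epoch of each record is
flagged unusable (filter settling / circular-edge region).

Analyzers (scalar functionals of one filtered epoch ``x`` of length ``m``):

* ``mean_absolute_amplitude``  ``mean(|x|)``       (scales with c)
* ``average_power``            ``mean(x^2)``       (scales with c^2)
* ``line_length``              ``mean(|diff(x)|)`` (scales with c)
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np

# Canonical clinical bands at 400 samples/s (Hz).
CLINICAL_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("low_gamma", 30.0, 70.0),
    ("high_gamma", 70.0, 140.0),
)
_REFERENCE_NYQUIST = 200.0

ANALYZER_NAMES: tuple[str, ...] = (
    "mean_absolute_amplitude", "average_power", "line_length")

_GAIN_CACHE: dict[tuple, np.ndarray] = {}


def _butter_gain_squared(low: float, high: float, order: int,
                         sampling_rate: float, freqs: np.ndarray) -> np.ndarray:
    from scipy.signal import butter

    sos = butter(order, [low, high], btype="band", fs=sampling_rate,
                 output="sos")
    z = np.exp(-2j * np.pi * freqs / sampling_rate)
    h = np.ones_like(z)
    for b0, b1, b2, a0, a1, a2 in sos:
        h *= (b0 + b1 * z + b2 * z * z) / (a0 + a1 * z + a2 * z * z)
    return np.abs(h) ** 2


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass contract: attenuation >= 20 dB one octave outside the band.

    Realized as an order-8 Butterworth (24 dB/octave asymptotic roll-off).
    """

    name: str
    low: float
    high: float
    order: int = 4   # scipy design order; band-pass doubles it

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError(f"invalid passband {self.low}-{self.high}")

    def validate_for(self, sampling_rate: float) -> None:
        if not self.high < sampling_rate / 2:
            raise ValueError(
                f"filter {self.name}: high edge {self.high} must be below "
                f"Nyquist {sampling_rate / 2}")

    def gain_squared(self, freqs: np.ndarray, sampling_rate: float) -> np.ndarray:
        """|H(f)|^2 of the zero-phase (forward-backward) filter.

        Cached per (band, rate, grid size): Monte-Carlo sweeps re-filter
        thousands of equally sized records.
        """
        self.validate_for(sampling_rate)
        key = (self.low, self.high, self.order, sampling_rate, len(freqs))
        hit = _GAIN_CACHE.get(key)
        if hit is not None:
            return hit
        gain = _butter_gain_squared(self.low, self.high, self.order,
                                    sampling_rate, freqs)
        if len(_GAIN_CACHE) > 64:
            _GAIN_CACHE.clear()
        _GAIN_CACHE[key] = gain
        return gain


def clinical_filters() -> tuple[FilterSpec, ...]:
    return tuple(FilterSpec(n, lo, hi) for n, lo, hi in CLINICAL_BANDS)


def scaled_filters(sampling_rate: float) -> tuple[FilterSpec, ...]:
    """Six bands at the clinical bands' fractions of Nyquist, for any rate."""
    scale = (sampling_rate / 2) / _REFERENCE_NYQUIST
    return tuple(FilterSpec(n, lo * scale, hi * scale) for n, lo, hi in CLINICAL_BANDS)


def _analyzer(name: str, x: np.ndarray) -> np.ndarray:
    # x: (..., n_epochs, samples_per_epoch) -> (..., n_epochs)
    if name == "mean_absolute_amplitude":
        return np.abs(x).mean(axis=-1)
    if name == "average_power":
        return (x * x).mean(axis=-1)
    if name == "line_length":
        return np.abs(np.diff(x, axis=-1)).mean(axis=-1)
    raise KeyError(name)


@dataclass(frozen=True)
class AnalyzerSpec:
    name: str

    def __post_init__(self) -> None:
        if self.name not in ANALYZER_NAMES:
            raise ValueError(f"unknown analyzer {self.name!r}")

    def __call__(self, epochs: np.ndarray) -> np.ndarray:
        return _analyzer(self.name, epochs)


@dataclass(frozen=True)
class FeatureId:
    id: int
    channel: int
    filter: str
    analyzer: str


@dataclass(frozen=True)
class FeatureCatalog:
    """Deterministic channel-major enumeration of (channel, filter, analyzer)."""

    entries: tuple[FeatureId, ...]
    filters: tuple[FilterSpec, ...]
    analyzers: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> FeatureId:
        return self.entries[i]

    @property
    def n_channels(self) -> int:
        return 1 + max(e.channel for e in self.entries)

    def to_json(self) -> str:
        return json.dumps({
            "filters": [dataclasses.asdict(f) for f in self.filters],
            "analyzers": list(self.analyzers),
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureCatalog":
        d = json.loads(text)
        return cls(
            entries=tuple(FeatureId(**e) for e in d["entries"]),
            filters=tuple(FilterSpec(**f) for f in d["filters"]),
            analyzers=tuple(d["analyzers"]),
        )


def enumerate_features(n_channels: int,
                       filters: tuple[FilterSpec, ...] | None = None,
                       analyzers: tuple[str, ...] = ANALYZER_NAMES,
                       ) -> FeatureCatalog:
    """Full cross-product catalog; ids are stable, channel-major order."""
    if filters is None:
        filters = clinical_filters()
    if n_channels < 1 or len(filters) < 1 or len(analyzers) < 1:
        raise ValueError("need at least one channel, filter, and analyzer")
    for a in analyzers:
        AnalyzerSpec(a)
    entries = []
    i = 0
    for ch in range(n_channels):
        for f in filters:
            for a in analyzers:
                entries.append(FeatureId(i, ch, f.name, a))
                i += 1
    return FeatureCatalog(entries=tuple(entries), filters=tuple(filters),
                          analyzers=tuple(analyzers))


@dataclass(frozen=True)
class EpochGrid:
    """Half-open epochs aligned to the record start; default non-overlapping."""

    epoch_length: float = 13.8
    hop: float | None = None

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.hop is not None and self.hop <= 0:
            raise ValueError("hop must be positive")

    @property
    def effective_hop(self) -> float:
        return self.epoch_length if self.hop is None else self.hop


@dataclass(frozen=True)
class EpochIndex:
    starts: np.ndarray        # seconds
    start_sample: np.ndarray
    end_sample: np.ndarray
    epoch_length: float

    def __len__(self) -> int:
        return len(self.starts)


def segment_epochs(n_samples: int, sampling_rate: float,
                   grid: EpochGrid) -> EpochIndex:
    """Maximal set of whole epochs; any trailing partial epoch is dropped."""
    duration = n_samples / sampling_rate
    hop = grid.effective_hop
    n_ep = int(np.floor((duration - grid.epoch_length) / hop + 1e-9)) + 1
    if n_ep < 1:
        warnings.warn("record shorter than one epoch; empty segmentation")
        n_ep = 0
    starts = np.arange(n_ep) * hop
    s0 = np.round(starts * sampling_rate).astype(int)
    s1 = np.round((starts + grid.epoch_length) * sampling_rate).astype(int)
    s1 = np.minimum(s1, n_samples)
    return EpochIndex(starts=starts, start_sample=s0, end_sample=s1,
                      epoch_length=grid.epoch_length)


@dataclass
class FeatureMatrix:
    values: np.ndarray            # (n_epochs, n_features)
    epoch_starts: np.ndarray      # seconds
    epoch_length: float
    catalog: FeatureCatalog
    usable: np.ndarray            # bool per epoch

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values,
                          columns=[f"f{e.id}" for e in self.catalog.entries])
        df.insert(0, "epoch_start_s", self.epoch_starts)
        df.insert(1, "usable", self.usable.astype(int))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, catalog: FeatureCatalog) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        starts = df.pop("epoch_start_s").to_numpy(dtype=float)
        usable = df.pop("usable").to_numpy(dtype=bool)
        length = float(starts[1] - starts[0]) if len(starts) > 1 else 13.8
        return cls(values=df.to_numpy(dtype=float), epoch_starts=starts,
                   epoch_length=length, catalog=catalog, usable=usable)


def extract_features(signals: np.ndarray, sampling_rate: float,
                     catalog: FeatureCatalog, grid: EpochGrid) -> FeatureMatrix:
    """Apply every (filter, analyzer) pair per channel on every epoch.

    One forward FFT per channel; one inverse FFT per (channel, filter).
    Deterministic.  Epoch 0 and all-zero epochs are flagged unusable.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n = signals.shape
    if catalog.n_channels > n_ch:
        raise ValueError("catalog references channels missing from the record")
    for f in catalog.filters:
        f.validate_for(sampling_rate)
    idx = segment_epochs(n, sampling_rate, grid)
    n_ep = len(idx)
    n_feat = len(catalog)
    values = np.empty((n_ep, n_feat))
    if n_ep == 0:
        return FeatureMatrix(values, idx.starts, grid.epoch_length, catalog,
                             np.zeros(0, dtype=bool))

    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    gains = [f.gain_squared(freqs, sampling_rate) for f in catalog.filters]
    spe = idx.end_sample[0] - idx.start_sample[0]
    uniform = bool(np.all(idx.end_sample - idx.start_sample == spe))
    n_f, n_a = len(catalog.filters), len(catalog.analyzers)

    used_channels = sorted({e.channel for e in catalog.entries})
    for ch in used_channels:
        spec = np.fft.rfft(signals[ch])
        for fi, gain in enumerate(gains):
            filtered = np.fft.irfft(spec * gain, n=n)
            if uniform and grid.hop is None:
                epochs = filtered[idx.start_sample[0]:idx.end_sample[-1]]
                epochs = epochs.reshape(n_ep, spe)
            else:
                epochs = np.stack([filtered[a:b] for a, b in
                                   zip(idx.start_sample, idx.end_sample)])
            for ai, aname in enumerate(catalog.analyzers):
                col = ch * n_f * n_a + fi * n_a + ai
                values[:, col] = _analyzer(aname, epochs)

    usable = np.ones(n_ep, dtype=bool)
    usable[0] = False                      # settling epoch
    flat = np.stack([np.ptp(signals[:, a:b]) == 0
                     for a, b in zip(idx.start_sample, idx.end_sample)])
    usable &= ~flat
    return FeatureMatrix(values=values, epoch_starts=idx.starts,
                         epoch_length=grid.epoch_length, catalog=catalog,
                         usable=usable)


def aed_stability_screen(matrix: FeatureMatrix, aed_levels: np.ndarray,
                         threshold: float | None = None,
                         n_permutations: int = 500,
                         quantile: float = 0.999,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Exclude features whose |Spearman rho| with the AED level exceeds
    ``threshold``.

    ``aed_levels`` must already be resampled to the epoch timestamps.  When
    no threshold is given it is set to the ``quantile`` of a permutation
    null of |rho|.  A constant AED series disables the screen (everything
    retained, with a warning).

    Returns ``(retained_ids, excluded_ids)``.
    """
    from scipy.stats import rankdata

    levels = np.asarray(aed_levels, dtype=float)
    if len(levels) != matrix.n_epochs:
        raise ValueError("aed_levels must align with the epoch grid")
    ids = np.array([e.id for e in matrix.catalog.entries])
    mask = matrix.usable
    if np.ptp(levels[mask]) == 0:
        warnings.warn("constant AED level: stability screen disabled")
        return ids, np.empty(0, dtype=int)

    def spearman_all(y: np.ndarray) -> np.ndarray:
        ry = rankdata(y)
        ry = (ry - ry.mean()) / ry.std()
        rx = np.apply_along_axis(rankdata, 0, matrix.values[mask])
        rx = (rx - rx.mean(axis=0)) / rx.std(axis=0)
        return rx.T @ ry / len(ry)

    rho = spearman_all(levels[mask])
    if threshold is None:
        if rng is None:
            rng = np.random.default_rng(0)
        m = int(mask.sum())
        # permutation null of the max-|rho| scale: Spearman rho of permuted
        # ranks is asymptotically N(0, 1/(m-1)); simulate exactly instead
        null = np.empty(n_permutations)
        base = rankdata(levels[mask])
        base = (base - base.mean()) / base.std()
        for i in range(n_permutations):
            null[i] = abs(np.dot(base, rng.permutation(base)) / m)
        threshold = float(np.quantile(null, quantile))
    excluded = ids[np.abs(rho) > threshold]
    retained = ids[np.abs(rho) <= threshold]
    return retained, excluded
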