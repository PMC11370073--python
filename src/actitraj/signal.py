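"""Raw tri-axial signal processing: vector magnitude, windowing, features.

The classification pipeline operates on the Euclidean vector magnitude (VM)
of the three acceleration axes, segmented into fixed-length non-overlapping
windows (15 s at 30 Hz by default). Each window is reduced to a fixed,
ordered set of 25 time- and frequency-domain features that form the input
contract of the activity classifier. The per-window VM standard deviation is
additionally retained for non-wear detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "WindowFeatures",
    "FEATURE_NAMES",
    "vector_magnitude",
    "segment_windows",
    "extract_features",
    "extract_feature_table",
    "write_feature_table",
]

#: Ordered feature-name contract. The classifier refuses inputs whose
#: feature names or order differ from this list.
FEATURE_NAMES: tuple[str, ...] = (
    "vm_mean",
    "vm_sd",
    "vm_cv",
    "vm_min",
    "vm_max",
    "vm_p10",
    "vm_p25",
    "vm_p50",
    "vm_p75",
    "vm_p90",
    "vm_iqr",
    "vm_skew",
    "vm_kurtosis",
    "vm_autocorr_lag1",
    "vm_zero_crossings",
    "vm_peak_count",
    "total_power",
    "dominant_freq",
    "dominant_power",
    "dominant_power_frac",
    "second_dominant_freq",
    "spectral_entropy",
    "band_power_low",
    "band_power_high",
    "band_power_ratio",
)

# Dominant-frequency search excludes bins below this to suppress residual
# gravity leakage from the mean-centred window.
_MIN_SEARCH_FREQ_HZ = 0.1
# Band edges (Hz) for the two locomotion band-power features.
_LOW_BAND = (0.25, 2.5)
_HIGH_BAND = (2.5, 5.0)
_EPS = 1e-12


@dataclass(frozen=True)
class RawRecording:
    """A continuous tri-axial acceleration recording in units of g.

    Parameters
    ----------
    subject_id
        Identifier of the wearer.
    start_timestamp
        Local wall-clock time of the first sample.
    sample_rate
        Samples per second per axis (30 Hz for the hip-worn protocol).
    samples
        Array of shape (n, 3): columns x, y, z in g.
    """

    subject_id: str
    start_timestamp: datetime
    sample_rate: float
    samples: np.ndarray
    serial: str = "SIM000"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"samples must have shape (n, 3), got {arr.shape}")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def timestamp_of(self, index: int) -> datetime:
        return self.start_timestamp + timedelta(seconds=index / self.sample_rate)


@dataclass(frozen=True)
class WindowFeatures:
    """The 25-feature description of one 15-s window."""

    subject_id: str
    window_index: int
    window_start: datetime
    features: np.ndarray = field(repr=False)
    vm_sd: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.features, dtype=float)
        if arr.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} features, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "features", arr)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.features))


def vector_magnitude(xyz: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes, in g.

    ``xyz`` may be an (n, 3) array or a tuple of three equal-length axis
    arrays. Raises ``ValueError`` on ragged axes.
    """
    if isinstance(xyz, (tuple, list)) and len(xyz) == 3:
        lengths = {len(np.atleast_1d(a)) for a in xyz}
        if len(lengths) != 1:
            raise ValueError(f"axes have unequal lengths: {sorted(lengths)}")
        arr = np.column_stack([np.atleast_1d(np.asarray(a, float)) for a in xyz])
    else:
        arr = np.asarray(xyz, dtype=float)
        if arr.ndim == 1 and arr.shape == (3,):
            arr = arr.reshape(1, 3)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"expected (n, 3) samples, got shape {arr.shape}")
    # summed in axis order so the result is bit-identical to a per-sample loop
    return np.sqrt(arr[:, 0] ** 2 + arr[:, 1] ** 2 + arr[:, 2] ** 2)


def segment_windows(recording: RawRecording, window_s: float = 15.0) -> list[np.ndarray]:
    """Split a recording into consecutive non-overlapping raw windows.

    Windows are aligned to the recording start; a trailing partial window is
    dropped. The number of samples per window, ``sample_rate * window_s``,
    must be a whole number.
    """
    spw = recording.sample_rate * window_s
    if abs(spw - round(spw)) > 1e-9 or round(spw) <= 0:
        raise ValueError(
            f"sample_rate * window_s must be a positive integer, got {spw}"
        )
    spw = int(round(spw))
    n_windows = recording.n_samples // spw
    return [recording.samples[i * spw : (i + 1) * spw] for i in range(n_windows)]


def _spectrum(vm_centred: np.ndarray, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of the mean-centred VM (no taper)."""
    n = vm_centred.size
    spec = np.fft.rfft(vm_centred)
    power = (np.abs(spec) ** 2) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return freqs, power


def extract_features(
    window: np.ndarray,
    sample_rate: float,
    *,
    subject_id: str = "",
    window_index: int = 0,
    window_start: datetime | None = None,
    window_s: float | None = None,
) -> WindowFeatures:
    """Compute the fixed 25-feature vector on one raw window.

    All features are functions of the window's vector magnitude. Frequency
    features use an untapered FFT of the mean-centred VM; the dominant
    frequency search ignores bins below 0.1 Hz. For a zero-variance window
    (non-wear-like signal) the degenerate features are pinned to zero so the
    vector stays finite: autocorrelation, skewness, kurtosis and spectral
    entropy are all defined as 0.
    """
    window = np.asarray(window, dtype=float)
    vm = vector_magnitude(window)
    n = vm.size
    if n < 2:
        raise ValueError("window too short for feature extraction")
    if window_s is not None and n != int(round(window_s * sample_rate)):
        raise ValueError(
            f"expected {int(round(window_s * sample_rate))} samples for a "
            f"{window_s}-s window at {sample_rate} Hz, got {n}"
        )

    mean = float(vm.mean())
    sd = float(vm.std(ddof=0))
    centred = vm - mean

    cv = sd / mean if mean > _EPS else 0.0
    p10, p25, p50, p75, p90 = np.percentile(vm, [10, 25, 50, 75, 90])
    iqr = p75 - p25

    if sd > _EPS:
        z = centred / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
        autocorr = float(np.dot(centred[:-1], centred[1:]) / np.dot(centred, centred))
    else:
        skew = kurt = autocorr = 0.0

    signs = np.sign(centred)
    zero_crossings = int(np.sum(signs[:-1] * signs[1:] < 0))
    thresh = mean + sd
    above = vm > thresh
    # rising edges of the above-threshold indicator = distinct peaks
    peak_count = int(np.sum(above[1:] & ~above[:-1]) + (1 if above[0] else 0))

    freqs, power = _spectrum(centred, sample_rate)
    total_power = float(power.sum())

    search = freqs >= _MIN_SEARCH_FREQ_HZ
    if total_power > _EPS and search.any():
        sfreqs, spower = freqs[search], power[search]
        order = np.argsort(spower)[::-1]
        dom_i = order[0]
        dominant_freq = float(sfreqs[dom_i])
        dominant_power = float(spower[dom_i])
        dominant_frac = dominant_power / total_power
        second_freq = float(sfreqs[order[1]]) if order.size > 1 else 0.0
        p_norm = power / power.sum()
        nz = p_norm[p_norm > _EPS]
        entropy = float(-np.sum(nz * np.log(nz)) / np.log(len(p_norm)))
    else:
        dominant_freq = dominant_power = dominant_frac = second_freq = entropy = 0.0

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs < hi)
        return float(power[m].sum())

    bp_low = band_power(*_LOW_BAND)
    bp_high = band_power(*_HIGH_BAND)
    bp_ratio = bp_low / (bp_high + _EPS)

    values = np.array(
        [
            mean, sd, cv, float(vm.min()), float(vm.max()),
            float(p10), float(p25), float(p50), float(p75), float(p90),
            float(iqr), skew, kurt, autocorr, float(zero_crossings),
            float(peak_count), total_power, dominant_freq, dominant_power,
            dominant_frac, second_freq, entropy, bp_low, bp_high, bp_ratio,
        ]
    )
    return WindowFeatures(
        subject_id=subject_id,
        window_index=window_index,
        window_start=window_start or datetime(2000, 1, 1),
        features=values,
        vm_sd=sd,
    )


def extract_feature_table(
    recording: RawRecording, window_s: float = 15.0
) -> list[WindowFeatures]:
    """Window a recording and extract features for every full window."""
    windows = segment_windows(recording, window_s)
    out = []
    for i, w in enumerate(windows):
        start = recording.start_timestamp + timedelta(seconds=i * window_s)
        out.append(
            extract_features(
                w,
                recording.sample_rate,
                subject_id=recording.subject_id,
                window_index=i,
                window_start=start,
                window_s=window_s,
            )
        )
    return out


def write_feature_table(features: list[WindowFeatures], path) -> None:
    """Write one row per window: subject, ISO start, 25 features, vm_sd."""
    rows = []
    for f in features:
        row = {"subject_id": f.subject_id, "window_start": f.window_start.isoformat()}
        row.update(f.as_dict())
        row["vm_sd"] = f.vm_sd
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
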