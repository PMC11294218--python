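"""Raw EEG -> differential-entropy feature tensors.

Pipeline: drop the leading baseline, band-limit each trial into canonical
frequency bands, cut non-overlapping segments, and compute the Gaussian
differential entropy ``0.5 * ln(2*pi*e*var)`` per segment x channel x band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from damgcn.montage import DEAP32_CHANNELS, SEED62_CHANNELS

__all__ = [
    "EEGRecording",
    "BandSpec",
    "DEFeatureTensor",
    "DEAP_BANDS",
    "SEED_BANDS",
    "segment",
    "band_decompose",
    "differential_entropy",
    "extract_features",
    "binarize_deap_labels",
    "read_deap",
    "read_seed",
    "write_recording",
    "read_recording",
    "save_features",
    "load_features",
]

VARIANCE_FLOOR = 1e-12  # signal units squared; keeps DE finite on flat segments

DEAP_EEG_CHANNEL_COUNT = 32  # first 32 of the 40 recorded channels are EEG


@dataclass
class EEGRecording:
    """Multichannel EEG: trials x channels x time, plus labels and metadata.

    ``signal`` may be a single 3-D array (equal-length trials) or a list of
    2-D ``channels x time`` arrays (variable-length trials, SEED-style).
    """

    signal: np.ndarray | list[np.ndarray]
    fs: float
    labels: np.ndarray
    baseline_seconds: float = 0.0
    channel_names: tuple[str, ...] | None = None
    subject_ids: np.ndarray | None = None  # per-trial subject, optional

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = np.asarray(self.labels)
        if isinstance(self.signal, np.ndarray):
            if self.signal.ndim != 3:
                raise ValueError("array signal must be trials x channels x time")
            if not np.all(np.isfinite(self.signal)):
                raise ValueError("signal contains non-finite values")
        else:
            self.signal = [np.asarray(t, dtype=float) for t in self.signal]
            for t in self.signal:
                if t.ndim != 2:
                    raise ValueError("each trial must be channels x time")
        if len(self.labels) != self.n_trials:
            raise ValueError(
                f"{len(self.labels)} labels for {self.n_trials} trials"
            )

    @property
    def n_trials(self) -> int:
        return len(self.signal)

    @property
    def n_channels(self) -> int:
        return self.signal[0].shape[0]

    def trial(self, i: int) -> np.ndarray:
        return np.asarray(self.signal[i])


@dataclass(frozen=True)
class BandSpec:
    """Ordered frequency bands as (name, low_hz, high_hz) triples."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band specification is empty")
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name!r}: low {lo} must be < high {hi}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def clipped(self, fs: float) -> "BandSpec":
        """Clip band upper edges to the Nyquist frequency, warning when needed."""
        nyq = fs / 2.0
        out = []
        for name, lo, hi in self.bands:
            if hi > nyq:
                warnings.warn(
                    f"band {name!r} upper edge {hi} Hz exceeds Nyquist {nyq} Hz; clipping"
                )
                hi = nyq
            if lo >= hi:
                raise ValueError(f"band {name!r} entirely above Nyquist {nyq} Hz")
            out.append((name, lo, hi))
        return BandSpec(tuple(out))


# canonical band sets; the DEAP release is 4-45 Hz band-passed so its delta
# band is absent and gamma is capped at the release filter edge
DEAP_BANDS = BandSpec((
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
))
SEED_BANDS = BandSpec((
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 75.0),
))


@dataclass
class DEFeatureTensor:
    """Differential-entropy features: samples x channels x bands (nats)."""

    features: np.ndarray
    labels: np.ndarray
    sample_index: np.ndarray  # (n_samples, 2): (trial, segment-within-trial)
    band_names: tuple[str, ...]
    channel_names: tuple[str, ...] | None = None
    segment_seconds: float = field(default=float("nan"))
    subject_ids: np.ndarray | None = None  # per-sample subject

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 3:
            raise ValueError("features must be samples x channels x bands")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.sample_index) != n:
            raise ValueError("labels/sample_index length mismatch")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


def segment(rec: EEGRecording, segment_seconds: float) -> list[list[np.ndarray]]:
    """Cut each trial (baseline dropped) into non-overlapping windows.

    Returns one list of ``channels x window`` arrays per trial, in temporal
    order; a trailing partial window is discarded.  A trial shorter than one
    window yields an empty list with a warning.
    """
    win = segment_seconds * rec.fs
    if win <= 0 or abs(win - round(win)) > 1e-9:
        raise ValueError(
            f"segment_seconds * fs = {win} must be a positive integer sample count"
        )
    win = int(round(win))
    skip = int(round(rec.baseline_seconds * rec.fs))
    out = []
    for i in range(rec.n_trials):
        trial = rec.trial(i)[:, skip:]
        n_seg = trial.shape[1] // win
        if n_seg == 0:
            warnings.warn(f"trial {i}: usable duration shorter than one segment")
            out.append([])
            continue
        out.append([trial[:, k * win:(k + 1) * win] for k in range(n_seg)])
    return out


def _band_sos(lo: float, hi: float, fs: float, order: int = 5):
    nyq = fs / 2.0
    if hi >= nyq * 0.999:
        return sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def band_decompose(
    x: np.ndarray, fs: float, spec: BandSpec, method: str = "filter"
) -> np.ndarray:
    """Split ``channels x time`` into ``channels x bands x time``.

    ``method='filter'`` (default) applies a zero-phase 5th-order Butterworth
    band-pass per band.  ``method='stft'`` reconstructs each band from the
    short-time Fourier transform by zeroing out-of-band bins (Hann window).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    spec = spec.clipped(fs)
    out = np.empty((x.shape[0], len(spec), x.shape[1]))
    if method == "filter":
        for b, (_, lo, hi) in enumerate(spec.bands):
            sos = _band_sos(lo, hi, fs)
            out[:, b, :] = sps.sosfiltfilt(sos, x, axis=-1)
    elif method == "stft":
        nper = min(x.shape[1], int(fs))
        stft = sps.ShortTimeFFT(
            sps.windows.hann(nper, sym=False), hop=max(1, nper // 2), fs=fs
        )
        Z = stft.stft(x, axis=-1)  # channels x freqs x frames
        freqs = stft.f
        for b, (_, lo, hi) in enumerate(spec.bands):
            mask = (freqs >= lo) & (freqs < hi)
            rec = stft.istft(Z * mask[None, :, None], k1=x.shape[1])
            out[:, b, :] = rec[..., : x.shape[1]]
    else:
        raise ValueError(f"unknown band decomposition method {method!r}")
    return out


def differential_entropy(band_signal: np.ndarray) -> float:
    """Gaussian differential entropy of a band-limited segment, in nats.

    Uses the maximum-likelihood variance; variance is floored at
    ``VARIANCE_FLOOR`` so a flat segment yields a finite value.
    """
    x = np.asarray(band_signal, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples for a variance estimate")
    var = max(float(np.var(x)), VARIANCE_FLOOR)
    return 0.5 * math.log(2.0 * math.pi * math.e * var)


def _de_of_segments(segs: np.ndarray) -> np.ndarray:
    """Vectorized DE over the trailing time axis."""
    var = np.maximum(segs.var(axis=-1), VARIANCE_FLOOR)
    return 0.5 * np.log(2.0 * math.pi * math.e * var)


def extract_features(
    rec: EEGRecording,
    spec: BandSpec,
    segment_seconds: float,
    method: str = "filter",
) -> DEFeatureTensor:
    """Full pipeline: band-limit trials, segment, and compute DE per cell.

    Band filtering runs on the whole (baseline-stripped) trial before
    segmentation so short windows are not dominated by filter transients.
    """
    spec = spec.clipped(rec.fs)
    win = int(round(segment_seconds * rec.fs))
    if win <= 0 or abs(segment_seconds * rec.fs - win) > 1e-9:
        raise ValueError("segment_seconds * fs must be a positive integer")
    skip = int(round(rec.baseline_seconds * rec.fs))

    feats, labels, index, subjects = [], [], [], []
    for t in range(rec.n_trials):
        trial = rec.trial(t)[:, skip:]
        n_seg = trial.shape[1] // win
        if n_seg == 0:
            warnings.warn(f"trial {t}: usable duration shorter than one segment")
            continue
        banded = band_decompose(trial, rec.fs, spec, method=method)  # C x F x T
        segs = banded[:, :, : n_seg * win].reshape(
            banded.shape[0], len(spec), n_seg, win
        )
        de = _de_of_segments(segs)  # C x F x n_seg
        feats.append(np.moveaxis(de, 2, 0))  # n_seg x C x F
        labels.extend([rec.labels[t]] * n_seg)
        index.extend((t, k) for k in range(n_seg))
        if rec.subject_ids is not None:
            subjects.extend([rec.subject_ids[t]] * n_seg)

    if not feats:
        raise ValueError("no trial produced any segment")
    return DEFeatureTensor(
        features=np.concatenate(feats, axis=0),
        labels=np.asarray(labels),
        sample_index=np.asarray(index, dtype=int),
        band_names=spec.names,
        channel_names=rec.channel_names,
        segment_seconds=segment_seconds,
        subject_ids=np.asarray(subjects) if subjects else None,
    )


def binarize_deap_labels(
    ratings: np.ndarray, dimension: str = "valence", threshold: float = 5.0
) -> np.ndarray:
    """Binarize 1-9 affective ratings: rating > threshold -> class 1.

    ``ratings`` is either a 1-D array of ratings for one dimension or the
    (trials, 4) rating block in (valence, arousal, dominance, liking) order.
    A rating exactly at the threshold goes to the low class.
    """
    dims = {"valence": 0, "arousal": 1, "dominance": 2, "liking": 3}
    r = np.asarray(ratings, dtype=float)
    if r.ndim == 2:
        if dimension not in dims:
            raise ValueError(f"unknown rating dimension {dimension!r}")
        r = r[:, dims[dimension]]
    if np.any((r < 1.0) | (r > 9.0)):
        bad = r[(r < 1.0) | (r > 9.0)][0]
        raise ValueError(f"rating {bad} outside the 1-9 scale")
    return (r > threshold).astype(int)


# ---------------------------------------------------------------------------
# On-disk layouts
# ---------------------------------------------------------------------------


def read_deap(path) -> EEGRecording:
    """Read a DEAP-layout per-subject file (NPZ with ``data`` (40,40,8064)
    and ``labels`` (40,4)); only the 32 EEG channels are retained."""
    with np.load(path) as z:
        if "data" not in z or "labels" not in z:
            raise KeyError(f"{path}: DEAP layout requires 'data' and 'labels' arrays")
        data, labels = z["data"], z["labels"]
    if data.ndim != 3 or data.shape[1] < DEAP_EEG_CHANNEL_COUNT:
        raise ValueError(
            f"{path}: expected trials x >=32 channels x time, got {data.shape}"
        )
    if labels.shape[0] != data.shape[0]:
        raise ValueError(
            f"{path}: {labels.shape[0]} label rows for {data.shape[0]} trials"
        )
    return EEGRecording(
        signal=np.ascontiguousarray(data[:, :DEAP_EEG_CHANNEL_COUNT, :], dtype=float),
        fs=128.0,
        labels=labels,
        baseline_seconds=3.0,
        channel_names=DEAP32_CHANNELS,
    )


def read_seed(path) -> EEGRecording:
    """Read a SEED-layout per-session file (NPZ with ``trial_<k>`` arrays of
    shape channels x time, a ``labels`` vector, and ``fs``)."""

    with np.load(path) as z:
        if "labels" not in z:
            raise KeyError(f"{path}: SEED layout requires a 'labels' array")
        labels = z["labels"]
        fs = float(z["fs"]) if "fs" in z else 200.0
        trials = []
        for k in range(len(labels)):
            key = f"trial_{k}"
            if key not in z:
                raise KeyError(f"{path}: missing {key}")
            trials.append(np.asarray(z[key], dtype=float))
    n_ch = trials[0].shape[0]
    names = SEED62_CHANNELS if n_ch == 62 else None
    return EEGRecording(signal=trials, fs=fs, labels=labels, channel_names=names)


def write_recording(rec: EEGRecording, path) -> None:
    """Generic NPZ schema: ``signal``, ``fs``, ``labels`` (+ baseline)."""
    if not isinstance(rec.signal, np.ndarray):
        raise ValueError("generic layout requires equal-length trials")
    np.savez(
        path,
        signal=rec.signal,
        fs=rec.fs,
        labels=rec.labels,
        baseline_seconds=rec.baseline_seconds,
    )


def read_recording(path) -> EEGRecording:
    with np.load(path) as z:
        return EEGRecording(
            signal=z["signal"],
            fs=float(z["fs"]),
            labels=z["labels"],
            baseline_seconds=float(z["baseline_seconds"]) if "baseline_seconds" in z else 0.0,
        )


def save_features(tensor: DEFeatureTensor, path) -> None:
    arrays = dict(
        features=tensor.features,
        labels=tensor.labels,
        sample_index=tensor.sample_index,
        band_names=np.array(tensor.band_names),
        segment_seconds=tensor.segment_seconds,
    )
    if tensor.channel_names is not None:
        arrays["channel_names"] = np.array(tensor.channel_names)
    if tensor.subject_ids is not None:
        arrays["subject_ids"] = tensor.subject_ids
    np.savez(path, **arrays)


def load_features(path) -> DEFeatureTensor:
    with np.load(path, allow_pickle=False) as z:
        return DEFeatureTensor(
            features=z["features"],
            labels=z["labels"],
            sample_index=z["sample_index"],
            band_names=tuple(str(b) for b in z["band_names"]),
            channel_names=tuple(str(c) for c in z["channel_names"])
            if "channel_names" in z
            else None,
            segment_seconds=float(z["segment_seconds"]),
            subject_ids=z["subject_ids"] if "subject_ids" in z else None,
        )
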