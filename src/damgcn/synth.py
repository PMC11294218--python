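"""Synthetic EEG with analytically known, band- and channel-localized class
structure.

Each channel is a sum of band-limited Gaussian noise processes (filtered
with the same Butterworth filters the feature extractor uses, so generator
and analyzer agree on band definitions by construction).  Class information
is planted in the *variance* of informative (band, channel) cells: variance
is scaled by ``effect_size**class``, so the expected differential-entropy
gap per class step is exactly ``0.5 * ln(effect_size)`` nats.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from damgcn.features import (
    BandSpec,
    DEAP_BANDS,
    SEED_BANDS,
    EEGRecording,
    _band_sos,
)
from damgcn.montage import load_standard_montage

__all__ = ["SynthSpec", "SynthDataset", "generate", "write_fixture"]


@dataclass
class SynthSpec:
    """Recipe for a synthetic multi-subject dataset.

    ``trial_seconds`` is the *total* trial duration including the leading
    ``baseline_seconds`` (which carries no class signal and is dropped by the
    feature extractor).
    """

    n_subjects: int = 2
    n_trials: int = 20
    trial_seconds: float = 10.0
    baseline_seconds: float = 0.0
    fs: float = 128.0
    montage: str = "deap32"
    n_classes: int = 2
    bands: BandSpec = field(default_factory=lambda: DEAP_BANDS)
    informative_bands: tuple[str, ...] = ("gamma",)
    informative_channels: tuple[str, ...] = ("F3", "F4", "O1", "O2")
    effect_size: float = 4.0  # per-class variance multiplier
    noise_sigma: float = 1.0  # base std of every (band, channel) process
    subject_variability: float = 0.0  # sdlog of the per-subject gain
    background_correlation: float = 0.0  # cross-channel correlation of background noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if not 0.0 <= self.background_correlation < 1.0:
            raise ValueError("background_correlation must be in [0, 1)")
        if not self.informative_bands or not self.informative_channels:
            raise ValueError("informative band/channel sets must be non-empty")
        band_names = set(self.bands.names)
        unknown = set(self.informative_bands) - band_names
        if unknown:
            raise ValueError(f"informative bands {unknown} not in band spec")

    @classmethod
    def deap_like(cls, **overrides) -> "SynthSpec":
        """Full DEAP geometry: 40 trials x 63 s at 128 Hz with 3 s baseline."""
        defaults = dict(
            n_subjects=1, n_trials=40, trial_seconds=63.0, baseline_seconds=3.0,
            fs=128.0, montage="deap32", bands=DEAP_BANDS,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def seed_like(cls, **overrides) -> "SynthSpec":
        """SEED geometry: 62 channels at 200 Hz, five bands."""
        defaults = dict(
            n_subjects=1, n_trials=15, trial_seconds=120.0, baseline_seconds=0.0,
            fs=200.0, montage="seed62", n_classes=3, bands=SEED_BANDS,
            informative_channels=("F3", "F4", "O1", "O2"),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SynthDataset:
    spec: SynthSpec
    recordings: list[EEGRecording]  # one per subject
    channel_names: tuple[str, ...]
    cell_variances: np.ndarray  # (classes, channels, bands) planted variances

    def combined(self) -> EEGRecording:
        """All subjects stacked into one recording with per-trial subject ids."""
        sig = np.concatenate([np.asarray(r.signal) for r in self.recordings])
        labels = np.concatenate([r.labels for r in self.recordings])
        subjects = np.concatenate(
            [np.full(r.n_trials, i) for i, r in enumerate(self.recordings)]
        )
        return EEGRecording(
            signal=sig,
            fs=self.spec.fs,
            labels=labels,
            baseline_seconds=self.spec.baseline_seconds,
            channel_names=self.channel_names,
            subject_ids=subjects,
        )


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise of length n."""
    pad = max(int(fs), 64)  # discard filter edge transients
    white = rng.standard_normal(n + 2 * pad)
    sos = _band_sos(lo, hi, fs)
    x = sps.sosfiltfilt(sos, white)[pad:-pad]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate(spec: SynthSpec) -> SynthDataset:
    """Deterministically synthesize the dataset described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    montage = load_standard_montage(spec.montage)
    names = montage.channel_names
    bands = spec.bands.clipped(spec.fs)
    n_time = int(round(spec.trial_seconds * spec.fs))
    n_base = int(round(spec.baseline_seconds * spec.fs))
    upper = {n.upper() for n in spec.informative_channels}
    info_ch = [i for i, n in enumerate(names) if n.upper() in upper]
    if len(info_ch) != len(spec.informative_channels):
        missing = upper - {n.upper() for n in names}
        raise ValueError(f"informative channels not in montage: {sorted(missing)}")
    info_band = [i for i, n in enumerate(bands.names) if n in spec.informative_bands]

    base_var = spec.noise_sigma**2
    cell_var = np.full((spec.n_classes, len(names), len(bands)), base_var)
    for cls in range(spec.n_classes):
        for ci in info_ch:
            for bi in info_band:
                cell_var[cls, ci, bi] = base_var * spec.effect_size**cls

    rho = spec.background_correlation
    info_cells = {(ci, bi) for ci in info_ch for bi in info_band}
    recordings = []
    for _ in range(spec.n_subjects):
        gain = (
            float(np.exp(rng.normal(0.0, spec.subject_variability)))
            if spec.subject_variability > 0
            else 1.0
        )
        labels = np.arange(spec.n_trials) % spec.n_classes  # round-robin classes
        signal = np.zeros((spec.n_trials, len(names), n_time))
        for t in range(spec.n_trials):
            cls = labels[t]
            for bi, (_, lo, hi) in enumerate(bands.bands):
                # optional common source shared by background channels,
                # mimicking the strong cross-channel correlation of scalp EEG
                shared = (
                    _band_noise(rng, n_time, lo, hi, spec.fs) if rho > 0 else None
                )
                for ci in range(len(names)):
                    x = _band_noise(rng, n_time, lo, hi, spec.fs)
                    if shared is not None and (ci, bi) not in info_cells:
                        x = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * x
                    sd = np.sqrt(cell_var[cls, ci, bi]) * gain
                    # baseline span carries no class signal
                    if n_base > 0:
                        x[:n_base] *= spec.noise_sigma * gain / max(sd, 1e-30)
                    signal[t, ci] += sd * x
        recordings.append(
            EEGRecording(
                signal=signal,
                fs=spec.fs,
                labels=labels,
                baseline_seconds=spec.baseline_seconds,
                channel_names=names,
            )
        )
    return SynthDataset(
        spec=spec,
        recordings=recordings,
        channel_names=names,
        cell_variances=cell_var,
    )


def write_fixture(dataset: SynthDataset, layout: str, out_dir) -> list[str]:
    """Write per-subject files in a dataset-shaped layout plus a ground-truth
    sidecar JSON; returns the written paths.

    ``layout='deap'`` pads 8 all-zero non-EEG channels onto the 32 EEG
    channels so channel selection is exercised on read; ``layout='seed'``
    writes per-trial channel x time arrays; ``layout='generic'`` writes the
    plain ``signal/fs/labels`` schema.
    """
    os.makedirs(out_dir, exist_ok=True)
    spec = dataset.spec
    paths = []
    for s, rec in enumerate(dataset.recordings):
        path = os.path.join(out_dir, f"subject_{s:02d}.npz")
        sig = np.asarray(rec.signal)
        if layout == "deap":
            n_trials, n_ch, n_time = sig.shape
            padded = np.zeros((n_trials, n_ch + 8, n_time))
            padded[:, :n_ch, :] = sig
            # rating block: class 0 -> rating 3, class 1 -> rating 7 (etc.)
            ratings = np.ones((n_trials, 4)) * 3.0
            ratings += 4.0 * (rec.labels[:, None] > 0)
            np.savez(path, data=padded, labels=ratings)
        elif layout == "seed":
            arrays = {f"trial_{t}": sig[t] for t in range(sig.shape[0])}
            np.savez(path, labels=rec.labels, fs=rec.fs, **arrays)
        elif layout == "generic":
            np.savez(
                path,
                signal=sig,
                fs=rec.fs,
                labels=rec.labels,
                baseline_seconds=rec.baseline_seconds,
            )
        else:
            raise ValueError(f"unknown fixture layout {layout!r}")
        paths.append(path)

    truth = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
            if k != "bands"
        },
        "bands": [list(b) for b in spec.bands.bands],
        "informative_bands": list(spec.informative_bands),
        "informative_channels": list(spec.informative_channels),
        "cell_variances_shape": list(dataset.cell_variances.shape),
        "expected_de_gap_per_class_step_nats": 0.5 * float(np.log(spec.effect_size)),
    }
    truth_path = os.path.join(out_dir, "ground_truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
    paths.append(truth_path)
    return paths
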