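"""Recording container, file I/O, and the preprocessing filters.

Recordings are multichannel sleep EEG in microvolts with a per-30-s-epoch
hypnogram. Two preprocessing filters are applied downstream:

* a high-pass Butterworth of order 46 with stopband edge 0.5 Hz for the
  connectivity stage, and
* a 0.1-4 Hz band-pass (order-4 Butterworth) for slow-oscillation
  detection and phase estimation.

Both are applied forward-backward (zero phase) so event timing — trough
latency and instantaneous phase — is not shifted by filtering.

The native on-disk format is plain text: a TSV data matrix (one column per
channel, header row of 10-20 labels), a JSON sidecar with the sampling
rate, and a hypnogram text file with one stage label per 30-s epoch. EDF
files are also accepted when the optional ``mne`` dependency is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal

from .channels import ANALYSIS_CHANNELS, normalize_label, region_of

EPOCH_S = 30.0
STAGE_VOCABULARY = ("W", "N1", "N2", "SWS", "REM")
ANALYSIS_FS = 256.0

#: Connectivity high-pass: order 46, stopband edge 0.5 Hz. The order-46
#: design implies a sharp transition; the passband edge (the -3 dB critical
#: frequency of the Butterworth design) is placed at 0.75 Hz, which puts
#: > 150 dB of attenuation at 0.5 Hz.
HIGHPASS_ORDER = 46
HIGHPASS_EDGE_HZ = 0.75
HIGHPASS_STOPBAND_HZ = 0.5

#: Detection band-pass: 0.1-4 Hz, order 4.
DETECTION_BAND_HZ = (0.1, 4.0)
DETECTION_ORDER = 4


@dataclass
class Recording:
    """Channels x samples EEG matrix (µV) with labels, staging and regions."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    stages: list[str]
    region_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be channels x samples matching labels")
        self.channel_labels = [normalize_label(l) for l in self.channel_labels]
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for s in self.stages:
            if s not in STAGE_VOCABULARY:
                raise ValueError(f"unknown stage label {s!r}")
        n_epochs = int(self.duration_s // EPOCH_S)
        if len(self.stages) != n_epochs:
            raise ValueError(
                f"hypnogram has {len(self.stages)} epochs; recording duration "
                f"{self.duration_s:.1f} s allows {n_epochs}"
            )
        if not self.region_map:
            self.region_map = {
                ch: region_of(ch) for ch in ANALYSIS_CHANNELS
                if ch in self.channel_labels
            }

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(normalize_label(label))]

    def analysis_data(self) -> np.ndarray:
        """The 12 analysis channels, rows in the fixed anterior-posterior order."""
        missing = [c for c in ANALYSIS_CHANNELS if c not in self.channel_labels]
        if missing:
            raise ValueError(f"missing analysis channels: {', '.join(missing)}")
        idx = [self.channel_labels.index(c) for c in ANALYSIS_CHANNELS]
        return self.data[idx]


def read_hypnogram(path: str | Path) -> list[str]:
    lines = Path(path).read_text().split()
    return [s.strip() for s in lines if s.strip()]


def read_recording(path: str | Path, hypnogram_path: str | Path) -> Recording:
    """Read a recording (TSV + JSON sidecar, or EDF) and its hypnogram.

    Channel labels are matched case-insensitively to the 10-20 scheme;
    channels outside the montage are retained but excluded from analysis
    sets. All 12 analysis channels must be present.
    """
    path = Path(path)
    stages = read_hypnogram(hypnogram_path)
    if path.suffix.lower() in {".edf", ".bdf"}:
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> µV
        fs = float(raw.info["sfreq"])
        labels = list(raw.ch_names)
    else:
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(path, skiprows=1, delimiter="\t").T
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"sidecar metadata {sidecar} not found")
        meta = json.loads(sidecar.read_text())
        fs = float(meta["fs"])
        if "channel_labels" in meta:
            declared = [normalize_label(l) for l in meta["channel_labels"]]
            if declared != [normalize_label(l) for l in labels]:
                raise ValueError("sidecar channel labels disagree with TSV header")
    labels = [normalize_label(l) for l in labels]
    missing = [c for c in ANALYSIS_CHANNELS if c not in labels]
    if missing:
        raise ValueError(f"missing analysis channels: {', '.join(missing)}")
    return Recording(data=data, fs=fs, channel_labels=labels, stages=stages)


def write_recording(rec: Recording, path: str | Path,
                    hypnogram_path: str | Path | None = None,
                    fmt: str = "%.3f") -> None:
    """Write a recording as TSV + JSON sidecar (and optionally a hypnogram)."""
    path = Path(path)
    header = "\t".join(rec.channel_labels)
    np.savetxt(path, rec.data.T, fmt=fmt, delimiter="\t",
               header=header, comments="")
    path.with_suffix(".json").write_text(json.dumps(
        {"fs": rec.fs, "channel_labels": rec.channel_labels, "unit": "uV"}))
    if hypnogram_path is not None:
        Path(hypnogram_path).write_text("\n".join(rec.stages) + "\n")


def _highpass_sos(fs: float) -> np.ndarray:
    return scipy.signal.butter(HIGHPASS_ORDER, HIGHPASS_EDGE_HZ,
                               btype="highpass", fs=fs, output="sos")


def _bandpass_sos(fs: float) -> np.ndarray:
    return scipy.signal.butter(DETECTION_ORDER, DETECTION_BAND_HZ,
                               btype="bandpass", fs=fs, output="sos")


def resample_recording(rec: Recording, fs_new: float) -> Recording:
    """Polyphase resampling to a new rate (used to reach the 256-Hz analysis rate)."""
    from fractions import Fraction

    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    data = scipy.signal.resample_poly(rec.data, frac.numerator,
                                      frac.denominator, axis=1)
    return Recording(data=data, fs=fs_new, channel_labels=list(rec.channel_labels),
                     stages=list(rec.stages), region_map=dict(rec.region_map))


def highpass_connectivity(rec: Recording) -> Recording:
    """Zero-phase order-46 high-pass (stopband 0.5 Hz) for the connectivity stage.

    Recordings not at 256 Hz are resampled first.
    """
    if rec.fs < 2:
        raise ValueError("sampling rate too low to design the high-pass filter")
    if rec.fs != ANALYSIS_FS:
        rec = resample_recording(rec, ANALYSIS_FS)
    sos = _highpass_sos(rec.fs)
    data = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(data=data, fs=rec.fs, channel_labels=list(rec.channel_labels),
                     stages=list(rec.stages), region_map=dict(rec.region_map))


def bandpass_detection(rec: Recording) -> np.ndarray:
    """Zero-phase 0.1-4 Hz band-pass of every channel (detector/phase input)."""
    sos = _bandpass_sos(rec.fs)
    return scipy.signal.sosfiltfilt(sos, rec.data, axis=1)


def stage_mask(rec: Recording,
               stages_of_interest: set[str] = frozenset({"N2", "SWS"})) -> np.ndarray:
    """Boolean per-sample mask of the epochs in ``stages_of_interest``."""
    for s in stages_of_interest:
        if s not in STAGE_VOCABULARY:
            raise ValueError(f"unknown stage label {s!r}")
    mask = np.zeros(rec.n_samples, dtype=bool)
    epoch_len = int(round(EPOCH_S * rec.fs))
    for i, s in enumerate(rec.stages):
        if s in stages_of_interest:
            mask[i * epoch_len : (i + 1) * epoch_len] = True
    return mask
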