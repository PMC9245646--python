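"""Synthetic sleep-EEG generator with full ground truth.

Emulates the statistical structure the analysis assumes: 22-channel,
256-Hz recordings of alternating Stage-2/SWS blocks, built from

* a stable VAR background process with weak directional coupling between
  channels, scaled to a realistic NREM background amplitude;
* slow-oscillation (SO) templates — a raised-sine down state flanked by
  up-state lobes balanced so the cycle is zero-mean — embedded on a
  per-event channel footprint with per-channel propagation lags. Global
  SOs appear on (nearly) all channels, local SOs only on the seed
  channel's region;
* a Granger-causal coupling boost: inside two windows flanking each SO
  trough (default ±[250, 650] ms), selected off-diagonal VAR coefficients
  are multiplied by a gain, so directed information flow genuinely
  increases pre- and post-trough with a dip at the trough itself. The
  boost windows sit beyond ±250 ms because the 0.5-s analysis window
  integrates flow over ±250 ms around its center: any boost mass inside
  ±250 ms of the trough would raise the trough-centred window as much as
  the flanking ones and erase the dip;
* sleep-spindle bursts (a Hann-windowed 13-Hz sinusoid) overlapping a
  configurable fraction of SOs;
* behavioral improvement ratios with a planted linear dependence on a
  per-subject flow summary.

Everything planted is returned in a :class:`GroundTruth` record, and the
whole generator is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .channels import (MONTAGE_22, REGION_INDEX, REGIONS, SOURCE_CHANNELS,
                       region_of)
from .connectivity import MVARStabilityError, spectral_radius
from .io import EPOCH_S, Recording

#: Approximate anterior-posterior row of each montage channel (for lags).
_AP_ROW = {
    "Fp1": 0, "Fp2": 0,
    "F7": 1, "F3": 1, "Fz": 1, "F4": 1, "F8": 1,
    "T7": 2, "C3": 2, "Cz": 2, "C4": 2, "T8": 2,
    "CP1": 3, "CP2": 3,
    "P7": 4, "P3": 4, "Pz": 4, "P4": 4, "P8": 4,
    "POz": 5, "O1": 6, "O2": 6,
}

MIN_SO_SPACING_S = 4.0


@dataclass
class SimulationConfig:
    """Parameters of one synthetic subject.

    Amplitudes are in µV, durations in the stated units. The defaults
    describe the reference condition: 10-minute recordings, ~2 SOs per
    in-stage minute at -110 µV trough with an 800-ms down state flanked
    by 550-ms up-state lobes (so the full cycle, hence the ±pi phase
    span, fits the ±750-ms window-center range), half global / half
    local footprints, a 5x
    coupling boost in ±200-ms windows centred 450 ms before and after
    each trough, and spindles coupled to half of the SOs.
    """

    n_channels: int = 22
    fs: float = 256.0
    duration_s: float = 600.0
    var_order: int = 2
    base_coupling: np.ndarray | None = None     # (22, 22) lag-1 gains, row=sink
    ar_diag: tuple[float, float] = (0.55, -0.25)
    background_sd_uv: float = 15.0
    so_rate: float = 2.0                        # events/min of N2+SWS
    so_amplitude_uv: float = -110.0
    so_halfwave_ms: float = 800.0
    so_lead_ms: float = 550.0                   # leading up-state lobe
    so_trail_ms: float = 550.0                  # trailing up-state lobe
    fraction_global: float = 0.5
    footprint_global: tuple[str, ...] | None = None   # default: all channels
    propagation_lag_ms: float = 10.0            # per anterior-posterior row step
    coupling_boost: float = 5.0
    boost_centers_ms: tuple[float, ...] = (-450.0, 450.0)
    boost_halfwidth_ms: float = 200.0
    spindle_coupling_fraction: float = 0.5
    spindle_freq_hz: float = 13.0
    spindle_duration_s: float = 0.8
    spindle_amplitude_uv: float = 25.0
    behavior_slope: float = 0.2
    behavior_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 300.0 <= self.so_halfwave_ms <= 1000.0:
            raise ValueError("so_halfwave_ms must lie in [300, 1000]")
        if not 0.0 <= self.spindle_coupling_fraction <= 1.0:
            raise ValueError("spindle_coupling_fraction must lie in [0, 1]")
        if self.so_rate < 0:
            raise ValueError("so_rate must be nonnegative")

    def var_coeffs(self, boosted: bool = False) -> np.ndarray:
        """Stacked (p, N, N) coefficients of the background process."""
        n = self.n_channels
        coupling = self.base_coupling
        if coupling is None:
            coupling = default_base_coupling(n)
        a = np.zeros((self.var_order, n, n))
        gain = self.coupling_boost if boosted else 1.0
        a[0] = np.eye(n) * self.ar_diag[0] + coupling * gain
        if self.var_order > 1:
            a[1] = np.eye(n) * self.ar_diag[1]
        return a


def default_base_coupling(n_channels: int = 22, gain: float = 0.15) -> np.ndarray:
    """Directed lag-1 coupling from each source channel to every analysis
    channel in a more posterior region (anterior drives posterior).

    Restricting the coupling to the anterior-to-posterior direction makes
    the off-diagonal block strictly triangular in the anterior-posterior
    channel order, so the companion eigenvalues — and hence stability —
    are set by the diagonal autoregression alone and are unaffected by
    the coupling gain or its boost.
    """
    coupling = np.zeros((n_channels, n_channels))
    labels = list(MONTAGE_22[:n_channels])
    for src in SOURCE_CHANNELS:
        if src not in labels:
            continue
        j = labels.index(src)
        own_idx = REGION_INDEX[region_of(src)]
        for region, members in REGIONS.items():
            if REGION_INDEX[region] <= own_idx:
                continue
            for ch in members:
                if ch in labels:
                    coupling[labels.index(ch), j] = gain
    return coupling


@dataclass
class PlantedSO:
    """Ground-truth record of one planted slow oscillation."""

    trough_time_s: float
    seed_channel: str
    cluster: str                       # "Global" | "Local"
    channels: tuple[str, ...]          # footprint
    lags_ms: dict[str, float]
    amplitude_uv: float
    coupled: bool = False
    stage: str = "N2"


@dataclass
class GroundTruth:
    """Everything planted in one synthetic subject."""

    so_events: list[PlantedSO] = field(default_factory=list)
    spindle_events: list[tuple[str, float, float]] = field(default_factory=list)
    boost_intervals: list[tuple[float, float]] = field(default_factory=list)
    coupling_boost: float = 1.0
    behavior: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "so_events": [dataclasses.asdict(e) for e in self.so_events],
            "spindle_events": [list(s) for s in self.spindle_events],
            "boost_intervals": [list(b) for b in self.boost_intervals],
            "coupling_boost": self.coupling_boost,
            "behavior": self.behavior,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            so_events=[PlantedSO(**{**e, "channels": tuple(e["channels"])})
                       for e in payload["so_events"]],
            spindle_events=[tuple(s) for s in payload["spindle_events"]],
            boost_intervals=[tuple(b) for b in payload["boost_intervals"]],
            coupling_boost=payload["coupling_boost"],
            behavior=payload["behavior"],
        )


def simulate_var(coeffs: np.ndarray, noise_cov: np.ndarray, n_samples: int,
                 seed: int | np.random.Generator = 0,
                 burn_in: int | None = None) -> np.ndarray:
    """Draw an N x n_samples series from a stable VAR process.

    Raises :class:`MVARStabilityError` when the companion spectral radius
    is >= 1 and ``ValueError`` for a non-positive-definite noise covariance.
    The recursion is initialized with ``burn_in`` discarded samples
    (default ``max(200, 10 p)``).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    rho = spectral_radius(coeffs)
    if rho >= 1.0:
        raise MVARStabilityError(
            f"VAR coefficients are unstable (spectral radius {rho:.4f} >= 1)")
    noise_cov = np.asarray(noise_cov, dtype=float)
    try:
        chol = np.linalg.cholesky(noise_cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise covariance must be symmetric positive definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if burn_in is None:
        burn_in = max(200, 10 * p)
    total = n_samples + burn_in
    innov = chol @ rng.standard_normal((n, total))
    x = np.zeros((n, total))
    for t in range(p, total):
        acc = innov[:, t].copy()
        for k in range(p):
            acc += coeffs[k] @ x[:, t - k - 1]
        x[:, t] = acc
    return x[:, burn_in:]


def _simulate_var_switching(coeff_sets: tuple[np.ndarray, np.ndarray],
                            boost_mask: np.ndarray, noise_chol: np.ndarray,
                            rng: np.random.Generator,
                            burn_in: int = 200) -> np.ndarray:
    """VAR recursion whose coefficients switch per sample (base vs boosted)."""
    base, boosted = coeff_sets
    p, n, _ = base.shape
    total = boost_mask.size + burn_in
    innov = noise_chol @ rng.standard_normal((n, total))
    x = np.zeros((n, total))
    for t in range(p, total):
        a = boosted if (t >= burn_in and boost_mask[t - burn_in]) else base
        acc = innov[:, t].copy()
        for k in range(p):
            acc += a[k] @ x[:, t - k - 1]
        x[:, t] = acc
    return x[:, burn_in:]


def make_so_template(amplitude_uv: float, halfwave_ms: float, fs: float,
                     lead_ms: float = 0.0,
                     trail_ms: float | None = None) -> np.ndarray:
    """One zero-mean SO cycle: raised-sine down state with up-state lobes.

    The negative half-wave of ``halfwave_ms`` (trough equal to
    ``amplitude_uv``) is preceded by an up-state lobe of ``lead_ms`` and
    followed by one of ``trail_ms`` (default: twice the half-wave, i.e. a
    biphasic wave whose positive half has half the amplitude). The lobe
    amplitude ``|A| halfwave / (lead + trail)`` makes the cycle integrate
    to zero. The trough sits ``halfwave_ms / 2`` after the down state's
    first zero crossing.
    """
    if halfwave_ms <= 0:
        raise ValueError("halfwave duration must be positive")
    if trail_ms is None:
        trail_ms = 2.0 * halfwave_ms
    if trail_ms <= 0 or lead_ms < 0:
        raise ValueError("lobe durations must be nonnegative (trail positive)")
    n_neg = int(round(halfwave_ms / 1000.0 * fs))
    n_lead = int(round(lead_ms / 1000.0 * fs))
    n_trail = int(round(trail_ms / 1000.0 * fs))
    up_amp = abs(amplitude_uv) * halfwave_ms / (lead_ms + trail_ms)
    lobe = lambda n, amp: amp * np.sin(np.pi * np.arange(n) / n)  # noqa: E731
    return np.concatenate([
        lobe(n_lead, up_amp),
        lobe(n_neg, amplitude_uv),
        lobe(n_trail, up_amp),
    ])


def template_trough_offset(halfwave_ms: float, fs: float,
                           lead_ms: float = 0.0) -> int:
    """Sample offset of the trough within :func:`make_so_template` output."""
    return (int(round(lead_ms / 1000.0 * fs))
            + int(round(halfwave_ms / 1000.0 * fs)) // 2)


DISTRACTOR_KINDS = ("shallow", "short", "long", "small_p2p")


def make_distractor(kind: str, fs: float) -> np.ndarray:
    """SO-like waveforms that each violate a named detection criterion.

    ``shallow``   trough -50 µV (amplitude criterion) but peak-to-peak 95 µV;
    ``short``     200-ms negative half-wave (below the 300-ms bound);
    ``long``      1.2-s negative half-wave (above the 1-s bound);
    ``small_p2p`` trough -60 µV with a +5 µV rebound: peak-to-peak 65 µV
                  (fails the range criterion; with zero-crossing-delimited
                  candidates any wave failing it also fails the amplitude
                  criterion, since trough <= -80 forces peak-to-peak >= 80).
    """
    if kind == "shallow":
        n = int(round(0.5 * fs))
        t = np.arange(n) / n
        return np.concatenate([-50 * np.sin(np.pi * t), 45 * np.sin(np.pi * t)])
    if kind == "short":
        return make_so_template(-100.0, 200.0, fs)
    if kind == "long":
        return make_so_template(-100.0, 1200.0, fs)
    if kind == "small_p2p":
        n = int(round(0.5 * fs))
        t = np.arange(n) / n
        return np.concatenate([-60 * np.sin(np.pi * t), 5 * np.sin(np.pi * t)])
    raise ValueError(f"unknown distractor kind {kind!r}")


def plant(signal: np.ndarray, waveform: np.ndarray, start_sample: int) -> None:
    """Add a waveform in place, clipped at the record edges."""
    n = signal.shape[-1]
    lo = max(start_sample, 0)
    hi = min(start_sample + waveform.size, n)
    if hi > lo:
        signal[..., lo:hi] += waveform[lo - start_sample : hi - start_sample]


def _alternating_stages(duration_s: float, block_epochs: int = 10) -> list[str]:
    """Alternating 5-min Stage-2 / SWS blocks covering the recording."""
    n_epochs = int(duration_s // EPOCH_S)
    stages = []
    for i in range(n_epochs):
        stages.append("N2" if (i // block_epochs) % 2 == 0 else "SWS")
    return stages


def _draw_trough_times(rng: np.random.Generator, n_events: int,
                       duration_s: float, edge_margin_s: float) -> np.ndarray:
    """Troughs uniform over the interior with >= 4-s spacing (rejection)."""
    times: list[float] = []
    for _ in range(200 * max(n_events, 1)):
        if len(times) == n_events:
            break
        t = rng.uniform(edge_margin_s, duration_s - edge_margin_s)
        if all(abs(t - u) >= MIN_SO_SPACING_S for u in times):
            times.append(t)
    if len(times) < n_events:
        raise ValueError(
            "could not place SOs with >= 4-s spacing; lower so_rate or "
            "lengthen the recording")
    return np.array(sorted(times))


def _local_footprint(seed_channel: str) -> tuple[str, ...]:
    return REGIONS[region_of(seed_channel)]


def simulate_subject(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic subject: recording plus ground truth.

    Deterministic given ``config.seed``. Raises when the SO rate implies
    inter-trough spacing below 4 s or the (base or boosted) VAR
    coefficients are unstable.
    """
    if config.so_rate > 0 and 60.0 / config.so_rate < MIN_SO_SPACING_S:
        raise ValueError(
            f"so_rate {config.so_rate}/min implies spacing "
            f"{60.0 / config.so_rate:.1f} s < {MIN_SO_SPACING_S} s")
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = config.n_channels
    labels = list(MONTAGE_22[:n])
    n_samples = int(round(config.duration_s * fs))
    stages = _alternating_stages(config.duration_s)

    base = config.var_coeffs(boosted=False)
    boosted = config.var_coeffs(boosted=True)
    for name, coeffs in (("base", base), ("boosted", boosted)):
        rho = spectral_radius(coeffs)
        if rho >= 1.0:
            raise MVARStabilityError(
                f"{name} VAR coefficients unstable (spectral radius {rho:.3f})")

    # --- SO schedule ---------------------------------------------------
    minutes = len(stages) * EPOCH_S / 60.0
    n_sos = int(round(config.so_rate * minutes))
    span_s = (config.so_lead_ms + config.so_halfwave_ms
              + config.so_trail_ms) / 1000.0
    edge_margin = max(2.0, span_s)
    troughs = (_draw_trough_times(rng, n_sos, config.duration_s, edge_margin)
               if n_sos else np.array([]))
    n_global = int(round(config.fraction_global * n_sos))
    is_global = np.zeros(n_sos, dtype=bool)
    if n_sos:
        is_global[rng.choice(n_sos, size=n_global, replace=False)] = True

    template = make_so_template(config.so_amplitude_uv, config.so_halfwave_ms,
                                fs, lead_ms=config.so_lead_ms,
                                trail_ms=config.so_trail_ms)
    trough_off = template_trough_offset(config.so_halfwave_ms, fs,
                                        lead_ms=config.so_lead_ms)
    footprint_global = (tuple(config.footprint_global)
                        if config.footprint_global else tuple(labels))

    so_events: list[PlantedSO] = []
    so_signal = np.zeros((n, n_samples))
    boost_mask = np.zeros(n_samples, dtype=bool)
    boost_intervals: list[tuple[float, float]] = []
    epoch_len = int(round(EPOCH_S * fs))
    for i, t in enumerate(troughs):
        seed_ch = SOURCE_CHANNELS[int(rng.integers(len(SOURCE_CHANNELS)))]
        footprint = footprint_global if is_global[i] else _local_footprint(seed_ch)
        lags = {
            ch: config.propagation_lag_ms * abs(_AP_ROW[ch] - _AP_ROW[seed_ch])
            for ch in footprint
        }
        for ch, lag in lags.items():
            trough_sample = int(round((t + lag / 1000.0) * fs))
            plant(so_signal[labels.index(ch)], template,
                  trough_sample - trough_off)
        for c in config.boost_centers_ms:
            lo = t + (c - config.boost_halfwidth_ms) / 1000.0
            hi = t + (c + config.boost_halfwidth_ms) / 1000.0
            boost_mask[max(int(lo * fs), 0) : min(int(hi * fs), n_samples)] = True
            boost_intervals.append((lo, hi))
        stage = stages[min(int(t // EPOCH_S), len(stages) - 1)]
        so_events.append(PlantedSO(
            trough_time_s=float(t), seed_channel=seed_ch,
            cluster="Global" if is_global[i] else "Local",
            channels=footprint, lags_ms=lags,
            amplitude_uv=config.so_amplitude_uv, stage=stage,
        ))

    # --- spindles ------------------------------------------------------
    spindles: list[tuple[str, float, float]] = []
    n_coupled = int(round(config.spindle_coupling_fraction * n_sos))
    coupled_idx = (rng.choice(n_sos, size=n_coupled, replace=False)
                   if n_sos else np.array([], dtype=int))
    spindle_n = int(round(config.spindle_duration_s * fs))
    burst = (config.spindle_amplitude_uv
             * np.hanning(spindle_n)
             * np.sin(2 * np.pi * config.spindle_freq_hz
                      * np.arange(spindle_n) / fs))
    spindle_signal = np.zeros((n, n_samples))
    for i in coupled_idx:
        so_events[int(i)].coupled = True
        start_s = troughs[int(i)] + 0.1
        ch = so_events[int(i)].seed_channel
        plant(spindle_signal[labels.index(ch)], burst, int(round(start_s * fs)))
        spindles.append((ch, float(start_s),
                         float(start_s + config.spindle_duration_s)))

    # --- background ----------------------------------------------------
    noise_chol = np.eye(n)
    background = _simulate_var_switching((base, boosted), boost_mask,
                                         noise_chol, rng)
    base_sd = np.sqrt(np.mean(np.var(background, axis=1)))
    background *= config.background_sd_uv / base_sd

    data = background + so_signal + spindle_signal
    rec = Recording(data=data, fs=fs, channel_labels=labels, stages=stages)
    gt = GroundTruth(so_events=so_events, spindle_events=spindles,
                     boost_intervals=boost_intervals,
                     coupling_boost=config.coupling_boost)
    return rec, gt


def generate_behavior(flow_summaries: np.ndarray, slope: float,
                      noise_sd: float, seed: int = 0) -> np.ndarray:
    """Per-subject improvement ratios with a planted linear flow dependence.

    improvement_i = 1 + slope * z(flow_i) + eps_i, eps ~ N(0, noise_sd^2).
    """
    flow = np.asarray(flow_summaries, dtype=float)
    if flow.size < 3:
        raise ValueError("need at least 3 subjects")
    sd = flow.std(ddof=0)
    if sd == 0:
        raise ValueError("flow summaries have zero variance; cannot standardize")
    z = (flow - flow.mean()) / sd
    rng = np.random.default_rng(seed)
    return 1.0 + slope * z + rng.normal(0.0, noise_sd, size=flow.size)


def write_behavior_csv(path: str | Path, subjects: list[str],
                       improvement: np.ndarray,
                       presleep: np.ndarray | None = None) -> None:
    """Behavioral table (subject_id, presleep, postsleep) as CSV.

    Presleep accuracies default to 0.75; postsleep is presleep times the
    improvement ratio.
    """
    if presleep is None:
        presleep = np.full(len(subjects), 0.75)
    with open(path, "w") as fh:
        fh.write("subject_id,presleep,postsleep\n")
        for sid, pre, ratio in zip(subjects, presleep, improvement):
            fh.write(f"{sid},{pre:.6f},{pre * ratio:.6f}\n")
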