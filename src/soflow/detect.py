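"""Slow-oscillation detection and matched non-SO control windows.

Candidate waves are delimited by zero crossings of the 0.1-4 Hz filtered
trace: a candidate starts at a positive-to-negative crossing, its negative
half-wave ends at the next negative-to-positive crossing, and the
candidate ends at the following positive-to-negative crossing. An SO is
emitted iff all four criteria hold:

1. trough amplitude <= -80 µV,
2. peak-to-peak range over the candidate >= 80 µV,
3. negative half-wave duration (first to second zero crossing) between
   300 ms and 1 s,
4. total candidate span at most 10 s,

and the trough sample lies inside a Stage-2/SWS epoch. Control windows
are 0.5-s segments on a random source channel, fully in-stage and more
than 10 s from every detected SO trough on any channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import SOURCE_CHANNELS

TROUGH_THRESHOLD_UV = -80.0
P2P_THRESHOLD_UV = 80.0
HALFWAVE_BOUNDS_S = (0.3, 1.0)
MAX_SPAN_S = 10.0
NON_SO_MARGIN_S = 10.0
NON_SO_WINDOW_S = 0.5


@dataclass
class SOEvent:
    """One detected slow oscillation on one channel."""

    channel: str
    trough_time: float          # s
    trough_amplitude: float     # µV, negative
    peak_to_peak: float         # µV
    zc_first: float             # s, start of negative half-wave
    zc_second: float            # s, end of negative half-wave
    span_start: float           # s, candidate start
    span_end: float             # s, candidate end
    stage: str = "N2"

    def validate(self) -> None:
        """Re-check the SO criteria independently of the detector's logic."""
        if self.trough_amplitude > TROUGH_THRESHOLD_UV:
            raise ValueError("trough amplitude above -80 µV")
        if self.peak_to_peak < P2P_THRESHOLD_UV:
            raise ValueError("peak-to-peak below 80 µV")
        dur = self.zc_second - self.zc_first
        if not HALFWAVE_BOUNDS_S[0] <= dur <= HALFWAVE_BOUNDS_S[1]:
            raise ValueError("negative half-wave outside [300 ms, 1 s]")
        if self.span_end - self.span_start > MAX_SPAN_S:
            raise ValueError("candidate span above 10 s")
        if not self.zc_first < self.trough_time < self.zc_second:
            raise ValueError("trough outside the negative half-wave")


@dataclass
class NonSOWindow:
    """A 0.5-s control window far from every SO trough."""

    channel: str
    center_time: float
    stage: str
    length: float = NON_SO_WINDOW_S


def _zero_crossings(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of positive-to-negative and negative-to-positive crossings.

    A crossing index i marks the first sample of the new sign; exact zeros
    adopt the sign of the preceding sample so they do not create spurious
    crossings.
    """
    sign = np.sign(x)
    for i in range(1, sign.size):  # propagate through exact zeros
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    d = np.diff(sign)
    pos_to_neg = np.nonzero(d < 0)[0] + 1
    neg_to_pos = np.nonzero(d > 0)[0] + 1
    return pos_to_neg, neg_to_pos


def detect_sos(filtered: np.ndarray, mask: np.ndarray, fs: float,
               channel: str = "", stages: list[str] | None = None) -> list[SOEvent]:
    """Detect SOs in one channel of the 0.1-4 Hz filtered trace.

    ``mask`` is the per-sample Stage-2/SWS mask. Events are returned
    sorted by trough time; if overlapping candidates ever arise the deeper
    trough wins.
    """
    filtered = np.asarray(filtered, dtype=float)
    p2n, n2p = _zero_crossings(filtered)
    events: list[SOEvent] = []
    for start in p2n:
        ups = n2p[n2p > start]
        if ups.size == 0:
            continue
        zc2 = ups[0]
        downs = p2n[p2n > zc2]
        end = downs[0] if downs.size else filtered.size - 1
        neg = filtered[start:zc2]
        if neg.size == 0:
            continue
        trough_idx = start + int(np.argmin(neg))
        trough = filtered[trough_idx]
        segment = filtered[start:end + 1]
        p2p = float(segment.max() - segment.min())
        halfwave_s = (zc2 - start) / fs
        span_s = (end - start) / fs
        if trough > TROUGH_THRESHOLD_UV:
            continue
        if p2p < P2P_THRESHOLD_UV:
            continue
        if not HALFWAVE_BOUNDS_S[0] <= halfwave_s <= HALFWAVE_BOUNDS_S[1]:
            continue
        if span_s > MAX_SPAN_S:
            continue
        if not mask[trough_idx]:
            continue
        stage = "N2"
        if stages is not None:
            stage = stages[min(int(trough_idx / fs // 30), len(stages) - 1)]
        events.append(SOEvent(
            channel=channel,
            trough_time=trough_idx / fs,
            trough_amplitude=float(trough),
            peak_to_peak=p2p,
            zc_first=start / fs,
            zc_second=zc2 / fs,
            span_start=start / fs,
            span_end=end / fs,
            stage=stage,
        ))
    # overlap resolution: deeper trough wins
    events.sort(key=lambda e: e.trough_time)
    kept: list[SOEvent] = []
    for ev in events:
        if kept and ev.span_start < kept[-1].span_end:
            if ev.trough_amplitude < kept[-1].trough_amplitude:
                kept[-1] = ev
            continue
        kept.append(ev)
    return kept


def detect_all_channels(filtered: np.ndarray, mask: np.ndarray, fs: float,
                        labels: list[str],
                        stages: list[str] | None = None) -> list[SOEvent]:
    """Run the detector on every channel of a filtered matrix."""
    events: list[SOEvent] = []
    for row, label in zip(filtered, labels):
        events.extend(detect_sos(row, mask, fs, channel=label, stages=stages))
    events.sort(key=lambda e: (e.trough_time, e.channel))
    return events


def sample_non_so_windows(all_so_events: list[SOEvent], mask: np.ndarray,
                          fs: float, n_windows: int, seed: int = 0,
                          stages: list[str] | None = None) -> list[NonSOWindow]:
    """Randomized 0.5-s control windows, one per SO by convention.

    Channels are drawn uniformly from the four sources; centers uniformly
    from samples > 10 s away from every SO trough on any channel, with the
    window fully inside an N2/SWS epoch.
    """
    rng = np.random.default_rng(seed)
    half = int(round(NON_SO_WINDOW_S / 2 * fs))
    eligible = mask.copy()
    # window must fit inside the in-stage region
    ok = np.ones_like(eligible)
    for off in range(-half, half + 1):
        ok &= np.roll(eligible, -off)
    eligible = ok
    eligible[:half] = False
    eligible[-half:] = False
    margin = int(round(NON_SO_MARGIN_S * fs))
    for ev in all_so_events:
        t = int(round(ev.trough_time * fs))
        eligible[max(t - margin, 0): t + margin + 1] = False
    candidates = np.nonzero(eligible)[0]
    if candidates.size == 0:
        raise ValueError(
            f"no eligible non-SO positions: every sample is within "
            f"{NON_SO_MARGIN_S} s of an SO trough or out of stage")
    centers = rng.choice(candidates, size=n_windows, replace=True)
    channels = rng.choice(SOURCE_CHANNELS, size=n_windows, replace=True)
    windows = []
    for c, ch in zip(centers, channels):
        stage = "N2"
        if stages is not None:
            stage = stages[min(int(c / fs // 30), len(stages) - 1)]
        windows.append(NonSOWindow(channel=str(ch), center_time=c / fs,
                                   stage=stage))
    return windows


def write_events_bed(events: list[SOEvent], path) -> None:
    """BED-like interval export: 0-based half-open spans in milliseconds."""
    with open(path, "w") as fh:
        for e in events:
            start = int(round(e.span_start * 1000))
            end = int(round(e.span_end * 1000)) + 1
            fh.write(f"{e.channel}\t{start}\t{end}\tSO\t{e.trough_amplitude:.1f}\n")


def events_to_rows(events: list[SOEvent], subject: str = "") -> list[dict]:
    """Long-format rows for CSV export."""
    return [{
        "subject": subject, "channel": e.channel,
        "trough_time_s": e.trough_time, "trough_uv": e.trough_amplitude,
        "p2p_uv": e.peak_to_peak, "zc1_s": e.zc_first, "zc2_s": e.zc_second,
        "stage": e.stage,
    } for e in events]
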