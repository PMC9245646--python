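"""End-to-end orchestration: detect -> cluster/couple -> connectivity ->
phase -> peaks -> statistics, with a self-contained synthetic demo.

The pipeline consumes a recording + hypnogram (+ optional spindle list
and behavioral table), runs every stage with the reference parameters
(order p=13, 0.5-s windows, 2-sample stride, pi/64 phase grid, ±400-ms
footprint tolerance, 200 clustering restarts) and writes tidy CSV tables
plus a JSON manifest of every active setting and seed. Reruns with an
identical config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clu
from . import connectivity as conn
from . import detect as det
from . import io as sio
from . import phase as ph
from . import simulate as sim
from . import stats as st
from .channels import SOURCE_CHANNELS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis parameters; defaults reproduce the reference pipeline."""

    out_dir: str = "soflow_out"
    order: int = conn.DEFAULT_ORDER          # MVAR order p
    n_freq_bins: int = 128
    mvar_method: str = "vm"                  # short-window estimator
    freq_average: str = "magnitude"
    taper: bool = True
    footprint_tolerance_s: float = clu.FOOTPRINT_TOLERANCE_S
    clustering_reps: int = clu.DEFAULT_RESTARTS
    cluster_per_stage: bool = False      # cluster N2 and SWS separately
    reselect_order: bool = False
    order_max: int = 20
    seed: int = 0

    def to_manifest(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SubjectResult:
    """All per-subject tables produced by the analysis stages."""

    subject: str
    events: list[det.SOEvent]
    cluster_names: np.ndarray | None
    coupled: np.ndarray
    phase_series: list[ph.PhaseSeries] = field(default_factory=list)
    peaks: list[ph.PeakRecord] = field(default_factory=list)
    non_so_outflow: pd.DataFrame = field(default_factory=pd.DataFrame)
    skipped: list[str] = field(default_factory=list)


def analyze_subject(rec: sio.Recording, subject: str, config: RunConfig,
                    spindle_events: list[tuple[str, float, float]] | None = None,
                    ) -> SubjectResult:
    """Run detection, clustering, connectivity and phase stages on one subject."""
    rng = np.random.default_rng(config.seed)
    freqs = conn.default_freq_grid(config.n_freq_bins)
    hp = sio.highpass_connectivity(rec)
    filtered = sio.bandpass_detection(rec)
    mask = sio.stage_mask(rec)

    events = det.detect_all_channels(filtered, mask, rec.fs,
                                     rec.channel_labels, rec.stages)
    logger.info("%s: %d SOs detected", subject, len(events))

    cluster_names = None
    if events:
        footprints = clu.build_footprints(events, rec.channel_labels,
                                          config.footprint_tolerance_s)
        groups = [list(range(len(events)))]
        if config.cluster_per_stage:
            groups = [[i for i, e in enumerate(events) if e.stage == stage]
                      for stage in ("N2", "SWS")]
        cluster_names = np.empty(len(events), dtype=object)
        try:
            for idx in groups:
                if not idx:
                    continue
                model = clu.kmeans_hamming([footprints[i] for i in idx],
                                           reps=config.clustering_reps,
                                           seed=int(rng.integers(2**31)))
                cluster_names[idx] = model.cluster_names()
        except ValueError as exc:
            logger.warning("%s: clustering skipped (%s)", subject, exc)
            cluster_names = None
    coupled = clu.flag_coupling(events, spindle_events or [])

    data12 = hp.analysis_data()
    p = config.order
    if config.reselect_order:
        n_window = int(round(conn.WINDOW_S * rec.fs))
        starts = rng.choice(max(data12.shape[1] - n_window, 1),
                            size=min(20, max(data12.shape[1] // n_window, 1)))
        wins = [data12[:, s:s + n_window] for s in starts]
        p = conn.select_order_aic(wins, config.order_max, method=config.mvar_method)
        logger.info("%s: AIC-selected order p=%d", subject, p)

    # SO phase comes from the 0.1-4 Hz trace of the raw recording (the
    # high-passed connectivity data has the SO wave itself removed)
    phase_input = filtered
    half = int(round(conn.EPOCH_HALF_S * rec.fs))
    result = SubjectResult(subject=subject, events=events,
                           cluster_names=cluster_names, coupled=coupled)
    source_events = [(i, e) for i, e in enumerate(events)
                     if e.channel in SOURCE_CHANNELS]
    for so_id, ev in source_events:
        trough = int(round(ev.trough_time * rec.fs))
        try:
            qseries = conn.so_epoch_quantifiers(
                data12, rec.fs, trough, p=p, freqs=freqs, so_id=so_id,
                method=config.mvar_method, average=config.freq_average)
        except ValueError as exc:
            result.skipped.append(f"so {so_id}: {exc}")
            continue
        epoch = phase_input[rec.channel_labels.index(ev.channel),
                            trough - half: trough + half]
        try:
            phase = ph.so_phase(epoch, taper=config.taper)
            lo, hi = ph.monotonic_valid_range(phase)
        except (ValueError, ph.EventSkipped) as exc:
            result.skipped.append(f"so {so_id}: {exc}")
            continue
        centers = np.round(qseries[0].window_centers * rec.fs).astype(int) + half
        valid = (centers >= lo) & (centers <= hi)
        center_phase = phase[np.clip(centers, 0, phase.size - 1)]
        meta = {"subject": subject, "so_channel": ev.channel}
        cluster_name = (str(cluster_names[so_id])
                        if cluster_names is not None else None)
        for q in qseries:
            series_specs = [("ALL", q.outflow)]
            series_specs += [(r, v) for r, v in q.to_region.items()]
            for sink, values in series_specs:
                try:
                    s = ph.resample_to_phase(values, center_phase, valid,
                                             source=q.source, sink=sink, **meta)
                except ph.EventSkipped as exc:
                    result.skipped.append(f"so {so_id} {q.source}->{sink}: {exc}")
                    continue
                s.cluster = cluster_name            # type: ignore[attr-defined]
                s.coupled = bool(coupled[so_id])    # type: ignore[attr-defined]
                result.phase_series.append(s)

    # non-SO control windows: one per source-channel SO
    n_windows = len(source_events)
    if n_windows:
        try:
            windows = det.sample_non_so_windows(
                events, mask, rec.fs, n_windows,
                seed=int(rng.integers(2**31)), stages=rec.stages)
        except ValueError as exc:
            logger.warning("%s: non-SO sampling failed (%s)", subject, exc)
            windows = []
        rows = []
        for w in windows:
            center = int(round(w.center_time * rec.fs))
            try:
                outflow, _ = conn.non_so_quantifiers(
                    data12, rec.fs, center, w.channel, p=p, freqs=freqs,
                    method=config.mvar_method, average=config.freq_average)
            except ValueError as exc:
                result.skipped.append(f"non-SO at {w.center_time:.1f}s: {exc}")
                continue
            rows.append({"subject": subject, "source": w.channel,
                         "center_time_s": w.center_time, "stage": w.stage,
                         "outflow": outflow})
        result.non_so_outflow = pd.DataFrame(rows)
    return result


def subject_mean_series(result: SubjectResult,
                        stratify: tuple[str, ...] = ()) -> list[ph.PhaseSeries]:
    """Average per-SO phase series within (so_channel, source, sink) groups,
    optionally stratified by cluster and/or coupling."""
    groups: dict[tuple, list[ph.PhaseSeries]] = {}
    for s in result.phase_series:
        key = [s.so_channel, s.source, s.sink]
        if "cluster" in stratify:
            if getattr(s, "cluster", None) is None:
                continue
            key.append(s.cluster)
        if "coupled" in stratify:
            key.append(getattr(s, "coupled", None))
        groups.setdefault(tuple(key), []).append(s)
    out = []
    for key, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
        mean = ph.average_phase_series(
            members, subject=result.subject, so_channel=key[0],
            source=key[1], sink=key[2])
        if "cluster" in stratify:
            mean.cluster = key[3]                   # type: ignore[attr-defined]
        if "coupled" in stratify:
            mean.coupled = key[-1]                  # type: ignore[attr-defined]
        out.append(mean)
    return out


def build_peak_table(results: list[SubjectResult],
                     stratify: tuple[str, ...] = ()) -> pd.DataFrame:
    """Long-format table of pre/post peak heights with predictor codings."""
    rows = []
    for res in results:
        for series in subject_mean_series(res, stratify):
            try:
                peak = ph.extract_peaks(series)
            except ValueError:
                continue
            for phase_name in ("pre", "post"):
                row = {
                    "subject": peak.subject,
                    "so_channel": peak.so_channel,
                    "source": peak.source,
                    "sink": peak.sink,
                    "phase": phase_name,
                    "phase_code": st.PHASE_CODE[phase_name],
                    "peak_height": (peak.prepeak_value if phase_name == "pre"
                                    else peak.postpeak_value),
                    "peak_phase": (peak.prepeak_phase if phase_name == "pre"
                                   else peak.postpeak_phase),
                    "source_idx": st.source_index(peak.source),
                    "so_channel_idx": st.source_index(peak.so_channel),
                    "D_source_SO": st.d_source_so(peak.source, peak.so_channel),
                }
                if peak.sink != "ALL":
                    row["D_sink_SO"] = st.d_sink_so(peak.sink, peak.so_channel)
                    row["D_source_sink"] = st.d_source_sink(peak.source, peak.sink)
                    row["relative_distance"] = st.relative_distance(
                        peak.sink, peak.source, peak.so_channel)
                if "cluster" in stratify:
                    row["cluster"] = getattr(series, "cluster", None)
                    row["cluster_code"] = st.CLUSTER_CODE.get(row["cluster"])
                if "coupled" in stratify:
                    row["coupled"] = getattr(series, "coupled", None)
                    row["coupling_code"] = st.COUPLING_CODE.get(row["coupled"])
                rows.append(row)
    return pd.DataFrame(rows)


def phase_condition_table(results: list[SubjectResult]) -> tuple[dict, np.ndarray]:
    """Per-subject outflow at the five canonical phases and in non-SO windows."""
    phase_values: dict[str, list[float]] = {k: [] for k in
                                            ph.CANONICAL_PHASE_INDEX}
    non_so = []
    for res in results:
        outflow_series = [s for s in subject_mean_series(res) if s.sink == "ALL"]
        if not outflow_series or res.non_so_outflow.empty:
            continue
        stack = np.vstack([s.values for s in outflow_series])
        counts = np.sum(~np.isnan(stack), axis=0)
        mean = np.where(counts > 0,
                        np.nansum(np.nan_to_num(stack), axis=0)
                        / np.maximum(counts, 1), np.nan)
        for name, idx in ph.CANONICAL_PHASE_INDEX.items():
            phase_values[name].append(float(mean[idx]))
        non_so.append(float(res.non_so_outflow["outflow"].mean()))
    return ({k: np.array(v) for k, v in phase_values.items()}, np.array(non_so))


def make_demo(out_dir: str | Path, seed: int = 0, n_subjects: int = 6,
              duration_s: float = 600.0,
              behavior_slope: float = 0.2,
              behavior_noise_sd: float = 0.05) -> dict:
    """Write a self-contained synthetic study: recordings, hypnograms,
    spindle lists, ground truth, and a behavioral table.

    Subjects differ in their planted coupling boost (evenly spaced in
    [1.5, 4]); the behavioral improvement ratio depends linearly on the
    standardized boost, the true driver of each subject's SO-locked flow.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    boosts = np.linspace(2.0, 8.0, n_subjects)
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    manifest = {"seed": seed, "subjects": {}}
    for sid, boost in zip(subjects, boosts):
        cfg = sim.SimulationConfig(duration_s=duration_s, coupling_boost=boost,
                                   seed=int(rng.integers(2**31)))
        rec, gt = sim.simulate_subject(cfg)
        sio.write_recording(rec, out / f"{sid}.tsv", out / f"{sid}_hypnogram.txt")
        gt.to_json(out / f"{sid}_truth.json")
        with open(out / f"{sid}_spindles.csv", "w") as fh:
            fh.write("channel,start_s,end_s\n")
            for ch, s, e in gt.spindle_events:
                fh.write(f"{ch},{s:.4f},{e:.4f}\n")
        manifest["subjects"][sid] = {"coupling_boost": float(boost),
                                     "seed": cfg.seed}
    if n_subjects >= 3:
        improvement = sim.generate_behavior(boosts, behavior_slope,
                                            behavior_noise_sd,
                                            seed=int(rng.integers(2**31)))
        sim.write_behavior_csv(out / "behavior.csv", subjects, improvement)
    else:
        logger.warning("fewer than 3 subjects: behavioral table not generated")
    (out / "demo_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_spindles_csv(path: str | Path) -> list[tuple[str, float, float]]:
    df = pd.read_csv(path)
    return [(str(r.channel), float(r.start_s), float(r.end_s))
            for r in df.itertuples()]


def run_pipeline(data_dir: str | Path, config: RunConfig) -> Path:
    """Run the full analysis over a demo-style study directory.

    Expects ``<subject>.tsv`` + ``<subject>_hypnogram.txt`` (+ optional
    ``<subject>_spindles.csv``) per subject and ``behavior.csv``. Writes
    all output tables and the run manifest into ``config.out_dir``.
    """
    data_dir = Path(data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setLevel(logging.INFO)
    pkg_logger = logging.getLogger("soflow")
    pkg_logger.addHandler(log_handler)
    if pkg_logger.level == logging.NOTSET:
        pkg_logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(data_dir, out, config)
    finally:
        pkg_logger.removeHandler(log_handler)
        log_handler.close()


def _run_pipeline(data_dir: Path, out: Path, config: RunConfig) -> Path:
    recordings = sorted(data_dir.glob("*.tsv"))
    if not recordings:
        raise FileNotFoundError(f"no recordings (*.tsv) found in {data_dir}")
    behavior_path = data_dir / "behavior.csv"
    behavior = pd.read_csv(behavior_path) if behavior_path.exists() else None
    if behavior is not None:
        behavior = behavior.rename(columns={"subject_id": "subject"})
        behavior["improvement"] = behavior["postsleep"] / behavior["presleep"]

    results = []
    event_rows = []
    footprint_rows = []
    for path in recordings:
        sid = path.stem
        hyp = data_dir / f"{sid}_hypnogram.txt"
        spindle_path = data_dir / f"{sid}_spindles.csv"
        spindles = read_spindles_csv(spindle_path) if spindle_path.exists() else []
        rec = sio.read_recording(path, hyp)
        res = analyze_subject(rec, sid, config, spindle_events=spindles)
        results.append(res)
        rows = det.events_to_rows(res.events, subject=sid)
        for i, row in enumerate(rows):
            row["cluster"] = (str(res.cluster_names[i])
                              if res.cluster_names is not None else "")
            row["coupled"] = bool(res.coupled[i])
        event_rows.extend(rows)
        if res.events:
            for fp in clu.build_footprints(res.events, rec.channel_labels,
                                           config.footprint_tolerance_s):
                frow = {"subject": sid, "so_id": fp.so_index}
                frow.update({ch: int(v) for ch, v in
                             zip(rec.channel_labels, fp.vector)})
                footprint_rows.append(frow)

    pd.DataFrame(event_rows).to_csv(out / "so_events.csv", index=False)
    footprints_df = pd.DataFrame(footprint_rows)
    footprints_df.to_csv(out / "footprints.csv", index=False)
    # per-channel SO occurrence rate within each cluster
    events_df = pd.DataFrame(event_rows)
    if not events_df.empty and events_df["cluster"].ne("").any():
        occurrence = (events_df.groupby(["cluster", "channel"]).size()
                      / events_df.groupby("cluster").size())
        occurrence.rename("occurrence_rate").reset_index() \
            .to_csv(out / "cluster_occurrence.csv", index=False)
    series_rows = []
    for res in results:
        for s in subject_mean_series(res):
            for g, v, n in zip(s.grid, s.values, s.counts):
                if n > 0:
                    series_rows.append({
                        "subject": s.subject, "so_channel": s.so_channel,
                        "source": s.source, "sink": s.sink,
                        "phase_rad": g, "value": v, "n_sos": int(n)})
    pd.DataFrame(series_rows).to_csv(out / "phase_series.csv", index=False)
    peak_table = build_peak_table(results)
    peak_table.to_csv(out / "peak_table.csv", index=False)
    non_so = pd.concat([r.non_so_outflow for r in results
                        if not r.non_so_outflow.empty], ignore_index=True) \
        if any(not r.non_so_outflow.empty for r in results) else pd.DataFrame()
    non_so.to_csv(out / "non_so_outflow.csv", index=False)

    stats_outputs = {}
    phase_vals, nonso_vals = phase_condition_table(results)
    if nonso_vals.size >= 3:
        anova = st.compare_so_vs_nonso(phase_vals, nonso_vals)
        anova.coefficients.to_csv(out / "anova_coefficients.csv", index=False)
        anova.comparisons.to_csv(out / "anova_comparisons.csv", index=False)
        stats_outputs["anova"] = True
    else:
        logger.warning("ANOVA skipped: fewer than 3 subjects with data")
        stats_outputs["anova"] = False

    outflow_peaks = peak_table[peak_table["sink"] == "ALL"]
    n_subjects = outflow_peaks["subject"].nunique() if not peak_table.empty else 0
    if n_subjects >= 2 and len(outflow_peaks) > 8:
        lme = st.peak_height_lme(
            outflow_peaks,
            ["source_idx", "so_channel_idx", "D_source_SO", "phase_code"])
        lme.coefficients.to_csv(out / "lme_outflow.csv", index=False)
        stats_outputs["lme"] = True
    else:
        logger.warning("LME skipped: insufficient subjects or rows")
        stats_outputs["lme"] = False

    if behavior is not None and n_subjects >= 3:
        flow_peaks = peak_table[(peak_table["sink"] != "ALL")
                                & (peak_table["phase"] == "post")]
        flow = flow_peaks.rename(columns={"peak_height": "flow"})
        for grouping in ("D_source_SO", "D_source_sink"):
            res = st.wpa_regressions(flow, behavior, grouping=grouping)
            res.comparisons.to_csv(out / f"wpa_{grouping}.csv", index=False)
        rel = flow.copy()
        rel["rel_sign"] = np.sign(rel["relative_distance"]).astype(int)
        st.wpa_regressions(rel, behavior, grouping="rel_sign") \
            .comparisons.to_csv(out / "wpa_relative_distance.csv", index=False)
        stats_outputs["wpa"] = True
    else:
        logger.warning("WPA regressions skipped: no behavior or too few subjects")
        stats_outputs["wpa"] = False

    manifest = {"config": config.to_manifest(), "stages": stats_outputs,
                "n_subjects": len(results),
                "n_events": int(len(event_rows)),
                "skipped": {r.subject: r.skipped for r in results}}
    blob = json.dumps(manifest, sort_keys=True).encode()
    manifest["manifest_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
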