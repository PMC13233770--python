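"""End-to-end orchestration of the postural-dynamics pipeline.

Stages (each writes versioned artifacts under the working directory and a
machine-readable run log):

``simulate``  — synthetic cohorts (DLC CSVs, ground truth, manifest);
``extract``   — mask, downsample, six morphometric channels, QC,
                normalization, trend decomposition;
``ethogram``  — contraction events, DPE/SePE/StaPE labels, kinematics,
                temporal statistics, transitions;
``eigenshape``— EFD amplitude spectra, static/dynamic eigenciona spaces,
                score trajectories;
``space``     — balanced discovery subset, density noise scan, GMM,
                UMAP embedding, kNN label propagation, dwell times;
``hmm``       — 8-state Gaussian HMM, occupancy/bout-duration fold
                changes, per-condition transition matrices;
``stats``     — condition-level nonparametric comparisons.

All stage parameters live in :class:`PipelineConfig`; defaults are the
reference analysis values (p-cutoff 0.6, 1:5 downsampling, ≥20% QC,
50-frame decomposition period, prominence 0.7 / width 5, 70% major-event
fraction, 2 s bout merge, EFD order 30, 99.9% harmonic energy, ≥85% PCA
variance, UMAP neighbors 50 / min_dist 0.7, 8 HMM states, 5-frame HMM
bout threshold).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import efd as efd_mod
from . import ethogram as eth_mod
from . import io as io_mod
from . import morphometry as morph_mod
from . import state_hmm as hmm_mod
from . import stats as stats_mod
from . import behavior_space as space_mod
from .bodyplan import default_body_plan
from .synthetic import SynthConfig, StimulusConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "ConfigError", "DependencyError", "DataError",
           "run", "SUBCOMMANDS"]

SUBCOMMANDS = ("simulate", "extract", "ethogram", "eigenshape", "space",
               "hmm", "stats", "all")


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


class DataError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    # simulate
    n_control: int = 4
    n_stimulus: int = 3
    n_frames: int = 3600            # 3 min at 20 Hz per synthetic animal
    stimulus_onset_frame: int = 1200
    # extract
    p_cutoff: float = 0.6
    downsample_factor: int = 5
    qc_min_fraction: float = 0.20
    interp_max_gap: int = 20
    decomposition_period: int = 50
    start_fit_frames: int = 25
    trend_max_gap: int = 200
    # ethogram
    sg_window: int = 11
    sg_order: int = 3
    min_prominence: float = 0.7
    min_width: int = 5
    major_fraction: float = 0.70
    quiescence_z: float = 0.5
    min_bout_s: float = 2.0
    # eigenshape
    efd_order: int = 30
    harmonic_energy: float = 0.999
    pca_min_var: float = 0.85
    n_ec: int = 5
    # behavior space
    discovery_target: int = 120_000
    gmm_k_range: tuple = (2, 20)
    umap_neighbors: int = 50
    umap_min_dist: float = 0.7
    knn_k: int = 15
    # hmm
    hmm_states: int = 8
    hmm_min_bout: int = 5
    hmm_restarts: int = 3
    baseline_condition: str = "control"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ConfigError(f"invalid config key(s) {sorted(bad)}; "
                              f"valid keys: {sorted(valid)}")
        return cls(**data)

    def with_overrides(self, overrides: dict) -> "PipelineConfig":
        merged = asdict(self)
        valid = set(merged)
        for key, value in overrides.items():
            if key not in valid:
                raise ConfigError(f"invalid config key {key!r}; "
                                  f"valid keys: {sorted(valid)}")
            current = merged[key]
            if isinstance(current, bool):
                merged[key] = value in ("1", "true", "True")
            elif isinstance(current, int):
                merged[key] = int(value)
            elif isinstance(current, float):
                merged[key] = float(value)
            else:
                merged[key] = value
        return PipelineConfig(**merged)


def _log_run(out: Path, stage: str, cfg: PipelineConfig, t0: float) -> None:
    log_path = out / "run_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {"runs": []}
    log["runs"].append({"stage": stage, "parameters": asdict(cfg),
                        "elapsed_s": round(time.time() - t0, 3)})
    log_path.write_text(json.dumps(log, indent=1))


def _require(out: Path, artifact: str, producer: str) -> Path:
    path = out / artifact
    if not path.exists():
        raise DependencyError(f"missing artifact {artifact!r}; "
                              f"run the {producer!r} stage first")
    return path


# --------------------------------------------------------------------------
# stages

def run_simulate(cfg: PipelineConfig, out: Path) -> None:
    base = SynthConfig(n_frames=cfg.n_frames, seed=cfg.seed)
    recs = simulate_cohort(cfg.n_control, base, condition="control")
    stim = dataclasses.replace(
        base, seed=cfg.seed + 1000,
        stimulus=StimulusConfig(onset_frame=cfg.stimulus_onset_frame))
    recs += simulate_cohort(cfg.n_stimulus, stim,
                            seeds=[cfg.seed + 1000 + i for i in range(cfg.n_stimulus)],
                            condition="poke")
    write_cohort(recs, out / "recordings")


def _load_cohort(cfg: PipelineConfig, out: Path):
    manifest = io_mod.read_manifest(_require(out, "recordings/manifest.csv", "simulate"))
    plan = default_body_plan()
    cohort = []
    for _, row in manifest.iterrows():
        series = io_mod.read_dlc_csv(out / "recordings" / row["path"], plan)
        series.animal_id = row["animal_id"]
        series.condition = row["condition"]
        series.fps = float(row["fps"])
        series.pixel_scale = float(row["pixel_scale_mm_per_px"])
        onset = row["stimulus_onset_frame"]
        series.stimulus_onset = None if pd.isna(onset) else int(onset)
        cohort.append(series)
    if not cohort:
        raise DataError("manifest lists no recordings")
    return cohort, plan


def _prepared_series(cfg: PipelineConfig, series):
    masked = io_mod.mask_low_confidence(series, cfg.p_cutoff)
    return io_mod.downsample(masked, cfg.downsample_factor)


def run_extract(cfg: PipelineConfig, out: Path) -> None:
    cohort, plan = _load_cohort(cfg, out)
    mdir = out / "metrics"
    mdir.mkdir(parents=True, exist_ok=True)
    kept = []
    for series in cohort:
        prepared = _prepared_series(cfg, series)
        metrics = morph_mod.compute_metrics(prepared, plan)
        retain, coverage = io_mod.qc_coverage(metrics, cfg.qc_min_fraction)
        if not retain:
            continue
        cleaned = morph_mod.normalize_and_clean(metrics, cfg.interp_max_gap)
        trend = morph_mod.decompose_trend(cleaned, cfg.decomposition_period,
                                          cfg.start_fit_frames, cfg.trend_max_gap)
        tidy = metrics.to_frame().melt(id_vars=["frame", "time_s"],
                                       var_name="channel", value_name="value")
        tidy.to_csv(mdir / f"{series.animal_id}_metrics_um.csv", index=False)
        pd.DataFrame(trend.channels).assign(frame=np.arange(trend.n_frames)) \
            .to_csv(mdir / f"{series.animal_id}_trend_z.csv", index=False)
        kept.append({"animal_id": series.animal_id, "condition": series.condition,
                     "fps": prepared.fps, "stimulus_onset": prepared.stimulus_onset,
                     **{f"coverage_{k}": v for k, v in coverage.items()}})
    if not kept:
        raise DataError("no recording passed quality control")
    pd.DataFrame(kept).to_csv(mdir / "qc.csv", index=False)


def _load_extracted(cfg: PipelineConfig, out: Path):
    qc = pd.read_csv(_require(out, "metrics/qc.csv", "extract"))
    rows = []
    for _, row in qc.iterrows():
        animal = row["animal_id"]
        metrics = pd.read_csv(out / "metrics" / f"{animal}_metrics_um.csv") \
            .pivot(index="frame", columns="channel", values="value")
        trend = pd.read_csv(out / "metrics" / f"{animal}_trend_z.csv").set_index("frame")
        onset = None if pd.isna(row["stimulus_onset"]) else int(row["stimulus_onset"])
        rows.append((row, metrics, trend, onset))
    return rows


def run_ethogram(cfg: PipelineConfig, out: Path) -> None:
    edir = out / "ethograms"
    edir.mkdir(parents=True, exist_ok=True)
    ethograms, event_rows = [], []
    for row, metrics, trend_df, onset in _load_extracted(cfg, out):
        fps = float(row["fps"])
        trend = morph_mod.TrendSeries(
            channels={c: trend_df[c].to_numpy() for c in trend_df.columns},
            fps=fps, period=cfg.decomposition_period,
            animal_id=row["animal_id"], condition=row["condition"],
            stimulus_onset=onset)
        events_by_channel = {}
        for channel in morph_mod.METRIC_CHANNELS:
            evs = eth_mod.detect_events(trend.channels[channel], channel,
                                        prominence=cfg.min_prominence,
                                        min_width=cfg.min_width,
                                        sg_window=cfg.sg_window,
                                        sg_order=cfg.sg_order)
            evs = eth_mod.grade_events(evs, cfg.major_fraction)
            evs = [eth_mod.event_kinematics(ev, metrics[channel].to_numpy(), fps)
                   for ev in evs]
            events_by_channel[channel] = evs
            event_rows += [{"animal_id": row["animal_id"],
                            "condition": row["condition"], **dataclasses.asdict(ev)}
                           for ev in evs]
        raw = eth_mod.classify_states(events_by_channel, trend,
                                      quiescence_z=cfg.quiescence_z)
        clean = eth_mod.clean_states(raw, cfg.min_bout_s)
        clean.to_frame().to_csv(edir / f"{row['animal_id']}_ethogram.csv", index=False)
        ethograms.append(clean)
    pd.DataFrame(event_rows).to_csv(edir / "events.csv", index=False)
    tm = eth_mod.pool_transitions(ethograms)
    (edir / "transitions.json").write_text(json.dumps({
        "states": list(tm.states), "counts": tm.counts.tolist(),
        "probabilities": tm.probabilities.tolist()}))
    eth_mod.state_probability_timecourse(ethograms) \
        .to_csv(edir / "state_probability_timecourse.csv", index=False)
    stats = {eth.animal_id: eth_mod.temporal_stats(eth) for eth in ethograms}
    pd.DataFrame([
        {"animal_id": a, "state": s, "n_bouts": d[s]["n_bouts"],
         "median_duration_s": float(np.median(d[s]["durations_s"])) if d[s]["n_bouts"] else np.nan,
         "frequency_per_min": d[s]["frequency_per_min"]}
        for a, d in stats.items() for s in eth_mod.STATE_ORDER
    ]).to_csv(edir / "temporal_stats.csv", index=False)


def run_eigenshape(cfg: PipelineConfig, out: Path) -> None:
    cohort, plan = _load_cohort(cfg, out)
    sdir = out / "shape"
    sdir.mkdir(parents=True, exist_ok=True)
    frames_list = []
    for series in cohort:
        prepared = _prepared_series(cfg, series)
        spectra, frames, rejections = efd_mod.frame_spectra(
            prepared.coords, plan, order=cfg.efd_order)
        df = pd.DataFrame(spectra, columns=[f"A{i+1}" for i in range(cfg.efd_order)])
        df.insert(0, "frame", frames)
        df.insert(0, "condition", series.condition)
        df.insert(0, "animal_id", series.animal_id)
        frames_list.append(df)
    allspec = pd.concat(frames_list, ignore_index=True)
    full = allspec[[f"A{i+1}" for i in range(cfg.efd_order)]].to_numpy()
    n_keep = efd_mod.choose_harmonics(full, cfg.harmonic_energy)
    n_keep = min(max(n_keep, 1), 10)  # cap at the reference 10-harmonic spectrum
    keep_cols = [f"A{i+1}" for i in range(n_keep)]
    allspec[["animal_id", "condition", "frame"] + keep_cols] \
        .to_csv(sdir / "amplitude_spectra.csv", index=False)

    X = allspec[keep_cols].to_numpy()
    static = efd_mod.fit_shape_space(X, cfg.pca_min_var, "static", keep_cols)
    deriv = efd_mod.amplitude_derivatives(X, allspec["animal_id"].to_numpy())
    dynamic = efd_mod.fit_shape_space(deriv[np.all(np.isfinite(deriv), axis=1)],
                                      cfg.pca_min_var, "dynamic", keep_cols)
    for name, space in (("static", static), ("dynamic", dynamic)):
        (sdir / f"shape_space_{name}.json").write_text(json.dumps({
            "kind": space.kind, "mean": space.mean.tolist(),
            "scale": space.scale.tolist(), "loadings": space.loadings.tolist(),
            "explained_variance_fraction": space.explained_variance_fraction.tolist(),
            "k": space.k, "feature_names": space.feature_names}))
    scores = efd_mod.project(X, static, n_components=cfg.n_ec)
    score_df = allspec[["animal_id", "condition", "frame"]].copy()
    for i in range(scores.shape[1]):
        score_df[f"EC{i+1}"] = scores[:, i]
    score_df.to_csv(sdir / "ec_scores.csv", index=False)


def _load_scores(out: Path) -> pd.DataFrame:
    return pd.read_csv(_require(out, "shape/ec_scores.csv", "eigenshape"))


def run_space(cfg: PipelineConfig, out: Path) -> None:
    scores = _load_scores(out)
    bdir = out / "space"
    bdir.mkdir(parents=True, exist_ok=True)
    ec_cols = [c for c in scores.columns if c.startswith("EC")]
    X = scores[ec_cols].to_numpy()
    disc = space_mod.balanced_subset(scores["condition"].to_numpy(),
                                     min(cfg.discovery_target, len(X)), cfg.seed)
    scan = space_mod.hdbscan_noise_scan(X[disc][:20000])
    scan.to_csv(bdir / "noise_scan.csv", index=False)
    k_lo, k_hi = cfg.gmm_k_range
    model = space_mod.select_gmm(X[disc], range(k_lo, k_hi + 1), seed=cfg.seed,
                                 discovery_indices=disc)
    model.selection_table.to_csv(bdir / "gmm_selection.csv", index=False)
    disc_labels = model.predict(X[disc])
    labels = np.empty(len(X), dtype=int)
    labels[disc] = disc_labels
    rest = np.setdiff1d(np.arange(len(X)), disc)
    if len(rest):
        labels[rest] = space_mod.propagate_labels(
            X[disc], disc_labels, X[rest], min(cfg.knn_k, len(disc)))
    out_labels = scores[["animal_id", "condition", "frame"]].copy()
    out_labels["cluster"] = labels
    out_labels.to_csv(bdir / "cluster_labels.csv", index=False)
    # embed a bounded subset for visualization
    emb_idx = disc[:20000]
    emb = space_mod.embed_umap(X[emb_idx], min(cfg.umap_neighbors, len(emb_idx) - 1),
                               cfg.umap_min_dist, cfg.seed)
    emb_df = scores.iloc[emb_idx][["animal_id", "condition", "frame"]].copy()
    emb_df[["umap_x", "umap_y"]] = emb.coords
    emb_df["cluster"] = labels[emb_idx]
    emb_df.to_csv(bdir / "embedding.csv", index=False)
    fps = 20.0 / cfg.downsample_factor
    occ = space_mod.occupancy_maps(emb.coords, labels[emb_idx],
                                   scores["animal_id"].to_numpy()[emb_idx],
                                   scores["condition"].to_numpy()[emb_idx], fps)
    dwell = pd.concat({c: d["dwell"] for c, d in occ.items()}, axis=0)
    dwell.to_csv(bdir / "dwell_times_s.csv")


def run_hmm(cfg: PipelineConfig, out: Path) -> None:
    scores = _load_scores(out)
    hdir = out / "hmm"
    hdir.mkdir(parents=True, exist_ok=True)
    ec_cols = [c for c in scores.columns if c.startswith("EC")]
    per_animal = {a: g[ec_cols].to_numpy() for a, g in scores.groupby("animal_id")}
    feats = hmm_mod.build_features(per_animal)
    model, decoded = hmm_mod.fit_hmm(feats, cfg.hmm_states, seed=cfg.seed,
                                     n_restarts=cfg.hmm_restarts,
                                     min_bout=cfg.hmm_min_bout)
    condition_of = dict(scores.groupby("animal_id")["condition"].first())
    fps = 20.0 / cfg.downsample_factor
    metrics = hmm_mod.state_metrics(decoded, condition_of, fps, cfg.hmm_states,
                                    baseline=cfg.baseline_condition
                                    if cfg.baseline_condition in set(condition_of.values())
                                    else None)
    metrics.occupancy.to_csv(hdir / "occupancy.csv")
    metrics.bout_duration.to_csv(hdir / "bout_duration_s.csv")
    if metrics.fold_change is not None:
        metrics.fold_change.to_csv(hdir / "fold_change.csv")
    trans = hmm_mod.hmm_transition_analysis(decoded, condition_of, cfg.hmm_states)
    for cond, entry in trans.items():
        if cond == "differences":
            continue
        pd.DataFrame(entry["frame"]).to_csv(hdir / f"transitions_{cond}.csv",
                                            index=False)
    rows = [{"animal_id": a, "frame": i, "state": int(s)}
            for a, seq in decoded.items() for i, s in enumerate(seq)]
    pd.DataFrame(rows).to_csv(hdir / "decoded_states.csv", index=False)
    (hdir / "model.json").write_text(json.dumps({
        "n_states": model.n_states,
        "transition_matrix": model.transition_matrix.tolist(),
        "means": model.means.tolist(),
        "state_order": model.state_order.tolist(),
        "min_bout": model.min_bout,
        "feature_names": model.feature_names}))


def run_stats(cfg: PipelineConfig, out: Path) -> None:
    stats_path = _require(out, "ethograms/temporal_stats.csv", "ethogram")
    qc = pd.read_csv(_require(out, "metrics/qc.csv", "extract"))
    temporal = pd.read_csv(stats_path).merge(
        qc[["animal_id", "condition"]], on="animal_id")
    gdir = out / "group_stats"
    gdir.mkdir(parents=True, exist_ok=True)
    results = []
    conditions = sorted(temporal["condition"].unique())
    for state in temporal["state"].unique():
        for feature in ("median_duration_s", "frequency_per_min"):
            groups = [temporal[(temporal["state"] == state)
                               & (temporal["condition"] == c)]
                      [feature].dropna().to_numpy() for c in conditions]
            pairs = [(i, j) for i in range(len(conditions))
                     for j in range(i + 1, len(conditions))]
            for i, j in pairs:
                if len(groups[i]) and len(groups[j]):
                    r = stats_mod.mann_whitney(groups[i], groups[j],
                                               (f"{state}:{feature}:{conditions[i]}",
                                                f"{conditions[j]}"))
                    results.append(r)
    stats_mod.comparisons_to_frame(results).to_csv(gdir / "comparisons.csv",
                                                   index=False)
    med = temporal.pivot_table(index="condition", columns="state",
                               values="median_duration_s", aggfunc="median")
    if cfg.baseline_condition in med.index:
        stats_mod.percent_change(med, cfg.baseline_condition) \
            .to_csv(gdir / "percent_change_duration.csv")


STAGES = {"simulate": run_simulate, "extract": run_extract,
          "ethogram": run_ethogram, "eigenshape": run_eigenshape,
          "space": run_space, "hmm": run_hmm, "stats": run_stats}
#: execution order for `all`
STAGE_ORDER = ("simulate", "extract", "ethogram", "eigenshape", "space",
               "hmm", "stats")


def run(subcommand: str, cfg: PipelineConfig, out: str | Path) -> None:
    """Execute one stage (or ``all``) into the working directory ``out``."""
    if subcommand not in SUBCOMMANDS:
        raise ConfigError(f"unknown subcommand {subcommand!r}; "
                          f"choose from {SUBCOMMANDS}")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stages = STAGE_ORDER if subcommand == "all" else (subcommand,)
    for stage in stages:
        t0 = time.time()
        STAGES[stage](cfg, out)
        _log_run(out, stage, cfg, t0)
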