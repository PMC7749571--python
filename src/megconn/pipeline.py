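"""Stage orchestration: simulate -> preprocess -> connect -> metrics -> stats.

Each stage is a pure function of (input files, config, seed) writing plain
files into an output directory; ``run_all`` chains them and records a
reproducibility manifest (config hash, seed, package version, per-file
SHA-256 checksums).  Subjects whose recording contains no clean analysis
window are excluded and listed in the screening report rather than aborting
the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import fc_matrix, threshold_graph
from .graph_metrics import metrics_record
from .group_analysis import run_group_comparison, score_metric_correlations
from .io_core import (
    AnalysisConfig,
    CohortTable,
    ConfigurationError,
    ScreeningError,
    read_cohort,
    read_timeseries,
    write_cohort,
    write_results,
    write_timeseries,
)
from .preprocessing import preprocess_subject
from .synthetic_data import GroundTruth, default_cohort_truth, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict[str, str]] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def record(self, stage: str, paths: list[Path]) -> None:
        self.stages[stage] = {p.name: _sha256(p) for p in sorted(paths)}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: AnalysisConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _subject_files(in_dir: Path) -> list[tuple[Path, Path]]:
    pairs = []
    for sidecar in sorted(in_dir.glob("*.json")):
        if sidecar.name in ("ground_truth.json", "manifest.json"):
            continue
        h5 = sidecar.with_suffix(".h5")
        if h5.exists():
            pairs.append((h5, sidecar))
    if not pairs:
        raise ConfigurationError(f"no subject (.h5, .json) pairs in {in_dir}")
    return pairs


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(
    out_dir: Path,
    seed: int,
    truth: Optional[GroundTruth] = None,
    n_patient: int = 22,
    n_control: int = 18,
    n_channels: int = 9,
    fs: float = 300.0,
    duration_s: float = 60.0,
) -> list[Path]:
    """Write per-subject HDF5 + sidecars, cohort CSV and ground_truth.json."""
    out_dir.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = default_cohort_truth(n_channels=n_channels, seed=seed)
    recordings, cohort, truth_metrics = simulate_cohort(
        truth, n_patient=n_patient, n_control=n_control,
        fs=fs, duration_s=duration_s, seed=seed,
    )
    written = []
    for ts in recordings:
        h5 = out_dir / f"{ts.subject_id}.h5"
        sidecar = out_dir / f"{ts.subject_id}.json"
        write_timeseries(ts, h5, sidecar)
        written += [h5, sidecar]
    cohort_csv = out_dir / "cohort.csv"
    write_cohort(cohort, cohort_csv)
    gt_path = out_dir / "ground_truth.json"
    with open(gt_path, "w") as fh:
        d = dataclasses.asdict(truth)
        d["edges"] = [dataclasses.asdict(e) for e in truth.edges]
        d["score_couplings"] = [dataclasses.asdict(c) for c in truth.score_couplings]
        json.dump(d, fh, indent=1, sort_keys=True)
        fh.write("\n")
    tm_path = out_dir / "truth_metrics.tsv"
    if not truth_metrics.empty:
        write_results(truth_metrics, tm_path)
        written.append(tm_path)
    return written + [cohort_csv, gt_path]


def preprocess_stage(config: AnalysisConfig, in_dir: Path, out_dir: Path) -> list[Path]:
    """Per-subject screening + band decomposition; emits per-band HDF5 and a
    screening report TSV (subject, n_flagged, window_start, status)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    report = []
    written = []
    for h5, sidecar in _subject_files(in_dir):
        ts = read_timeseries(h5, sidecar)
        try:
            window = preprocess_subject(ts, config)
        except ScreeningError as exc:
            logger.warning("excluding subject %s: %s", ts.subject_id, exc)
            report.append({"subject_id": ts.subject_id, "n_flagged": -1,
                           "window_start": -1, "status": "excluded"})
            continue
        out = out_dir / f"{ts.subject_id}_bands.h5"
        with h5py.File(out, "w") as fh:
            fh.attrs["subject_id"] = ts.subject_id
            fh.attrs["group"] = ts.group
            fh.attrs["fs"] = window.fs
            fh.attrs["start"] = window.start
            fh.attrs["stop"] = window.stop
            fh.attrs["channel_labels"] = list(window.channel_labels)
            if window.region_labels:
                fh.attrs["region_labels"] = json.dumps(
                    window.region_labels, sort_keys=True)
            for name, mat in window.band_data.items():
                fh.create_dataset(f"band/{name}", data=mat, track_times=False)
        written.append(out)
        report.append({"subject_id": ts.subject_id,
                       "n_flagged": window.n_flagged,
                       "window_start": window.start, "status": "ok"})
    rep_path = out_dir / "screening.tsv"
    write_results(pd.DataFrame(report), rep_path)
    return written + [rep_path]


def _load_window(path: Path):
    from .preprocessing import CleanWindow

    with h5py.File(path, "r") as fh:
        regions = (json.loads(fh.attrs["region_labels"])
                   if "region_labels" in fh.attrs else None)
        w = CleanWindow(
            subject_id=str(fh.attrs["subject_id"]),
            group=str(fh.attrs["group"]),
            fs=float(fh.attrs["fs"]),
            channel_labels=tuple(str(c) for c in fh.attrs["channel_labels"]),
            start=int(fh.attrs["start"]),
            stop=int(fh.attrs["stop"]),
            data=np.zeros((len(fh.attrs["channel_labels"]), 2)),
            region_labels=regions,
        )
        for name in fh["band"]:
            w.band_data[name] = np.asarray(fh[f"band/{name}"])
    return w


def connect_stage(config: AnalysisConfig, in_dir: Path, out_dir: Path) -> list[Path]:
    """FC matrices + thresholded edge lists per subject and band."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    edge_rows = []
    files = sorted(in_dir.glob("*_bands.h5"))
    if not files:
        raise ConfigurationError(f"no *_bands.h5 files in {in_dir}")
    for path in files:
        window = _load_window(path)
        out = out_dir / path.name.replace("_bands.h5", "_fc.h5")
        with h5py.File(out, "w") as fh:
            fh.attrs["subject_id"] = window.subject_id
            fh.attrs["group"] = window.group
            for bname in sorted(window.band_data):
                cm = fc_matrix(window, bname)
                g = threshold_graph(cm, alpha=config.alpha)
                grp = fh.create_group(bname)
                grp.create_dataset("R", data=cm.R, track_times=False)
                grp.create_dataset("W", data=g.W, track_times=False)
                grp.attrs["K"] = cm.K
                for i, j, w in g.edge_list():
                    from .connectivity import correlation_t, correlation_p

                    edge_rows.append({
                        "subject_id": window.subject_id,
                        "band": bname,
                        "node_i": window.channel_labels[i],
                        "node_j": window.channel_labels[j],
                        "R": w,
                        "TP": correlation_t(w, cm.K),
                        "p": correlation_p(w, cm.K),
                        "sign": "excitatory" if w > 0 else "inhibitory",
                    })
        written.append(out)
    edges_path = out_dir / "edges.tsv"
    if edge_rows:
        write_results(pd.DataFrame(edge_rows), edges_path)
        written.append(edges_path)
    return written


def metrics_stage(config: AnalysisConfig, in_dir: Path, out_path: Path) -> list[Path]:
    """Graph metrics per subject and band from the *_fc.h5 files."""
    rows = []
    files = sorted(in_dir.glob("*_fc.h5"))
    if not files:
        raise ConfigurationError(f"no *_fc.h5 files in {in_dir}")
    from .connectivity import WeightedGraph

    for path in files:
        with h5py.File(path, "r") as fh:
            sid = str(fh.attrs["subject_id"])
            for bname in sorted(fh):
                W = np.asarray(fh[f"{bname}/W"])
                g = WeightedGraph(
                    nodes=tuple(f"ch{i:03d}" for i in range(W.shape[0])),
                    W=W, K=int(fh[bname].attrs["K"]), band=bname,
                    subject_id=sid, alpha=config.alpha, tp_crit=0.0,
                )
                rec = metrics_record(g)
                rows.append({"subject_id": sid, "band": bname, **rec.scalars()})
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_results(pd.DataFrame(rows), out_path)
    return [out_path]


def stats_stage(
    config: AnalysisConfig, metrics_path: Path, cohort_path: Path, out_dir: Path
) -> list[Path]:
    """Group comparisons + score-metric correlations."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_path)
    cohort.metrics = pd.read_csv(metrics_path, sep="\t")
    stats = run_group_comparison(cohort, alpha=config.alpha)
    stats_path = out_dir / "stats.tsv"
    write_results(stats, stats_path)
    written = [stats_path]
    try:
        corr = score_metric_correlations(cohort, alpha=config.alpha)
        if not corr.empty:
            corr_path = out_dir / "correlations.tsv"
            write_results(corr, corr_path)
            written.append(corr_path)
    except Exception as exc:  # degenerate cohorts: correlations are optional
        logger.warning("score-metric correlations skipped: %s", exc)
    return written


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_all(
    config: AnalysisConfig,
    in_dir: str | Path,
    out_dir: str | Path,
    simulate: bool = False,
    seed: Optional[int] = None,
    **simulate_kwargs,
) -> RunManifest:
    """Run every stage; returns (and writes) the manifest.

    With ``simulate=True`` the cohort is generated into ``in_dir`` first;
    otherwise ``in_dir`` must already contain the subject files and
    cohort.csv (checked before any compute).
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    seed = config.seed if seed is None else seed
    manifest = RunManifest(
        config_hash=config_hash(config), seed=seed, version=__version__,
        started=time.time(),
    )
    if simulate:
        files = simulate_stage(in_dir, seed, fs=config.fs,
                               duration_s=config.window_s, **simulate_kwargs)
        manifest.record("simulate", files)
    cohort_csv = in_dir / "cohort.csv"
    if not cohort_csv.exists():
        raise ConfigurationError(f"missing cohort CSV: {cohort_csv}")
    _subject_files(in_dir)  # fail fast before any compute

    pre_dir = out_dir / "preprocessed"
    manifest.record("preprocess", preprocess_stage(config, in_dir, pre_dir))
    fc_dir = out_dir / "connectivity"
    manifest.record("connect", connect_stage(config, pre_dir, fc_dir))
    metrics_path = out_dir / "metrics.tsv"
    manifest.record("metrics", metrics_stage(config, fc_dir, metrics_path))
    manifest.record("stats", stats_stage(config, metrics_path, cohort_csv, out_dir))
    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    return manifest
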