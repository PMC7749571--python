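"""Core data model, readers/writers and configuration.

Everything downstream — preprocessing, connectivity, graph metrics, group
statistics — operates on the containers defined here.  The central object is
:class:`SourceTimeSeries`, one subject's source-level (virtual-sensor)
recording: a channels × samples matrix of magnetic field amplitudes in
picotesla (pT) with a sampling rate in Hz.  Channel order is authoritative
from ``channel_labels``; every derived matrix (band-filtered copies,
connectivity matrices, adjacency matrices) is indexed in that order.

On-disk formats are deliberately plain: HDF5 (dataset ``data``) or delimited
text for matrices, a JSON sidecar for per-subject metadata, CSV for cohort
tables, TSV for results, YAML for configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional

import h5py
import numpy as np
import pandas as pd
import yaml


class MegconnError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(MegconnError):
    """Invalid or missing configuration / metadata."""


class FormatError(MegconnError):
    """Malformed input file (ragged matrix, bad header, ...)."""


class ParameterError(MegconnError):
    """A parameter value outside its valid domain."""


class ScreeningError(MegconnError):
    """Raised when artifact/spike screening leaves no usable data."""


Group = Literal["patient", "control"]
_VALID_GROUPS = ("patient", "control")

Region = Literal["PCC", "frontal", "other"]
_VALID_REGIONS = ("PCC", "frontal", "other")

SCORE_NAMES = ("VCI", "PRI", "WMI", "PSI", "FSIQ")
SCORE_MIN, SCORE_MAX = 40.0, 160.0


# ---------------------------------------------------------------------------
# frequency bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ParameterError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: The canonical seven-band decomposition, delta through fast ripple.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
    BandDefinition("ripple", 80.0, 250.0),
    BandDefinition("fast_ripple", 250.0, 500.0),
)

_BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def band_by_name(name: str) -> BandDefinition:
    try:
        return _BAND_BY_NAME[name]
    except KeyError:
        raise ConfigurationError(f"unknown band name {name!r}") from None


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

@dataclass
class SourceTimeSeries:
    """One subject's source-level multichannel recording (amplitudes in pT).

    Parameters
    ----------
    subject_id : str
    group : {"patient", "control"}
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique labels; defines the authoritative channel order.
    region_labels : mapping channel label -> {"PCC", "frontal", "other"}, optional
        If given it must cover every channel.
    allow_nan : bool
        NaN-containing data is rejected unless this is set.
    """

    subject_id: str
    group: str
    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    region_labels: Optional[dict[str, str]] = None
    allow_nan: bool = False

    def __post_init__(self) -> None:
        if self.group not in _VALID_GROUPS:
            raise ConfigurationError(
                f"group must be one of {_VALID_GROUPS}, got {self.group!r}"
            )
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise FormatError(
                f"data must be 2-D with >=2 channels and >=2 samples, "
                f"got shape {self.data.shape}"
            )
        if not self.fs > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")
        if self.region_labels is not None:
            missing = set(self.channel_labels) - set(self.region_labels)
            if missing:
                raise ConfigurationError(
                    f"region_labels missing channels: {sorted(missing)}"
                )
            bad = set(self.region_labels.values()) - set(_VALID_REGIONS)
            if bad:
                raise ConfigurationError(f"unknown region labels: {sorted(bad)}")
        if not self.allow_nan and not np.isfinite(self.data).all():
            raise FormatError(
                f"subject {self.subject_id}: non-finite samples present "
                "(pass allow_nan=True to accept)"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "SourceTimeSeries":
        """New instance sharing metadata but carrying different samples."""
        return dataclasses.replace(self, data=np.asarray(data, dtype=np.float64))


# ---------------------------------------------------------------------------
# scores and cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectScores:
    """WISC-IV index scores (standard scale, each bounded to [40, 160])."""

    subject_id: str
    VCI: float
    PRI: float
    WMI: float
    PSI: float
    FSIQ: float

    def __post_init__(self) -> None:
        for name in SCORE_NAMES:
            v = float(getattr(self, name))
            if not (SCORE_MIN <= v <= SCORE_MAX):
                raise ParameterError(
                    f"{self.subject_id}: score {name}={v} outside "
                    f"[{SCORE_MIN}, {SCORE_MAX}]"
                )

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in SCORE_NAMES}


SUBJECT_COLUMNS = (
    "subject_id", "group", "age", "sex", "course_months", "n_seizures",
) + SCORE_NAMES

METRIC_COLUMNS = ("subject_id", "band", "SA", "DA", "LA", "CA")


@dataclass
class CohortTable:
    """Per-subject demographics + cognitive scores, plus per-band graph metrics.

    ``subjects`` has one row per subject with the columns in
    :data:`SUBJECT_COLUMNS`; ``metrics`` (optional until the metrics stage has
    run) has one row per (subject, band) with columns :data:`METRIC_COLUMNS`.
    """

    subjects: pd.DataFrame
    metrics: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = set(SUBJECT_COLUMNS) - set(self.subjects.columns)
        if missing:
            raise FormatError(f"cohort table missing columns: {sorted(missing)}")
        ids = self.subjects["subject_id"]
        if ids.duplicated().any():
            raise FormatError("duplicate subject_ids in cohort table")
        bad = set(self.subjects["group"]) - set(_VALID_GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")

    def require_two_groups(self) -> None:
        counts = self.subjects["group"].value_counts()
        if counts.get("patient", 0) < 2 or counts.get("control", 0) < 2:
            raise ParameterError(
                "group comparison requires >=2 subjects per group, have "
                f"{dict(counts)}"
            )

    def group_ids(self, group: str) -> list[str]:
        sel = self.subjects[self.subjects["group"] == group]
        return list(sel["subject_id"])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Pipeline-wide parameters with the study's recording defaults.

    window_s=60 (the clean analysis window), artifact_amp_pT=6 (absolute
    per-sample amplitude screen), notch_hz=50 (mains interference),
    spike_band/spike_z govern the automated stand-in for visual spike
    screening, alpha is the edge/stat significance level.
    """

    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    fs: float = 6000.0
    window_s: float = 60.0
    artifact_amp_pT: float = 6.0
    notch_hz: float = 50.0
    spike_band: tuple[float, float] = (1.0, 70.0)
    spike_z: float = 8.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("at least one band required")
        if self.window_s * self.fs < 3:
            raise ConfigurationError("window_s * fs must be >= 3 samples")
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [
            {"name": b.name, "lo": b.lo, "hi": b.hi} for b in self.bands
        ]
        d["spike_band"] = list(self.spike_band)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        bands = d.pop("bands", None)
        if bands is not None:
            parsed = []
            for b in bands:
                if isinstance(b, str):
                    parsed.append(band_by_name(b))
                else:
                    parsed.append(BandDefinition(b["name"], float(b["lo"]), float(b["hi"])))
            d["bands"] = tuple(parsed)
        if "spike_band" in d:
            d["spike_band"] = tuple(float(x) for x in d["spike_band"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> np.ndarray:
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if "data" not in fh:
                raise FormatError(f"{path}: no 'data' dataset")
            return np.asarray(fh["data"], dtype=np.float64)
    delim = "," if path.suffix == ".csv" else None
    try:
        mat = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse matrix ({exc})") from exc
    return mat


def read_timeseries(path: str | Path, sidecar: str | Path) -> SourceTimeSeries:
    """Read one subject's matrix (HDF5 or delimited text) + JSON sidecar.

    The sidecar must provide ``subject_id``, ``group``, ``fs`` and
    ``channel_labels``; ``region_labels`` is optional.
    """
    path, sidecar = Path(path), Path(sidecar)
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("subject_id", "group", "fs", "channel_labels"):
        if key not in meta:
            raise ConfigurationError(f"sidecar {sidecar} lacks required key {key!r}")
    data = _read_matrix(path)
    return SourceTimeSeries(
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        data=data,
        fs=float(meta["fs"]),
        channel_labels=tuple(meta["channel_labels"]),
        region_labels=dict(meta["region_labels"]) if meta.get("region_labels") else None,
        allow_nan=bool(meta.get("allow_nan", False)),
    )


def write_timeseries(
    ts: SourceTimeSeries, path: str | Path, sidecar: Optional[str | Path] = None
) -> None:
    """Write matrix (format by suffix) and, if requested, the JSON sidecar.

    HDF5 datasets are created with ``track_times=False`` so byte-identical
    re-runs produce byte-identical files.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=ts.data, track_times=False)
    elif path.suffix == ".csv":
        np.savetxt(path, ts.data, delimiter=",", fmt="%.17g")
    else:
        np.savetxt(path, ts.data, delimiter="\t", fmt="%.17g")
    if sidecar is not None:
        meta = {
            "subject_id": ts.subject_id,
            "group": ts.group,
            "fs": ts.fs,
            "channel_labels": list(ts.channel_labels),
            "region_labels": ts.region_labels,
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")


def write_results(table: pd.DataFrame | CohortTable, path: str | Path) -> None:
    """Write a results table as TSV: header row, deterministic column order,
    floats at full precision.  Empty tables are a contract violation."""
    if isinstance(table, CohortTable):
        table = table.subjects
    if not isinstance(table, pd.DataFrame):
        raise ParameterError(f"expected DataFrame or CohortTable, got {type(table)}")
    if table.empty:
        raise ParameterError("refusing to write an empty results table")
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    # round_trip: pandas' fast float parser is off by 1 ulp on some values
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_cohort(path: str | Path) -> CohortTable:
    """Read the cohort CSV (subject_id, group, age, sex, course_months,
    n_seizures, VCI..FSIQ)."""
    df = pd.read_csv(path)
    return CohortTable(subjects=df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.subjects.to_csv(path, index=False, float_format="%.17g")
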