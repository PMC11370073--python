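"""File formats and pipeline configuration.

Raw recordings use a plain-text CSV layout deliberately compatible with
common raw-actigraphy CSV exports: three header lines (device serial,
start time, sample rate), a column-name line, then one x,y,z row per
sample in units of g::

    serial,SIM000
    start_time,2021-05-03T08:00:00
    sample_rate,30
    x,y,z
    0.012,-0.004,0.998

Cohort tables, daily summaries, bout logs and feature tables are ordinary
CSV with documented column names. The pipeline configuration is a single
YAML file holding every numeric constant of the method (sample rate,
window length, non-wear threshold and duration, valid-day/subject rules,
guideline thresholds, forest size, spline quantiles, seeds); CLI flags
override the file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signal import RawRecording

__all__ = [
    "PipelineConfig",
    "ParseError",
    "read_raw_recording",
    "write_raw_recording",
    "read_cohort_table",
    "write_bout_log",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def write_raw_recording(recording: RawRecording, path) -> None:
    """Write a recording in the documented raw CSV layout."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"serial,{recording.serial}\n")
        fh.write(f"start_time,{recording.start_timestamp.isoformat()}\n")
        fh.write(f"sample_rate,{recording.sample_rate:g}\n")
        fh.write("x,y,z\n")
        np.savetxt(fh, recording.samples, delimiter=",", fmt="%.6f")


def read_raw_recording(path, subject_id: str | None = None) -> RawRecording:
    """Parse a raw recording CSV; malformed rows are reported by line number."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise ParseError(f"{path}: truncated header (need 4 header lines)")
    header: dict[str, str] = {}
    for ln, line in enumerate(lines[:3], start=1):
        parts = line.split(",", 1)
        if len(parts) != 2:
            raise ParseError(f"{path}:{ln}: expected 'key,value' header line, got {line!r}")
        header[parts[0].strip()] = parts[1].strip()
    for key in ("serial", "start_time", "sample_rate"):
        if key not in header:
            raise ParseError(f"{path}: missing header field {key!r}")
    try:
        start = datetime.fromisoformat(header["start_time"])
    except ValueError:
        raise ParseError(f"{path}:2: invalid start_time {header['start_time']!r}") from None
    try:
        rate = float(header["sample_rate"])
    except ValueError:
        raise ParseError(f"{path}:3: invalid sample_rate {header['sample_rate']!r}") from None

    samples = []
    for ln, line in enumerate(lines[4:], start=5):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(f"{path}:{ln}: expected 3 comma-separated values, got {line!r}")
        try:
            samples.append([float(v) for v in parts])
        except ValueError:
            raise ParseError(f"{path}:{ln}: non-numeric sample {line!r}") from None
    return RawRecording(
        subject_id=subject_id or header["serial"],
        start_timestamp=start,
        sample_rate=rate,
        samples=np.asarray(samples, dtype=float).reshape(-1, 3),
        serial=header["serial"],
    )


_COHORT_REQUIRED = ("child_id", "sex", "wave", "age_years")
_COHORT_COVARIATES = ("maternal_work", "dwelling", "yard_size", "season", "covid")


def read_cohort_table(path, drop_incomplete: bool = True, logger=None):
    """Read and validate a day-level cohort table.

    Requires the identifier/outcome columns and checks sex coding; rows
    with missing covariate values are dropped (complete-case analysis) with
    the count logged. Duplicate child-wave(-day) keys are an integrity
    error.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    bad_sex = set(df["sex"].astype(str).unique()) - {"male", "female"}
    if bad_sex:
        raise ParseError(f"{path}: invalid sex values {sorted(bad_sex)}")

    keys = ["child_id", "wave"] + (["day_index"] if "day_index" in df.columns else [])
    if df.duplicated(subset=keys).any():
        raise ParseError(f"{path}: duplicate {'-'.join(keys)} rows")

    present_covs = [c for c in _COHORT_COVARIATES if c in df.columns]
    if drop_incomplete and present_covs:
        complete = df[present_covs].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped and logger is not None:
            logger.info("dropped %d rows with incomplete covariates", n_dropped)
        df = df[complete].reset_index(drop=True)
    return df


def write_bout_log(bouts, path) -> None:
    """Ground-truth bout log: label, ISO-8601 start and end."""
    pd.DataFrame(
        [{"label": b.label, "start": b.start.isoformat(), "end": b.end.isoformat()} for b in bouts]
    ).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, in one place.

    Defaults are the method's published constants: 30 Hz sampling, 15-s
    windows, 13 mg non-wear SD threshold sustained >= 30 min, 480 wear
    minutes per valid day, >= 4 valid days with >= 1 weekend day, 180/60
    min guideline thresholds, a 500-tree forest and 4 spline knots at the
    (0.05, 0.35, 0.65, 0.95) age quantiles.
    """

    sample_rate: float = 30.0
    window_s: float = 15.0
    nonwear_sd_threshold: float = 0.013
    nonwear_min_duration: float = 30.0
    valid_day_wear_min: float = 480.0
    min_valid_days: int = 4
    min_weekend_days: int = 1
    tpa_threshold: float = 180.0
    mvpa_threshold: float = 60.0
    n_trees: int = 500
    spline_quantiles: tuple = (0.05, 0.35, 0.65, 0.95)
    covariates: tuple = ("maternal_work", "dwelling", "yard_size", "season", "covid", "wear_minutes")
    marginal_policy: str = "reference"
    seed: int = 0
    # demo-scale synthetic inputs for the end-to-end run
    corpus_subjects: int = 8
    corpus_session_s: float = 300.0
    pipeline_children: int = 2
    cohort_children: int = 150
    output_dir: str = "artifacts"

    def __post_init__(self) -> None:
        for name in (
            "sample_rate", "window_s", "nonwear_sd_threshold", "nonwear_min_duration",
            "valid_day_wear_min", "tpa_threshold", "mvpa_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.spline_quantiles = tuple(self.spline_quantiles)
        self.covariates = tuple(self.covariates)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["spline_quantiles"] = list(self.spline_quantiles)
        d["covariates"] = list(self.covariates)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["spline_quantiles"] = list(self.spline_quantiles)
        d["covariates"] = list(self.covariates)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
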