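"""Reading and writing CGM cohorts as delimited text, plus run configuration.

The on-disk schema is a minimal CSV with a header: a glucose column
(mg/dL or mmol/L), an optional ISO-8601 timestamp column and an optional
subject column.  Traces are assumed contiguous at the declared sampling
period; if timestamps reveal a gap larger than 1.5 sampling periods the
trace is split into contiguous segments (bridging a sensor gap would corrupt
the lag structure of the autocovariance), and the split is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import SamplingSpec
from .estimation import CGMTrace, FitSettings, GlycemicRange, SubjectFit

__all__ = [
    "MGDL_PER_MMOLL",
    "TraceFileSpec",
    "RunConfig",
    "load_config",
    "read_cohort",
    "write_cohort",
    "write_manifest",
    "fits_to_frame",
]

logger = logging.getLogger("cgmplan")

#: Conversion factor between glucose units: 1 mmol/L = 18.016 mg/dL.
MGDL_PER_MMOLL = 18.016

#: A gap longer than this many sampling periods splits a trace into segments.
GAP_FACTOR = 1.5


@dataclass(frozen=True)
class TraceFileSpec:
    """Where and how to read a cohort CSV."""

    path: str | Path
    glucose_col: str = "glucose"
    timestamp_col: str | None = "timestamp"
    subject_col: str | None = "subject_id"
    units: str = "mg/dL"
    sampling: SamplingSpec = SamplingSpec()

    def __post_init__(self) -> None:
        if self.units not in ("mg/dL", "mmol/L"):
            raise ValueError("units must be 'mg/dL' or 'mmol/L'")


@dataclass(frozen=True)
class RunConfig:
    """Run-level settings shared by the CLI subcommands."""

    range_name: str = "tbr"
    max_lag: int = 50
    weights: str = "pairs"
    period_seconds: float = 300.0
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    @property
    def range(self) -> GlycemicRange:
        return GlycemicRange.from_name(self.range_name)

    @property
    def sampling(self) -> SamplingSpec:
        return SamplingSpec(self.period_seconds)

    @property
    def fit_settings(self) -> FitSettings:
        return FitSettings(max_lag=self.max_lag, weights=self.weights)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML/key-value text file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def read_cohort(spec: TraceFileSpec) -> list[CGMTrace]:
    """Read a cohort CSV into one CGMTrace per subject per contiguous segment."""
    path = Path(spec.path)
    df = pd.read_csv(path)
    missing = [
        c
        for c in (spec.glucose_col, spec.timestamp_col, spec.subject_col)
        if c is not None and c not in df.columns
    ]
    # optional columns that are simply absent are tolerated; the glucose column is not
    if spec.glucose_col not in df.columns:
        raise ValueError(f"{path}: missing glucose column {spec.glucose_col!r}")
    missing = [c for c in missing if c != spec.glucose_col]

    glucose = pd.to_numeric(df[spec.glucose_col], errors="coerce")
    bad = glucose.index[glucose.isna() | ~np.isfinite(glucose)]
    if len(bad):
        raise ValueError(
            f"{path}: unparseable glucose value at data row {int(bad[0]) + 2} "
            f"(value {df[spec.glucose_col].iloc[bad[0]]!r})"
        )
    values = glucose.to_numpy(dtype=float)
    if spec.units == "mmol/L":
        values = values * MGDL_PER_MMOLL

    has_ts = spec.timestamp_col is not None and spec.timestamp_col not in missing
    has_subj = spec.subject_col is not None and spec.subject_col not in missing

    seconds = None
    if has_ts:
        try:
            ts = pd.to_datetime(df[spec.timestamp_col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: unparseable timestamp column: {exc}") from exc
        seconds = ts.astype("int64").to_numpy() / 1e9

    subjects = df[spec.subject_col].astype(str).to_numpy() if has_subj \
        else np.repeat("subject", len(df))

    traces: list[CGMTrace] = []
    for subject in pd.unique(subjects):
        mask = subjects == subject
        rows = np.flatnonzero(mask)
        g = values[mask]
        if seconds is None:
            traces.append(CGMTrace(g, spec.sampling, subject_id=str(subject)))
            continue
        t = seconds[mask]
        steps = np.diff(t)
        non_mono = np.flatnonzero(steps <= 0)
        if non_mono.size:
            raise ValueError(
                f"{path}: non-increasing timestamp for subject {subject!r} "
                f"at data row {int(rows[non_mono[0] + 1]) + 2}"
            )
        breaks = np.flatnonzero(steps > GAP_FACTOR * spec.sampling.period_seconds)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [g.size]))
        if breaks.size:
            logger.info(
                "subject %s: %d gap(s) > %.0f s, split into %d segments",
                subject, breaks.size, GAP_FACTOR * spec.sampling.period_seconds,
                starts.size,
            )
        for seg, (a, b) in enumerate(zip(starts, ends)):
            traces.append(
                CGMTrace(g[a:b], spec.sampling, subject_id=str(subject),
                         timestamps=t[a:b], segment=seg)
            )
    return traces


def write_cohort(traces: list[CGMTrace], path: str | Path) -> None:
    """Write traces to the cohort CSV schema (subject_id, [timestamp,] glucose)."""
    frames = []
    for trace in traces:
        frame = pd.DataFrame({"subject_id": trace.subject_id, "glucose": trace.values})
        if trace.timestamps is not None:
            frame.insert(1, "timestamp", pd.to_datetime(trace.timestamps, unit="s"))
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_manifest(path: str | Path, **fields) -> None:
    """Write a JSON provenance manifest (seed, parameters, package version)."""
    from . import __version__

    payload = {"package": "cgmplan", "version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def fits_to_frame(fits: list[SubjectFit]) -> pd.DataFrame:
    """Serialize per-subject fits to a tidy table."""
    return pd.DataFrame(
        [
            {
                "subject_id": f.subject_id,
                "p_hat": f.p_hat,
                "alpha_hat": f.alpha_hat,
                "sigma2_hat": f.sigma2_hat,
                "n_samples": f.n_samples,
                "degenerate": f.degenerate,
                "warning": f.warning,
            }
            for f in fits
        ]
    )
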