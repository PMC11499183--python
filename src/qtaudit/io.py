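"""Interchange formats and run configuration.

CSV is the canonical waveform format: comment lines (``#``) carrying
record metadata (seed, config hash, sampling rate, sex, rhythm), then a
header row of ``time_ms`` plus lead names, one column per lead in mV.
Ground truth travels as a JSON sidecar (``<id>.truth.json``).  Every file
the pipeline writes records the seed and a hash of the configuration so a
run can be reproduced from its artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import UnusableRecordError
from .synth import CohortConfig, ECGRecord, GroundTruth, STANDARD_LEADS


def config_hash(obj) -> str:
    """Short stable hash of a (nested) configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    if isinstance(obj, dict):
        # artifact destinations are not part of the scientific configuration
        obj = {k: v for k, v in obj.items() if k != "out_dir"}
    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    n_records: int = 200
    seed: int = 0
    out_dir: str = "qtaudit_run"
    sample_rate_hz: float = 500.0
    duration_s: float = 10.0
    noise_sd_mv: float = 0.02
    male_threshold_ms: float = 470.0
    female_threshold_ms: float = 480.0
    qrs_cutoff_ms: float = 120.0
    suppression_prob: float = 0.75
    use_truth_fiducials: bool = False
    write_waveforms: bool = False
    cohort: Mapping = field(default_factory=dict)  # CohortConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        kw = dict(
            n_records=self.n_records,
            seed=self.seed,
            sample_rate_hz=self.sample_rate_hz,
            duration_s=self.duration_s,
            noise_sd_mv=self.noise_sd_mv,
        )
        kw.update(self.cohort)
        return CohortConfig(**kw)


def _header_lines(record: ECGRecord, seed, cfg_hash: str) -> list[str]:
    meta = {k: v for k, v in record.meta.items()}
    return [
        f"# record_id={record.record_id}",
        f"# seed={seed}",
        f"# config_hash={cfg_hash}",
        f"# sample_rate_hz={record.sample_rate_hz:g}",
        f"# meta={json.dumps(meta, sort_keys=True, default=str)}",
    ]


def write_record_csv(
    record: ECGRecord,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
    seed: int | None = None,
    cfg_hash: str = "",
) -> Path:
    """Write one record (and its truth sidecar) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{record.record_id}.csv"
    t = record.time_ms
    header = ",".join(["time_ms", *record.lead_names])
    body = np.column_stack([t, record.signals.T])
    with open(path, "w") as fh:
        for line in _header_lines(record, seed, cfg_hash):
            fh.write(line + "\n")
        fh.write(header + "\n")
        np.savetxt(fh, body, fmt="%.6f", delimiter=",")
    if truth is not None:
        with open(out_dir / f"{record.record_id}.truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
    return path


def read_record_csv(path: str | Path) -> tuple[ECGRecord, GroundTruth | None]:
    """Read one waveform CSV (with optional truth sidecar) back."""
    path = Path(path)
    meta: dict = {}
    sample_rate = None
    record_id = path.stem
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            key, _, val = line[1:].strip().partition("=")
            key = key.strip()
            if key == "sample_rate_hz":
                sample_rate = float(val)
            elif key == "record_id":
                record_id = val
            elif key == "meta":
                meta = json.loads(val)
            elif key == "seed":
                meta["seed"] = val
    df = pd.read_csv(path, skiprows=n_comments)
    if "time_ms" not in df.columns:
        raise ValueError(f"{path.name}: missing time_ms header")
    t = df["time_ms"].to_numpy()
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError(f"{path.name}: non-monotone time column")
    if sample_rate is None:
        sample_rate = 1000.0 / float(np.median(np.diff(t)))
    leads = tuple(c for c in df.columns if c != "time_ms")
    unknown = [l for l in leads if l not in STANDARD_LEADS]
    if unknown:
        warnings.warn(
            f"{path.name}: non-standard lead name(s) {unknown}; retained but "
            "excluded from the primary-lead rule", stacklevel=2)
    signals = df[list(leads)].to_numpy().T
    rec = ECGRecord(record_id, sample_rate, leads, signals, meta)
    truth = None
    sidecar = path.with_suffix("").with_suffix(".truth.json")
    sidecar = path.parent / f"{path.stem}.truth.json"
    if sidecar.exists():
        with open(sidecar) as fh:
            truth = GroundTruth.from_dict(json.load(fh))
    return rec, truth


def read_waveforms(
    directory: str | Path,
) -> tuple[list[tuple[ECGRecord, GroundTruth | None]], dict[str, str]]:
    """Read every waveform CSV in a directory.

    Malformed files are reported by filename in the returned error map; the
    run continues over the rest.  An empty directory is an error.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.glob("*.csv")
                   if p.name not in ("covariates.csv", "measurements.csv",
                                     "paired_calls.csv"))
    if not files:
        raise UnusableRecordError(f"no waveform CSVs in {directory}")
    out: list[tuple[ECGRecord, GroundTruth | None]] = []
    errors: dict[str, str] = {}
    for p in files:
        try:
            out.append(read_record_csv(p))
        except Exception as exc:  # per-file failure must not stop the run
            errors[p.name] = str(exc)
    return out, errors


def write_table(df: pd.DataFrame, path: str | Path, seed, cfg_hash: str) -> Path:
    """Write a tabular artifact with the seed/config-hash provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)
    return path
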