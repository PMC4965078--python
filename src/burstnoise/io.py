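"""CSV/JSON interchange for count tables, flow events, summaries, estimates.

Fixed dialect throughout: comma separator, header row, UTF-8, '.' decimal;
floats are written with 9 significant digits so diffs are reproducible
across platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .burst import BurstEstimate
from .noise_stats import PopulationSummary
from .synthetic import (
    COUNT_COLUMNS,
    FLOW_COLUMNS,
    ClonePanelConfig,
    PerturbationConfig,
)

__all__ = [
    "SchemaError",
    "read_count_table",
    "read_flow_table",
    "write_table",
    "summaries_to_frame",
    "frame_to_summaries",
    "estimates_to_frame",
    "RunConfig",
]

FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    return df


def _bad_lines(mask: np.ndarray) -> str:
    # +2: header is line 1, first data row line 2
    lines = (np.flatnonzero(mask) + 2).tolist()
    shown = ", ".join(map(str, lines[:10]))
    more = "" if len(lines) <= 10 else f" (+{len(lines) - 10} more)"
    return shown + more


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a per-cell mRNA count table.

    Schema: clone_id, condition, cell_id, mrna_count; counts must be
    non-negative integers.  Malformed rows are reported with their file
    line numbers.
    """
    df = _read_csv(path, COUNT_COLUMNS)
    counts = pd.to_numeric(df["mrna_count"], errors="coerce")
    bad = counts.isna().to_numpy()
    if bad.any():
        raise SchemaError(f"{path}: non-numeric mrna_count on line(s) {_bad_lines(bad)}")
    neg = (counts < 0).to_numpy()
    if neg.any():
        raise SchemaError(f"{path}: negative mrna_count on line(s) {_bad_lines(neg)}")
    frac = (counts % 1 != 0).to_numpy()
    if frac.any():
        raise SchemaError(f"{path}: non-integer mrna_count on line(s) {_bad_lines(frac)}")
    df = df.copy()
    df["mrna_count"] = counts.astype(np.int64)
    df["clone_id"] = df["clone_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    return df[COUNT_COLUMNS + [c for c in df.columns if c not in COUNT_COLUMNS]]


def read_flow_table(path) -> pd.DataFrame:
    """Read and validate a flow-event table (clone_id, condition, event_id,
    fsc, ssc, mesf); channel values must be numeric and non-negative."""
    df = _read_csv(path, FLOW_COLUMNS)
    df = df.copy()
    for col in ("fsc", "ssc", "mesf"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.isna().to_numpy()
        if bad.any():
            raise SchemaError(f"{path}: non-numeric {col} on line(s) {_bad_lines(bad)}")
        neg = (v < 0).to_numpy()
        if neg.any():
            raise SchemaError(f"{path}: negative {col} on line(s) {_bad_lines(neg)}")
        df[col] = v
    df["clone_id"] = df["clone_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def summaries_to_frame(summaries: list[PopulationSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        d = dataclasses.asdict(s)
        d["flags"] = ";".join(s.flags)
        rows.append(d)
    return pd.DataFrame(rows)


def _parse_flags(raw) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ()
    return tuple(s for s in str(raw).split(";") if s)


def frame_to_summaries(df: pd.DataFrame) -> list[PopulationSummary]:
    out = []
    for _, r in df.iterrows():
        flags = _parse_flags(r.get("flags", ""))
        out.append(
            PopulationSummary(
                clone_id=str(r["clone_id"]),
                condition=str(r["condition"]),
                n=int(r["n"]),
                mean=float(r["mean"]),
                variance=float(r["variance"]),
                cv2=float(r["cv2"]),
                fano=float(r["fano"]),
                flags=flags,
            )
        )
    return out


def estimates_to_frame(estimates: list[BurstEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        d = dataclasses.asdict(e)
        d["flags"] = ";".join(e.flags)
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_estimates(df: pd.DataFrame) -> list[BurstEstimate]:
    out = []
    for _, r in df.iterrows():
        flags = _parse_flags(r.get("flags", ""))
        out.append(
            BurstEstimate(
                clone_id=str(r["clone_id"]),
                condition=str(r["condition"]),
                mean=float(r["mean"]),
                cv2=float(r["cv2"]),
                burst_size=float(r["burst_size"]),
                b_geom=float(r["b_geom"]),
                burst_frequency=float(r["burst_frequency"]),
                manifold=int(r["manifold"]),
                source=str(r["source"]),
                flags=flags,
            )
        )
    return out


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration (seed is mandatory for any stochastic
    command; the CLI --seed flag overrides the file value)."""

    seed: int = 0
    panel: ClonePanelConfig = field(default_factory=ClonePanelConfig)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    gate_n: int = 3000
    grid_max: int = 12
    units: str = "fish"
    outdir: str = "."

    def __post_init__(self):
        if self.units not in ("fish", "mesf"):
            raise ValueError("units must be 'fish' or 'mesf'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        panel = dict(kw.pop("panel", {}))
        pert = dict(kw.pop("perturbation", {}))
        seed = int(kw.pop("seed", 0))
        panel.setdefault("seed", seed)
        if "burst_size_range" in panel:
            panel["burst_size_range"] = tuple(panel["burst_size_range"])
        if "burst_freq_range" in panel:
            panel["burst_freq_range"] = tuple(panel["burst_freq_range"])
        return cls(
            seed=seed,
            panel=ClonePanelConfig(**panel),
            perturbation=PerturbationConfig(**pert),
            **kw,
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, panel=dataclasses.replace(self.panel, seed=seed)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel"]["burst_size_range"] = list(self.panel.burst_size_range)
        d["panel"]["burst_freq_range"] = list(self.panel.burst_freq_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
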