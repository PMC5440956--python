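"""Delimited-text formats, configuration files, seeds and run manifests.

All tables are comma-delimited UTF-8 with a header row. Unknown parents are
encoded as ``0``. A run manifest (JSON) records the configuration snapshot,
the seed, and SHA-256 checksums of every file a stage read or wrote, so a
run can be replayed and verified exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ChainConfig, SimConfig
from .exceptions import ValidationError
from .pedigree import PEDIGREE_COLUMNS, Pedigree
from .variance import LITTER_COLUMNS, VE_COLUMNS


def read_pedigree(path) -> Pedigree:
    """Read and validate a pedigree table (id,sire,dam,sex,line,generation)."""
    df = pd.read_csv(path, dtype=str).fillna("0")
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"pedigree file {path} lacks columns {missing}")
    df["generation"] = df["generation"].astype(int)
    return Pedigree(df)


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.frame[PEDIGREE_COLUMNS].to_csv(path, index=False)


def read_litter_records(path) -> pd.DataFrame:
    """Read and validate litter records (doe,parity,year_season,lactation_class,litter_size)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in LITTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"litter-record file {path} lacks columns {missing}")
    for col in ("parity", "litter_size"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as exc:
            raise ValidationError(f"non-integer {col} in {path}: {exc}")
    if (df["litter_size"] < 0).any():
        row = df.index[df["litter_size"] < 0][0]
        raise ValidationError(f"negative litter size at row {row} of {path}")
    dup = df.duplicated(subset=["doe", "parity"])
    if dup.any():
        doe, par = df.loc[dup.idxmax(), ["doe", "parity"]]
        raise ValidationError(f"duplicate record for doe {doe!r} parity {par}")
    return df[LITTER_COLUMNS]


def write_litter_records(records: pd.DataFrame, path) -> None:
    records[LITTER_COLUMNS].to_csv(path, index=False)


def read_ve_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in VE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"variance-record file {path} lacks columns {missing}")
    return df[VE_COLUMNS]


def write_ve_records(records: pd.DataFrame, path) -> None:
    records[VE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------


def load_config(path) -> SimConfig:
    """SimConfig from a YAML file whose keys mirror the dataclass fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("parity_count_distribution", "parity_lactation_effects"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    try:
        return SimConfig(**raw)
    except TypeError as exc:
        raise ValidationError(f"bad config {path}: {exc}")


def save_config(config: SimConfig, path) -> None:
    data = asdict(config)
    for key in ("parity_count_distribution", "parity_lactation_effects"):
        data[key] = list(data[key])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def substream_seeds(seed: int, n: int) -> list:
    """Deterministic per-stage (or per-replicate) seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Config snapshot, seed and per-stage file checksums of one run."""

    seed: int
    config: dict
    version: str = __version__
    stages: list = field(default_factory=list)

    def record_stage(self, name: str, inputs=(), outputs=()) -> None:
        self.stages.append(
            {
                "stage": name,
                "inputs": {str(p): _checksum(p) for p in inputs},
                "outputs": {str(p): _checksum(p) for p in outputs},
            }
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
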