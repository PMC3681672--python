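"""File formats and run configuration.

Probe tables are tab-delimited with header
``sample_id  chrom  pos  X  Y  R  BAF`` (one file per sample, positions
0-based).  Trees are Newick with branch lengths in years and the LUCA
time carried in a root comment; NEXUS export goes through dendropy.
Configuration is a single YAML file; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .calling import CallerConfig
from .cohort import CohortConfig
from .trees import SampledTree

PROBE_COLUMNS = ["sample_id", "chrom", "pos", "X", "Y", "R", "BAF"]


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table lacks columns {missing}")
    df.to_csv(path, sep="\t", index=False, columns=PROBE_COLUMNS, float_format="%.6g")


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} lacks columns {missing}")
    return df


def write_tree(tree: SampledTree, path: str | Path, schema: str = "newick") -> None:
    if schema == "newick":
        Path(path).write_text(tree.to_newick())
    elif schema == "nexus":
        Path(path).write_text(
            tree.to_dendropy().as_string(schema="nexus", suppress_item_comments=False)
        )
    else:
        raise ValueError("schema must be 'newick' or 'nexus'")


def read_tree(path: str | Path, luca_time: float | None = None) -> SampledTree:
    text = Path(path).read_text()
    return SampledTree.from_newick(text, luca_time=luca_time)


@dataclasses.dataclass
class RunConfig:
    """Top-level configuration: one seed, per-stage parameter blocks."""

    seed: int = 0
    genome_length_mb: float = 3164.0
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    caller: CallerConfig = dataclasses.field(default_factory=CallerConfig)
    mcmc_iterations: int = 200_000
    mcmc_thin: int = 100
    mcmc_burnin: float = 0.1


def _update_dataclass(obj, values: dict, context: str):
    known = {f.name for f in dataclasses.fields(obj)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    for k, v in values.items():
        current = getattr(obj, k)
        if dataclasses.is_dataclass(current) and isinstance(v, dict):
            _update_dataclass(current, v, f"{context}.{k}")
        else:
            if k == "segment_cm" and isinstance(v, list):
                v = tuple(v)
            setattr(obj, k, v)
    return obj


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    cfg = RunConfig()
    caller_cfg = raw.pop("caller", None)
    _update_dataclass(cfg, raw, "run")
    if caller_cfg:
        _update_dataclass(cfg.caller, caller_cfg, "caller")
        cfg.caller.__post_init__()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            d = {}
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if f.name == "thresholds":  # caller boxes are not YAML-portable here
                    continue
                d[f.name] = plain(v)
            return d
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(plain(cfg), sort_keys=False))
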