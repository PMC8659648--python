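"""Shared I/O, configuration and seeding plumbing.

Matrices travel as plain comma-delimited text in samples x channels
orientation, full precision, no header ('.' decimal, '\\n' line ends).
Datasets round-trip as a directory of CSVs plus a ``config.yaml``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .simulate import ChannelMatrix, LatentMatrix, SimulationConfig, SyntheticDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_dataset",
    "load_dataset",
    "child_seed",
]

PathLike = Union[str, Path]


def child_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage, per-replication child seed.

    Mixing the stage label through a CRC keeps streams independent and
    ensures adding a new stage never perturbs existing ones.
    """
    ss = np.random.SeedSequence(
        [int(master_seed) % (2**31), zlib.crc32(stage.encode()), int(index)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def read_matrix(path: PathLike) -> np.ndarray:
    """Read a samples x channels numeric text matrix.

    Comma- or tab-delimited; a single header row is auto-detected and
    skipped.  Ragged rows, non-numeric cells and NaN/Inf are rejected with
    their location.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = "\t" if ("\t" in lines[0] and "," not in lines[0]) else ","

    def parse_row(line: str, row_idx: int):
        cells = [c.strip() for c in line.split(delim)]
        out = []
        for col_idx, cell in enumerate(cells):
            try:
                val = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {row_idx}, column {col_idx}: "
                    f"{cell!r}"
                ) from None
            if not np.isfinite(val):
                raise ValueError(
                    f"{path}: non-finite value ({cell}) at row {row_idx}, "
                    f"column {col_idx}"
                )
            out.append(val)
        return out

    start = 0
    try:
        first = parse_row(lines[0], 0)
    except ValueError:
        # header row: every later row must parse
        start = 1
        if len(lines) == 1:
            raise
        first = None

    rows = []
    width = None
    for i, line in enumerate(lines[start:], start=start):
        row = first if (i == 0 and first is not None) else parse_row(line, i)
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(
                f"{path}: ragged row {i}: expected {width} columns, got {len(row)}"
            )
        rows.append(row)
    return np.asarray(rows, dtype=float)


def write_matrix(matrix: np.ndarray, path: PathLike) -> Path:
    """Write a samples x channels matrix as full-precision CSV (no header)."""
    arr = np.asarray(matrix, dtype=float)
    if arr.size == 0:
        raise ValueError("refusing to write an empty matrix")
    if arr.ndim == 1:
        arr = arr[:, None]
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains NaN/Inf")
    path = Path(path)
    np.savetxt(path, arr, delimiter=",", fmt="%.17g")
    return path


def save_dataset(dataset: SyntheticDataset, out_dir: PathLike) -> Path:
    """Persist a synthetic dataset as a directory of CSVs + config.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.observed.as_samples(), out / "observed.csv")
    write_matrix(dataset.clean.as_samples(), out / "clean.csv")
    write_matrix(dataset.latents.values.T, out / "latents.csv")
    write_matrix(dataset.W, out / "W.csv")
    cfg = asdict(dataset.config)
    cfg["channel_scale_range"] = (
        list(cfg["channel_scale_range"]) if cfg["channel_scale_range"] else None
    )
    if dataset.channel_scales is not None:
        cfg["channel_scales"] = dataset.channel_scales.tolist()
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out


def load_dataset(in_dir: PathLike) -> SyntheticDataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    src = Path(in_dir)
    raw_cfg = yaml.safe_load((src / "config.yaml").read_text())
    scales = raw_cfg.pop("channel_scales", None)
    if raw_cfg.get("channel_scale_range"):
        raw_cfg["channel_scale_range"] = tuple(raw_cfg["channel_scale_range"])
    config = SimulationConfig(**raw_cfg)
    observed = ChannelMatrix.from_samples(read_matrix(src / "observed.csv"))
    clean = ChannelMatrix.from_samples(read_matrix(src / "clean.csv"))
    latents = LatentMatrix(values=read_matrix(src / "latents.csv").T)
    W = read_matrix(src / "W.csv")
    return SyntheticDataset(
        config=config,
        latents=latents,
        W=W,
        clean=clean,
        observed=observed,
        channel_scales=np.asarray(scales) if scales is not None else None,
    )


def write_config_echo(config: dict, path: PathLike) -> Path:
    """Write the resolved run configuration next to a command's output."""
    path = Path(path)
    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
    return path
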