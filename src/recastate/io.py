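"""Shared image/table I/O and run manifests.

Conventions used across all output tables: coordinates in μm with pixel
provenance columns, origin top-left, x = column; frame indices 0-based;
time columns in minutes for time-lapse data and seconds for FRET traces.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "read_traces",
    "write_results",
    "config_hash",
]

TRACE_COLUMNS = ["molecule", "frame", "time_s", "donor", "acceptor"]


def read_image_stack(
    path,
    channel: int | None = None,
    n_channels: int = 1,
) -> np.ndarray:
    """Read a TIFF stack as a (T, Y, X) array for one channel.

    Multi-channel stacks are assumed frame-interleaved (c0 t0, c1 t0,
    c0 t1, ...); pass ``n_channels`` and ``channel`` to deinterleave.
    Pixel type is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack not found: {path}")
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"ambiguous axis layout {data.shape} in {path}; expected (T, Y, X) — "
            "split channels into separate files or declare a sidecar config"
        )
    if n_channels > 1:
        if channel is None:
            raise ValueError("channel selector required for interleaved stacks")
        if data.shape[0] % n_channels != 0:
            raise ValueError(
                f"{data.shape[0]} frames not divisible by {n_channels} channels"
            )
        data = data[channel::n_channels]
    return data


def write_image_stack(path, stack: np.ndarray) -> None:
    """Write a (T, Y, X) or (Y, X) array as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack), photometric="minisblack")


def read_traces(path) -> pd.DataFrame:
    """Read smFRET traces from a long-format CSV.

    Expects columns molecule, frame, time_s, donor, acceptor (one row per
    molecule per frame).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table {path} missing columns: {missing}")
    return df


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir,
    config: dict | None = None,
    seeds: dict | None = None,
) -> dict:
    """Write result tables as CSV plus a JSON manifest.

    The manifest records the written files, the configuration hash, the
    seeds, and the package version, making reruns auditable. Returns the
    manifest dict.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out / fname, index=False)
        files[name] = fname
    manifest = {
        "files": files,
        "config_hash": config_hash(config or {}),
        "seeds": seeds or {},
        "version": __version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
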