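"""File-format helpers: GMT gene sets, TF-target tables, image stacks,
track/phenotype CSVs and YAML configs."""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_tf_network",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_tracks_csv",
    "read_yaml_config",
]


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line, tab-separated: name, description, members."""
    sets = {}
    for line in pathlib.Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    lines = ["\t".join([name, description, *map(str, members)])
             for name, members in sets.items()]
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_tf_network(path) -> dict[str, list[str]]:
    """Two-column TSV (tf, target) -> dict tf -> target list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "target"],
                     comment="#")
    return {tf: sub["target"].astype(str).tolist()
            for tf, sub in df.groupby("tf")}


def write_stack_tiff(stack: np.ndarray, path) -> None:
    """Multi-page TIFF, one RGB page per frame (uint8)."""
    arr = np.clip(stack, 0.0, 1.0)
    tifffile.imwrite(path, (arr * 255).astype(np.uint8), photometric="rgb")


def read_stack_tiff(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr.astype(float) / 255.0


def write_tracks_csv(tracks_frame: pd.DataFrame, path) -> None:
    cols = ["colony_id", "frame_time_min", "area_px2", "mean_R", "mean_G",
            "mean_B", "x", "y", "dist_center_px"]
    tracks_frame[cols].to_csv(path, index=False)


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
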