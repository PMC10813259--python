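"""File input/output helpers: point sets, surfaces, datasets, configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .geometry import AttachmentNodeSet
from .sampling import MeshConfig, TrialRecord, dataset_from_frame, dataset_to_frame


def load_points_csv(path) -> np.ndarray:
    """Read an (n, 3) point set from a CSV with x,y,z columns (mm)."""
    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(cols) != 3:
        raise ValueError("CSV must have x, y, z columns")
    return df[cols].to_numpy(dtype=float)


def save_points_csv(points: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["x", "y", "z"]).to_csv(
        path, index=False
    )


def load_surface_points(path) -> np.ndarray:
    """Vertices of an STL/PLY bone surface (binary or ASCII), in mm."""
    mesh = trimesh.load(path, force="mesh")
    return np.asarray(mesh.vertices, dtype=float)


def save_dataset_csv(records: list[TrialRecord], path) -> None:
    dataset_to_frame(records).to_csv(path, index=False)


def load_dataset_csv(path) -> list[TrialRecord]:
    return dataset_from_frame(pd.read_csv(path))


def save_population(population, directory) -> None:
    """One node CSV per subject (columns side,x,y,z), acetabular rows first."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (ace, fem) in enumerate(population):
        rows = pd.concat(
            [
                pd.DataFrame(ace.nodes, columns=["x", "y", "z"]).assign(side="acetabular"),
                pd.DataFrame(fem.nodes, columns=["x", "y", "z"]).assign(side="femoral"),
            ]
        )
        rows.to_csv(directory / f"subject_{i:04d}.csv", index=False)


def load_population(directory) -> list:
    """Inverse of :func:`save_population`; subjects ordered by filename."""
    pairs = []
    for path in sorted(Path(directory).glob("subject_*.csv")):
        df = pd.read_csv(path)
        pairs.append(
            (
                AttachmentNodeSet(
                    nodes=df[df.side == "acetabular"][["x", "y", "z"]].to_numpy(), side="acetabular"
                ),
                AttachmentNodeSet(
                    nodes=df[df.side == "femoral"][["x", "y", "z"]].to_numpy(), side="femoral"
                ),
            )
        )
    return pairs


def load_run_config(path) -> dict:
    """YAML run configuration: n_trials, seed, mesh resolution, truncation."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def mesh_config_from_dict(cfg: dict) -> MeshConfig:
    return MeshConfig(
        n_lines=int(cfg.get("n_lines", 36)),
        head_radius=float(cfg.get("head_radius", 22.0)),
        head_center=tuple(cfg.get("head_center", (0.0, 0.0, 0.0))),
    )
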