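"""Statistical shape model (PCA) of paired capsule attachment loops.

Observations are the concatenated 3D coordinates of the corresponded
acetabular and femoral node loops (one flattened vector per hip).  Scores are
standardized to unit standard deviation per mode, so a score of +2 on mode 1
means "two population standard deviations along the first mode", matching the
bounds used for probabilistic sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .geometry import AttachmentNodeSet

__all__ = ["ShapeModel", "fit_shape_model", "reconstruct_attachments", "project_attachments"]


@dataclass
class ShapeModel:
    """PCA model of attachment geometry.

    ``mean_vector`` has length ``3*(n_ace + n_fem)``; ``pc_vectors`` holds the
    retained orthonormal modes as rows; ``mode_sd`` is the per-mode standard
    deviation of the training scores in mm; ``variance_fraction`` covers the
    full spectrum (sums to 1 when the population has any variance at all).
    """

    mean_vector: np.ndarray
    pc_vectors: np.ndarray
    mode_sd: np.ndarray
    variance_fraction: np.ndarray
    n_modes_retained: int
    n_nodes_acetabular: int
    n_nodes_femoral: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.pc_vectors = np.asarray(self.pc_vectors, dtype=float)
        self.mode_sd = np.asarray(self.mode_sd, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)

    def save_json(self, path) -> None:
        payload = {
            "mean_vector": self.mean_vector.tolist(),
            "pc_vectors": self.pc_vectors.tolist(),
            "mode_sd": self.mode_sd.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "n_modes_retained": self.n_modes_retained,
            "n_nodes_acetabular": self.n_nodes_acetabular,
            "n_nodes_femoral": self.n_nodes_femoral,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_json(cls, path) -> "ShapeModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mean_vector=np.array(payload["mean_vector"]),
            pc_vectors=np.array(payload["pc_vectors"]),
            mode_sd=np.array(payload["mode_sd"]),
            variance_fraction=np.array(payload["variance_fraction"]),
            n_modes_retained=payload["n_modes_retained"],
            n_nodes_acetabular=payload["n_nodes_acetabular"],
            n_nodes_femoral=payload["n_nodes_femoral"],
            metadata=payload.get("metadata", {}),
        )


def _flatten_pair(ace: AttachmentNodeSet, fem: AttachmentNodeSet) -> np.ndarray:
    return np.concatenate([ace.nodes.ravel(), fem.nodes.ravel()])


def fit_shape_model(
    population: list[tuple[AttachmentNodeSet, AttachmentNodeSet]],
    n_modes: int = 4,
) -> ShapeModel:
    """Fit a mean-centered PCA to a population of paired attachment loops.

    Requires at least ``n_modes + 1`` subjects with identical node counts and
    correspondence.  Training-shape scores are standardized to unit sample SD
    per mode (zero-variance populations get zero SDs, so every reconstruction
    returns the mean).
    """
    if len(population) < n_modes + 1:
        raise ValueError(f"need at least {n_modes + 1} subjects to fit {n_modes} modes")
    n_ace = len(population[0][0])
    n_fem = len(population[0][1])
    for ace, fem in population:
        if len(ace) != n_ace or len(fem) != n_fem:
            raise ValueError("all subjects must share node counts and correspondence")
        if ace.side != "acetabular" or fem.side != "femoral":
            raise ValueError("each pair must be (acetabular, femoral)")

    X = np.array([_flatten_pair(a, f) for a, f in population])
    mean = X.mean(axis=0)
    centered = X - mean
    total_var = float(np.sum(centered**2)) / max(len(population) - 1, 1)

    if total_var < 1e-18:
        dim = X.shape[1]
        return ShapeModel(
            mean_vector=mean,
            pc_vectors=np.zeros((n_modes, dim)),
            mode_sd=np.zeros(n_modes),
            variance_fraction=np.zeros(n_modes),
            n_modes_retained=n_modes,
            n_nodes_acetabular=n_ace,
            n_nodes_femoral=n_fem,
            metadata={"n_subjects": len(population), "degenerate": True},
        )

    max_rank = min(len(population) - 1, X.shape[1])
    pca = PCA(n_components=max_rank)
    pca.fit(X)
    k = min(n_modes, max_rank)
    pc_vectors = pca.components_[:k]
    mode_sd = np.sqrt(pca.explained_variance_[:k])  # sample SD (ddof=1) of raw scores
    if k < n_modes:
        pc_vectors = np.vstack([pc_vectors, np.zeros((n_modes - k, X.shape[1]))])
        mode_sd = np.concatenate([mode_sd, np.zeros(n_modes - k)])
    return ShapeModel(
        mean_vector=mean,
        pc_vectors=pc_vectors,
        mode_sd=mode_sd,
        variance_fraction=pca.explained_variance_ratio_,
        n_modes_retained=n_modes,
        n_nodes_acetabular=n_ace,
        n_nodes_femoral=n_fem,
        metadata={"n_subjects": len(population)},
    )


def reconstruct_attachments(
    model: ShapeModel, scores: np.ndarray
) -> tuple[AttachmentNodeSet, AttachmentNodeSet]:
    """Reconstruct paired attachment loops from standardized PC scores.

    Coordinates are ``mean + sum_i score_i * mode_sd_i * pc_vector_i``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size > model.n_modes_retained:
        raise ValueError(
            f"scores must be a vector of length <= {model.n_modes_retained}"
        )
    coords = model.mean_vector.copy()
    for i, s in enumerate(scores):
        coords += s * model.mode_sd[i] * model.pc_vectors[i]
    split = 3 * model.n_nodes_acetabular
    ace = AttachmentNodeSet(nodes=coords[:split].reshape(-1, 3), side="acetabular")
    fem = AttachmentNodeSet(nodes=coords[split:].reshape(-1, 3), side="femoral")
    return ace, fem


def project_attachments(
    model: ShapeModel, ace: AttachmentNodeSet, fem: AttachmentNodeSet
) -> np.ndarray:
    """Standardized PC scores of a shape (inverse of reconstruction)."""
    centered = _flatten_pair(ace, fem) - model.mean_vector
    raw = model.pc_vectors @ centered
    sd = np.where(model.mode_sd > 0, model.mode_sd, 1.0)
    return np.where(model.mode_sd > 0, raw / sd, 0.0)
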