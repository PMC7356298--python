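"""Weighted graph indices for individualized structural covariance networks.

All indices operate on a symmetric non-negative weight matrix with zero
diagonal (an :class:`~iscn.network.SCNMatrix` or a bare array).  Conventions:

* strength: sum of incident weights; the global value is the mean over nodes.
* clustering: Onnela geometric-mean-of-triangles formula on weights
  normalized by the global maximum weight; the global value is the
  unweighted mean of nodal values.
* path length: edge length is the reciprocal weight ``1/w``; distances are
  all-pairs shortest paths; the characteristic path length is the mean over
  ordered finite pairs (excluding the diagonal).
* efficiency: mean reciprocal shortest-path distance over ordered pairs,
  with unreachable pairs contributing 0.

On a complete graph with uniform weight ``w`` these reduce to closed forms:
strength ``(R-1)w``, clustering 1, path length ``1/w``, efficiency ``w``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .network import SCNMatrix

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "node_strength",
    "global_strength",
    "nodal_clustering",
    "global_clustering",
    "shortest_path_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "compute_metrics",
    "metrics_tables",
    "GLOBAL_INDEX_NAMES",
]

GLOBAL_INDEX_NAMES = ("strength", "clustering", "path_length", "efficiency")


@dataclass
class NodalMetrics:
    subject_id: str
    strength: np.ndarray
    clustering: np.ndarray


@dataclass
class GlobalMetrics:
    subject_id: str
    strength: float
    clustering: float
    path_length: float
    efficiency: float

    def as_dict(self) -> dict[str, float]:
        return {
            "strength": self.strength,
            "clustering": self.clustering,
            "path_length": self.path_length,
            "efficiency": self.efficiency,
        }


def _as_weights(W: SCNMatrix | np.ndarray) -> np.ndarray:
    if isinstance(W, SCNMatrix):
        return W.weights
    return np.asarray(W, dtype=float)


def node_strength(W: SCNMatrix | np.ndarray) -> np.ndarray:
    """Sum of incident edge weights per node (the diagonal is zero)."""
    return _as_weights(W).sum(axis=1)


def global_strength(W: SCNMatrix | np.ndarray) -> float:
    """Mean nodal strength over all nodes."""
    return float(node_strength(W).mean())


def nodal_clustering(W: SCNMatrix | np.ndarray) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    With weights normalized by the global maximum, ``w_hat = W / max(W)``,

        C_i = sum_{j,h} (w_hat_ij * w_hat_ih * w_hat_jh)^(1/3) / (k_i (k_i - 1))

    where ``k_i`` counts nonzero-weight neighbours; ``C_i = 0`` when
    ``k_i < 2``.  An all-zero matrix yields the zero vector.
    """
    A = _as_weights(W)
    wmax = A.max()
    if wmax == 0:
        return np.zeros(A.shape[0])
    cbrt = np.cbrt(A / wmax)
    triangles = np.diagonal(cbrt @ cbrt @ cbrt)
    k = np.count_nonzero(A, axis=1)
    denom = k * (k - 1)
    out = np.zeros(A.shape[0])
    ok = denom > 0
    out[ok] = triangles[ok] / denom[ok]
    return out


def global_clustering(W: SCNMatrix | np.ndarray) -> float:
    """Unweighted mean of nodal clustering coefficients."""
    return float(nodal_clustering(W).mean())


def shortest_path_matrix(W: SCNMatrix | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances under the length map ``l = 1/w``.

    Zero-weight entries are absent edges; unreachable pairs get ``inf``.
    """
    A = _as_weights(W)
    with np.errstate(divide="ignore", over="ignore"):
        lengths = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), 0.0)
    # dense csgraph input: 0 encodes "no edge"; csgraph wants C-contiguity
    return shortest_path(np.ascontiguousarray(lengths), method="auto", directed=False)


def characteristic_path_length(D: np.ndarray) -> float:
    """Mean distance over ordered finite pairs i != j; inf if none exist."""
    D = np.asarray(D, dtype=float)
    off = ~np.eye(D.shape[0], dtype=bool)
    finite = off & np.isfinite(D)
    if not finite.any():
        return float("inf")
    return float(D[finite].mean())


def global_efficiency(D: np.ndarray) -> float:
    """Mean reciprocal distance over ordered pairs i != j (1/inf = 0)."""
    D = np.asarray(D, dtype=float)
    off = ~np.eye(D.shape[0], dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    return float(inv[off].mean())


def compute_metrics(W: SCNMatrix) -> tuple[GlobalMetrics, NodalMetrics]:
    """All global and nodal indices for one subject's network."""
    strength = node_strength(W)
    clustering = nodal_clustering(W)
    D = shortest_path_matrix(W)
    g = GlobalMetrics(
        subject_id=W.subject_id,
        strength=float(strength.mean()),
        clustering=float(clustering.mean()),
        path_length=characteristic_path_length(D),
        efficiency=global_efficiency(D),
    )
    n = NodalMetrics(subject_id=W.subject_id, strength=strength, clustering=clustering)
    return g, n


def metrics_tables(
    matrices: list[SCNMatrix],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global (subjects x 4 indices) and nodal-CC (subjects x regions) tables."""
    if not matrices:
        raise ValueError("no matrices supplied")
    global_rows = []
    nodal_rows = []
    ids = []
    for W in matrices:
        g, n = compute_metrics(W)
        global_rows.append([g.strength, g.clustering, g.path_length, g.efficiency])
        nodal_rows.append(n.clustering)
        ids.append(W.subject_id)
    global_df = pd.DataFrame(global_rows, index=ids, columns=list(GLOBAL_INDEX_NAMES))
    nodal_df = pd.DataFrame(
        np.vstack(nodal_rows), index=ids, columns=list(matrices[0].atlas.names)
    )
    return global_df, nodal_df
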