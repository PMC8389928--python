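"""Aggregate detection by the inter-chain atom-distance cutoff rule.

Two chains are in contact iff any inter-chain bead pair lies within the
cutoff (default 0.55 nm = 5.5 Å) under the minimum-image convention —
the boundary is inclusive.  Clusters are the single-linkage connected
components of the resulting chain-contact graph.  From a trajectory the
module extracts the kinetic time series: the free-monomer count N_m(t),
the largest-cluster size M_max(t) and the per-frame size multisets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import Topology

__all__ = [
    "DEFAULT_CUTOFF",
    "ClusterSeries",
    "contact_chain_pairs",
    "cluster_labels",
    "cluster_sizes",
    "cluster_time_series",
]

#: Cluster cutoff in nm (5.5 Å).
DEFAULT_CUTOFF = 0.55


def contact_chain_pairs(
    positions: np.ndarray, box: float, topo: Topology, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """(n_pairs, 2) array of distinct chain pairs with any bead contact."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(positions, dtype=float) % box
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    ci = topo.chain_ids[pairs[:, 0]]
    cj = topo.chain_ids[pairs[:, 1]]
    inter = ci != cj
    cp = np.sort(np.column_stack([ci[inter], cj[inter]]), axis=1)
    if len(cp) == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(cp, axis=0)


def cluster_labels(
    positions: np.ndarray, box: float, topo: Topology, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Chain -> cluster-id mapping (single-linkage components).

    Labels are canonicalised to order of first appearance, so identical
    partitions always get identical label arrays.
    """
    pairs = contact_chain_pairs(positions, box, topo, cutoff)
    n = topo.n_chains
    if len(pairs) == 0:
        return np.arange(n)
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return _canonicalise(labels)


def _canonicalise(labels: np.ndarray) -> np.ndarray:
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def cluster_sizes(labels: np.ndarray) -> np.ndarray:
    """Multiset of cluster sizes (sorted descending)."""
    return np.sort(np.bincount(labels))[::-1].astype(np.int64)


@dataclass
class ClusterSeries:
    """Per-frame cluster labels and derived kinetic time series.

    Invariants: cluster sizes sum to ``n_chains`` in every frame;
    ``n_monomers`` counts clusters of size 1; ``1 <= m_max <= n_chains``.
    """

    times: np.ndarray  # ps
    labels: np.ndarray  # (n_frames, n_chains)
    sizes: list[np.ndarray]  # per-frame size multisets
    n_monomers: np.ndarray  # N_m per frame
    m_max: np.ndarray  # largest cluster size per frame

    @property
    def n_chains(self) -> int:
        return self.labels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "N_m": self.n_monomers, "M_max": self.m_max}
        )

    def save(self, csv_path: str | Path, sizes_path: str | Path | None = None) -> None:
        """Write the (time, N_m, M_max) table to CSV and, optionally, the
        full per-frame size lists to a JSON sidecar."""
        self.to_frame().to_csv(csv_path, index=False)
        if sizes_path is not None:
            payload = {
                "times": self.times.tolist(),
                "sizes": [s.tolist() for s in self.sizes],
                "labels": self.labels.tolist(),
            }
            Path(sizes_path).write_text(json.dumps(payload))

    @classmethod
    def from_labels(cls, times: np.ndarray, labels: np.ndarray) -> "ClusterSeries":
        times = np.asarray(times, dtype=float)
        labels = np.asarray(labels, dtype=np.int64)
        sizes = [cluster_sizes(lab) for lab in labels]
        n_monomers = np.array([int(np.sum(s == 1)) for s in sizes])
        m_max = np.array([int(s[0]) for s in sizes])
        return cls(times, labels, sizes, n_monomers, m_max)


def cluster_time_series(
    positions: np.ndarray,
    times: np.ndarray,
    box: float,
    topo: Topology,
    cutoff: float = DEFAULT_CUTOFF,
) -> ClusterSeries:
    """Apply the cluster definition to every frame of a trajectory.

    ``positions`` has shape (n_frames, n_beads, 3), time-ordered.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3 or positions.shape[2] != 3:
        raise ValueError("positions must have shape (n_frames, n_beads, 3)")
    if positions.shape[1] != topo.n_beads:
        raise ValueError("bead count inconsistent with topology")
    if len(times) != positions.shape[0]:
        raise ValueError("times and positions disagree on frame count")
    labels = np.stack(
        [cluster_labels(frame, box, topo, cutoff) for frame in positions]
    )
    return ClusterSeries.from_labels(times, labels)
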