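"""Structural descriptors of aggregates and their size-conditioned averages.

Three per-cluster descriptors characterise transient aggregate
morphology:

* the radius of gyration ``R_g`` (nm), from the unweighted gyration
  tensor of all beads in the cluster;
* the asphericity ``b = lam_z^2 - (lam_x^2 + lam_y^2)/2`` (nm^2), where
  ``lam_x^2 <= lam_y^2 <= lam_z^2`` are the sorted principal moments of
  the gyration tensor (0 for spherically symmetric shapes, ``R_g^2`` in
  the rod limit);
* the end-to-end correlation
  ``C_n = 2/(M(M-1)) * sum_{i<j} (n_i . n_j)^2`` over the unit
  end-to-end vectors of the M chains in the cluster — 1 for parallel
  (or antiparallel) alignment, ~1/3 for isotropic orientations.

Descriptors need contiguous coordinates, so clusters are first unwrapped
through the periodic boundary by walking their contact graph.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import DEFAULT_CUTOFF, ClusterSeries, contact_chain_pairs
from .model import Topology, minimum_image

__all__ = [
    "DegenerateChainError",
    "UndefinedDescriptorError",
    "unwrap_chain_coords",
    "unwrap_cluster",
    "gyration_descriptors",
    "end_to_end_unit_vectors",
    "end_to_end_correlation",
    "structural_records",
    "conditional_average_vs_M",
]


class DegenerateChainError(ValueError):
    """A chain has a zero-length end-to-end vector."""


class UndefinedDescriptorError(ValueError):
    """Descriptor undefined for the given cluster size (needs M >= 2)."""


def unwrap_chain_coords(
    positions: np.ndarray, box: float, topo: Topology
) -> np.ndarray:
    """Make every chain whole: bead b+1 placed by minimum image from bead b."""
    pos = np.asarray(positions, dtype=float) % box
    out = pos.copy()
    L = topo.chain_length
    for c in range(topo.n_chains):
        s = topo.chain_slice(c)
        chain = out[s]
        for b in range(1, L):
            chain[b] = chain[b - 1] + minimum_image(chain[b] - chain[b - 1], box)
    return out


def unwrap_cluster(
    positions: np.ndarray,
    box: float,
    topo: Topology,
    labels: np.ndarray,
    cluster_id: int,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Image-consistent coordinates of one cluster.

    Returns ``(coords, chains)`` where ``coords`` stacks the unwrapped
    beads of the member chains in chain order.  The cluster's contact
    graph is traversed breadth-first from an anchor chain; each newly
    reached chain is shifted by the whole-box translation that brings its
    contact bead to the minimum image of its already-placed partner, so
    every contact distance is <= cutoff in the output.

    Raises if the alleged cluster is not connected under the contact
    graph (internal-consistency error).
    """
    chains = np.flatnonzero(np.asarray(labels) == cluster_id)
    if len(chains) == 0:
        raise ValueError(f"no chains carry cluster id {cluster_id}")
    whole = unwrap_chain_coords(positions, box, topo)
    if len(chains) == 1:
        return whole[topo.chain_slice(chains[0])].copy(), chains

    pairs = contact_chain_pairs(positions, box, topo, cutoff)
    member = set(chains.tolist())
    adj: dict[int, list[int]] = {int(c): [] for c in chains}
    for a, b in pairs:
        if a in member and b in member:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))

    coords = {int(c): whole[topo.chain_slice(c)].copy() for c in chains}
    anchor = int(chains[0])
    placed = {anchor}
    queue = [anchor]
    while queue:
        current = queue.pop(0)
        for neigh in adj[current]:
            if neigh in placed:
                continue
            # translate the whole neighbour chain so its closest bead pair
            # with the placed chain sits at minimum image
            d = coords[neigh][None, :, :] - coords[current][:, None, :]
            dist2 = np.sum(minimum_image(d, box) ** 2, axis=2)
            ia, ib = np.unravel_index(np.argmin(dist2), dist2.shape)
            sep = coords[neigh][ib] - coords[current][ia]
            shift = minimum_image(sep, box) - sep
            coords[neigh] += shift
            placed.add(neigh)
            queue.append(neigh)
    if placed != member:
        raise ValueError(
            "cluster is not connected under the contact graph "
            f"(reached {len(placed)} of {len(member)} chains)"
        )
    return np.concatenate([coords[int(c)] for c in chains]), chains


def gyration_descriptors(coords: np.ndarray) -> tuple[float, float]:
    """(R_g, b) of a point set from its unweighted gyration tensor.

    Eigenvalues of the gyration tensor are the squared principal moments
    lam^2; ``R_g^2`` is their sum and ``b`` follows the sorted-moment
    convention lam_x^2 <= lam_y^2 <= lam_z^2.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    centred = coords - coords.mean(axis=0)
    tensor = centred.T @ centred / coords.shape[0]
    lam2 = np.sort(np.linalg.eigvalsh(tensor))
    r_g = float(np.sqrt(np.sum(lam2)))
    b = float(lam2[2] - 0.5 * (lam2[0] + lam2[1]))
    return r_g, b


def end_to_end_unit_vectors(coords: np.ndarray, chain_length: int) -> np.ndarray:
    """Unit end-to-end vectors of chains stacked in ``coords``.

    ``coords`` holds M unwrapped chains of ``chain_length`` beads each,
    concatenated; returns (M, 3).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] % chain_length:
        raise ValueError("coords length is not a multiple of chain_length")
    per_chain = coords.reshape(-1, chain_length, 3)
    vec = per_chain[:, -1, :] - per_chain[:, 0, :]
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms == 0):
        raise DegenerateChainError("zero-length end-to-end vector")
    return vec / norms[:, None]


def end_to_end_correlation(unit_vectors: np.ndarray) -> float:
    """C_n over all distinct pairs of unit end-to-end vectors.

    Uses the 3x3 Gram identity
    ``sum_{ij} (n_i . n_j)^2 = ||N^T N||_F^2`` so the cost is O(M)
    regardless of the number of pairs.
    """
    u = np.asarray(unit_vectors, dtype=float)
    m = u.shape[0]
    if m < 2:
        raise UndefinedDescriptorError("C_n requires a cluster of size >= 2")
    gram = u.T @ u
    total = float(np.sum(gram * gram)) - m  # remove the i == j terms
    return total / (m * (m - 1))


def structural_records(
    positions: np.ndarray,
    series: ClusterSeries,
    box: float,
    topo: Topology,
    cutoff: float = DEFAULT_CUTOFF,
    min_size: int = 1,
) -> pd.DataFrame:
    """Per-cluster descriptor stream over a trajectory.

    One row per cluster per frame with columns
    ``time, M, R_g, b, C_n`` (``C_n`` is NaN for monomers, where it is
    undefined).
    """
    rows = []
    for f, frame in enumerate(np.asarray(positions, dtype=float)):
        labels = series.labels[f]
        for cid in range(int(labels.max()) + 1):
            m = int(np.sum(labels == cid))
            if m < min_size:
                continue
            coords, _ = unwrap_cluster(frame, box, topo, labels, cid, cutoff)
            r_g, b = gyration_descriptors(coords)
            if m >= 2:
                c_n = end_to_end_correlation(
                    end_to_end_unit_vectors(coords, topo.chain_length)
                )
            else:
                c_n = np.nan
            rows.append((series.times[f], m, r_g, b, c_n))
    return pd.DataFrame(rows, columns=["time", "M", "R_g", "b", "C_n"])


def conditional_average_vs_M(records: pd.DataFrame) -> pd.DataFrame:
    """Pooled mean and sample SD of each descriptor versus cluster size.

    Records from all frames and repeats are pooled per size M; the
    spread column is the standard deviation of the sample (ddof=1, NaN
    when only a single record exists for that M).  Sizes with no records
    are simply absent.
    """
    grouped = records.groupby("M")
    out = grouped.agg(
        b_mean=("b", "mean"),
        b_sd=("b", lambda x: x.std(ddof=1)),
        R_g_mean=("R_g", "mean"),
        R_g_sd=("R_g", lambda x: x.std(ddof=1)),
        C_n_mean=("C_n", "mean"),
        C_n_sd=("C_n", lambda x: x.std(ddof=1)),
        n_records=("b", "size"),
    )
    return out.reset_index()
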