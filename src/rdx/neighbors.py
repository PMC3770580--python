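"""Neighbor search for short-ranged pair interactions.

The pair query contract is: for a cutoff ``c``, every unordered particle
pair at distance < ``c`` is returned exactly once. Enumeration is backed by
a k-d tree; a brute-force O(N^2) reference is provided for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["NeighborList", "build_neighbor_list", "brute_force_pairs"]


@dataclass
class NeighborList:
    """Unordered particle pairs within ``cutoff`` of each other.

    ``pairs`` is an (M, 2) int array with pairs[i, 0] < pairs[i, 1],
    sorted lexicographically so enumeration order is deterministic.
    """

    cutoff: float
    n_particles: int
    pairs: np.ndarray

    def distances(self, positions: np.ndarray) -> np.ndarray:
        """Current distances of the listed pairs (may exceed cutoff if positions moved)."""
        if len(self.pairs) == 0:
            return np.empty(0)
        if len(positions) != self.n_particles:
            raise ValueError(
                f"position array has {len(positions)} rows, list was built for {self.n_particles}"
            )
        delta = positions[self.pairs[:, 0]] - positions[self.pairs[:, 1]]
        return np.linalg.norm(delta, axis=1)

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Symmetric adjacency in CSR form (indptr, indices) for per-particle queries."""
        n = self.n_particles
        if len(self.pairs) == 0:
            return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
        src = np.concatenate([self.pairs[:, 0], self.pairs[:, 1]])
        dst = np.concatenate([self.pairs[:, 1], self.pairs[:, 0]])
        order = np.argsort(src, kind="stable")
        counts = np.bincount(src, minlength=n)
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        return indptr, dst[order].astype(np.int64)


def build_neighbor_list(positions_or_state, cutoff: float) -> NeighborList:
    """Enumerate all unordered pairs closer than ``cutoff`` (nm).

    Accepts a raw (N, 3) position array or a :class:`~rdx.model.SystemState`.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    positions = getattr(positions_or_state, "positions", positions_or_state)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    if n < 2:
        return NeighborList(cutoff=cutoff, n_particles=n, pairs=np.empty((0, 2), dtype=np.int64))
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        pairs = np.sort(pairs, axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = np.ascontiguousarray(pairs[order], dtype=np.int64)
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
    return NeighborList(cutoff=cutoff, n_particles=n, pairs=pairs)


def brute_force_pairs(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """O(N^2) reference pair enumeration (test oracle)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    delta = positions[:, None, :] - positions[None, :, :]
    dist = np.linalg.norm(delta, axis=-1)
    i, j = np.where(np.triu(dist < cutoff, k=1))
    return np.stack([i, j], axis=1).astype(np.int64)
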