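"""Stimulation design matrices for multi-site random mapping.

A mapping experiment stimulates N randomly chosen voxels at a time and
records one scalar response (peak postsynaptic current) per pattern.  The
binary design matrix A has one row per pattern and one column per voxel;
repeating until every voxel has been hit M times takes P = M·V/N patterns.
Each repetition block is an independent random partition of the voxels into
disjoint N-subsets, so rows within a block have pairwise-disjoint supports
("orthogonal patterns"); with M = N the system y = A x is determined
(P = V), while M < N relies on sparsity (compressed sensing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimPatternMatrix", "MeasurementVector", "ConnectivityMap", "build_design"]


@dataclass
class StimPatternMatrix:
    """Binary P×V_pad design matrix with block structure.

    ``real_voxels`` gives the first V columns; any trailing dummy columns
    pad V to a multiple of N and are excluded from reconstruction.
    """

    A: np.ndarray  # uint8, shape (P, V_pad)
    n_foci: int  # N
    repeats: int  # M
    block_index: np.ndarray  # shape (P,), repetition block of each row
    grid_shape: tuple[int, int, int]
    voxel_um: tuple[float, float, float] | None = None
    real_voxels: int = 0

    def __post_init__(self) -> None:
        if self.real_voxels == 0:
            self.real_voxels = self.A.shape[1]

    @property
    def P(self) -> int:
        return self.A.shape[0]

    @property
    def V(self) -> int:
        return self.real_voxels

    @property
    def V_pad(self) -> int:
        return self.A.shape[1]

    def validate(self) -> None:
        """Assert the design invariants: row sums N, column sums M, and
        disjoint supports within each repetition block."""
        if not np.all(self.A.sum(axis=1) == self.n_foci):
            raise ValueError("every row must contain exactly N foci")
        if not np.all(self.A.sum(axis=0) == self.repeats):
            raise ValueError("every voxel must be hit exactly M times")
        for b in np.unique(self.block_index):
            rows = self.A[self.block_index == b]
            if np.any(rows.sum(axis=0) > 1):
                raise ValueError(f"rows of block {b} overlap")


@dataclass
class MeasurementVector:
    """Per-pattern peak current magnitudes (pA)."""

    y: np.ndarray
    polarity: str = "EPSC"  # or "IPSC"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("measurements must be finite")


@dataclass
class ConnectivityMap:
    """Nonnegative per-voxel connection strength (pA) on a 3D grid."""

    x: np.ndarray
    grid_shape: tuple[int, int, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.x < -1e-12):
            raise ValueError("connectivity map must be nonnegative")
        self.x = np.maximum(self.x, 0.0)

    def as_volume(self) -> np.ndarray:
        """Reshape raster-order x into (nz, ny, nx)."""
        nx, ny, nz = self.grid_shape
        return self.x.reshape(nz, ny, nx)


def build_design(
    V: int,
    N: int,
    M: int,
    grid_shape: tuple[int, int, int] | None = None,
    seed: int = 0,
    voxel_um: tuple[float, float, float] | None = None,
) -> StimPatternMatrix:
    """Draw M independent random partitions of V voxels into N-subsets.

    Rows are ordered by repetition block, in random order within a block.
    If V is not divisible by N the matrix is padded with dummy voxels that
    are flagged via ``real_voxels`` and excluded from reconstruction.
    """
    if N < 1 or V < N or M < 1:
        raise ValueError("need N >= 1, V >= N, M >= 1")
    rng = np.random.default_rng(seed)
    V_pad = ((V + N - 1) // N) * N
    rows_per_block = V_pad // N
    A = np.zeros((M * rows_per_block, V_pad), dtype=np.uint8)
    block_index = np.repeat(np.arange(M), rows_per_block)
    for m in range(M):
        groups = rng.permutation(V_pad).reshape(rows_per_block, N)
        order = rng.permutation(rows_per_block)
        for r, g in enumerate(groups[order]):
            A[m * rows_per_block + r, g] = 1
    if grid_shape is None:
        grid_shape = (V, 1, 1)
    return StimPatternMatrix(
        A=A,
        n_foci=N,
        repeats=M,
        block_index=block_index,
        grid_shape=grid_shape,
        voxel_um=voxel_um,
        real_voxels=V,
    )
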