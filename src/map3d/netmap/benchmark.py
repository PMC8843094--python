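"""Recovery metrics and compressed-sensing benchmarking.

The benchmark sweeps the number of repetitions M from the fully determined
case (M = N, P = V) down to heavily compressed regimes (M < N), scoring
each reconstruction of a synthetic clustered phantom by relative ℓ₂ error
and by F1 overlap of the recovered support with the truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import build_design
from .solver import ReconSettings, forward_measure, reconstruct, select_lambda

__all__ = ["relative_l2_error", "support_f1", "cs_benchmark"]

SUPPORT_FRACTION = 0.1  # a voxel is "in the support" at >= 10% of map max


def relative_l2_error(x_true: np.ndarray, x_rec: np.ndarray) -> float:
    """‖x̂ − x‖₂ / ‖x‖₂."""
    x_true = np.asarray(x_true, dtype=float)
    x_rec = np.asarray(x_rec, dtype=float)
    denom = np.linalg.norm(x_true)
    if denom == 0:
        return float(np.linalg.norm(x_rec))
    return float(np.linalg.norm(x_rec - x_true) / denom)


def support_f1(
    x_true: np.ndarray, x_rec: np.ndarray, fraction: float = SUPPORT_FRACTION
) -> float:
    """F1 score of the recovered support.

    Both maps are thresholded at ``fraction`` of their own maximum; F1 is
    the harmonic mean of precision and recall of the resulting voxel sets.
    """
    st = np.asarray(x_true) >= fraction * np.asarray(x_true).max()
    sr = np.asarray(x_rec) >= fraction * max(np.asarray(x_rec).max(), 1e-300)
    tp = int(np.sum(st & sr))
    fp = int(np.sum(~st & sr))
    fn = int(np.sum(st & ~sr))
    if tp == 0:
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def cs_benchmark(
    V: int,
    N: int,
    M_values: list[int],
    phantom_spec=None,
    noise=None,
    n_seeds: int = 10,
    settings: ReconSettings | None = None,
) -> pd.DataFrame:
    """Recovery quality versus the number of repetitions M.

    For each M in ``M_values`` (each within [1, N]) and each seed, a fresh
    clustered phantom and design matrix are drawn, measurements are
    simulated (optionally with noise), and the reconstruction is scored.
    Returns a tidy DataFrame with per-(M, seed) rows; aggregate with
    ``df.groupby("M").median()``.  Error medians are non-increasing in M:
    more repetitions recover the map at least as well, and M = N reproduces
    the determined case P = V.
    """
    from ..synthdata import PhantomSpec, phantom_map

    if any(m < 1 or m > N for m in M_values):
        raise ValueError("M values must lie in [1, N]")
    if phantom_spec is None:
        phantom_spec = PhantomSpec(grid_shape=(V, 1, 1), n_sources=max(V // 50, 1))
    rows = []
    for M in M_values:
        for s in range(n_seeds):
            spec = phantom_spec.with_seed(1000 * s + phantom_spec.seed)
            truth = phantom_map(spec)
            design = build_design(
                V, N, M, grid_shape=spec.grid_shape, seed=2000 * s + M
            )
            y = forward_measure(design, truth, noise=noise, seed=3000 * s + M)
            if settings is None:
                lam = select_lambda(
                    design.A.astype(float), y.y, seed=4000 * s + M
                )
                inst_settings = ReconSettings(lam=lam)
            else:
                inst_settings = settings
            rec = reconstruct(design, y, inst_settings)
            rows.append(
                {
                    "M": M,
                    "seed": s,
                    "rel_l2_error": relative_l2_error(truth.x, rec.x),
                    "support_f1": support_f1(truth.x, rec.x),
                }
            )
    return pd.DataFrame(rows)
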