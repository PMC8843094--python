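"""Seeded generators emulating every data structure the pipeline consumes.

All generators are pure functions of their seed and spec so fixtures are
bit-identical across reruns.  They emulate the statistical character of the
real inputs — sparse nonnegative clustered connectivity (cluster extent
about 30 µm), evoked-current measurements with additive noise, trial
jitter, and occasional failures, Poisson-disc-separated neuron fields
(tens of µm mean separation), slow-indicator calcium transients with
post-stimulus onset, and defocus-blurred widefield stacks — without
claiming any biophysical fidelity beyond that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .netmap.design import ConnectivityMap, MeasurementVector, StimPatternMatrix
from .netmap.solver import forward_measure
from .netmap.traces import TraceSet

__all__ = [
    "PhantomSpec",
    "NoiseModel",
    "NeuronField",
    "CalciumKernel",
    "phantom_map",
    "simulate_mapping_experiment",
    "neuron_field",
    "synthetic_calcium",
    "synthetic_widefield_stack",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Clustered-connectivity phantom parameters.

    ``cluster_sd_um`` defaults to 15 µm so a cluster's visible extent
    (≈ ±1 sd) is about 30 µm, matching the spatial clusters seen in real
    single-focus input maps.
    """

    grid_shape: tuple[int, int, int] = (10, 10, 4)
    voxel_um: tuple[float, float, float] = (40.0, 40.0, 50.0)
    n_sources: int = 8
    amplitude_range: tuple[float, float] = (40.0, 120.0)  # pA
    cluster_sd_um: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 0 or self.n_sources > self.n_voxels:
            raise ValueError("n_sources must be in [0, V]")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[1] <= 0:
            raise ValueError("amplitudes must be > 0")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.grid_shape
        return nx * ny * nz

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


def phantom_map(spec: PhantomSpec) -> ConnectivityMap:
    """Sparse nonnegative clustered map: ``n_sources`` truncated-Gaussian
    bumps with centers uniform in the grid, raster-ordered x-fastest."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_um
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    zs = np.arange(nz) * dz
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    vol = np.zeros((nz, ny, nx))
    for _ in range(spec.n_sources):
        cx = rng.uniform(0, (nx - 1) * dx)
        cy = rng.uniform(0, (ny - 1) * dy)
        cz = rng.uniform(0, (nz - 1) * dz)
        amp = rng.uniform(*spec.amplitude_range)
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        sd = max(spec.cluster_sd_um, 1e-9)
        bump = amp * np.exp(-r2 / (2.0 * sd * sd))
        bump[r2 > (3.0 * sd) ** 2] = 0.0  # truncate at 3 sd
        if not bump.any():  # delta limit: all mass at the nearest voxel
            iz, iy, ix = np.unravel_index(np.argmin(r2), r2.shape)
            bump[iz, iy, ix] = amp
        vol += bump
    return ConnectivityMap(
        x=vol.ravel(), grid_shape=spec.grid_shape, provenance={"spec": vars(spec)}
    )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise for evoked-current peaks.

    ``additive_sd_pA`` is Gaussian instrument noise; ``failure_prob`` is the
    per-pattern chance that stimulation fails and the measurement collapses
    to baseline noise; ``jitter_sd`` is multiplicative trial-to-trial gain
    jitter (lognormal-free, simple 1 + ε with ε ~ N(0, sd)).
    """

    additive_sd_pA: float = 5.0
    failure_prob: float = 0.05
    jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValueError("failure_prob must be in [0, 1]")
        if self.additive_sd_pA < 0 or self.jitter_sd < 0:
            raise ValueError("noise sds must be >= 0")

    def apply(self, y_clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = np.asarray(y_clean, dtype=float).copy()
        if self.jitter_sd > 0:
            y *= 1.0 + rng.normal(0.0, self.jitter_sd, size=y.shape)
        if self.failure_prob > 0:
            fail = rng.random(y.shape) < self.failure_prob
            y[fail] = 0.0
        if self.additive_sd_pA > 0:
            y += rng.normal(0.0, self.additive_sd_pA, size=y.shape)
        return y


def simulate_mapping_experiment(
    x_true: ConnectivityMap,
    design: StimPatternMatrix,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> MeasurementVector:
    """Forward-simulate the measurement vector y = A·x_true with noise.

    The returned vector carries the seed and ground truth in metadata-free
    form via the caller; noiseless when ``noise`` is None.
    """
    return forward_measure(design, x_true, noise=noise, seed=seed)


@dataclass
class NeuronField:
    """Poisson-disc-separated neuron positions with response properties."""

    positions: np.ndarray  # (n, 3) µm
    min_separation_um: float
    amplitudes: np.ndarray  # per-neuron response amplitude (z units or pA)
    thresholds: np.ndarray  # per-neuron photosensitivity threshold (0-1)

    @property
    def n(self) -> int:
        return len(self.positions)

    def min_pairwise_distance(self) -> float:
        best = math.inf
        for i in range(self.n):
            d = np.linalg.norm(self.positions[i + 1 :] - self.positions[i], axis=1)
            if d.size:
                best = min(best, float(d.min()))
        return best


def neuron_field(
    extent_um: tuple[float, float, float],
    n: int,
    min_sep_um: float,
    seed: int = 0,
    max_attempts: int = 20000,
) -> NeuronField:
    """Dart-throwing Poisson-disc sampling of ``n`` neuron positions.

    All pairwise distances are ≥ ``min_sep_um``; an infeasible packing
    (attempt budget exhausted) raises.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    ext = np.asarray(extent_um, dtype=float)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} neurons with min separation "
                f"{min_sep_um} µm in {extent_um}; density too high"
            )
        cand = rng.uniform(0.0, ext)
        attempts += 1
        if all(np.linalg.norm(cand - p) >= min_sep_um for p in pts):
            pts.append(cand)
    positions = np.array(pts) if pts else np.empty((0, 3))
    amplitudes = rng.uniform(3.0, 8.0, size=n)  # healthy responders, z units
    thresholds = rng.uniform(0.2, 0.8, size=n)
    return NeuronField(
        positions=positions,
        min_separation_um=min_sep_um,
        amplitudes=amplitudes,
        thresholds=thresholds,
    )


@dataclass(frozen=True)
class CalciumKernel:
    """Double-exponential calcium transient shape.

    Defaults (50 ms rise, 1 s decay) imitate a slow red indicator; they are
    fixture parameters, not biophysical claims.
    """

    rise_ms: float = 50.0
    decay_ms: float = 1000.0
    amplitude: float = 5.0  # z units
    onset_delay_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_ms <= 0 or self.decay_ms <= 0:
            raise ValueError("time constants must be > 0")

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Transient sampled at ``t_ms`` after imaging onset, peak-normalized
        to ``amplitude``; zero before the onset delay."""
        t = np.asarray(t_ms, dtype=float) - self.onset_delay_ms
        w = np.exp(-t / self.decay_ms) - np.exp(-t / self.rise_ms)
        w[t < 0] = 0.0
        # normalize the peak of the double exponential
        tp = (
            self.rise_ms
            * self.decay_ms
            / (self.decay_ms - self.rise_ms)
            * math.log(self.decay_ms / self.rise_ms)
            if self.decay_ms != self.rise_ms
            else self.rise_ms
        )
        peak = math.exp(-tp / self.decay_ms) - math.exp(-tp / self.rise_ms)
        return self.amplitude * w / peak


def synthetic_calcium(
    field: NeuronField,
    patterns: list[np.ndarray],
    kernel: CalciumKernel = CalciumKernel(),
    frame_rate_hz: float = 10.0,
    duration_s: float = 4.0,
    noise_sd: float = 1.0,
    crosstalk_radius_um: float = 0.0,
    repeats: int = 1,
    seed: int = 0,
) -> tuple[TraceSet, np.ndarray]:
    """Simulated blanked-stimulus calcium recording.

    One sweep per (pattern, repeat): imaging starts at t = 0 immediately
    after photostimulation (the stimulus window itself is blanked), so each
    stimulated neuron's transient begins at the first frame.  Neurons
    within ``crosstalk_radius_um`` of a stimulated neuron receive
    attenuated transients with a Gaussian distance falloff
    (σ = radius / 2); unit-variance Gaussian frame noise is added on top of
    a zero baseline when ``noise_sd`` > 0.

    Returns ``(traces, labels)`` where ``traces.data`` is
    (n_sweeps, n_neurons, n_frames) raw fluorescence in baseline-sd units
    and ``labels`` maps each sweep to its pattern index.  Ground-truth
    responder sets live in ``traces.meta["responders"]``.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate_hz))
    dt_ms = 1000.0 / frame_rate_hz
    t_ms = np.arange(n_frames) * dt_ms
    base_shape = kernel.evaluate(t_ms) / max(kernel.amplitude, 1e-300)
    n_sweeps = len(patterns) * repeats
    data = np.zeros((n_sweeps, field.n, n_frames))
    labels = np.zeros(n_sweeps, dtype=int)
    responders = []
    s = 0
    for p_idx, members in enumerate(patterns):
        members = np.asarray(members, dtype=int)
        for _ in range(repeats):
            labels[s] = p_idx
            for j in range(field.n):
                if j in members:
                    gain = field.amplitudes[j]
                elif crosstalk_radius_um > 0 and members.size:
                    d = np.linalg.norm(
                        field.positions[members] - field.positions[j], axis=1
                    ).min()
                    if d > crosstalk_radius_um:
                        continue
                    sigma = crosstalk_radius_um / 2.0
                    gain = field.amplitudes[j] * math.exp(
                        -(d * d) / (2.0 * sigma * sigma)
                    )
                else:
                    continue
                data[s, j] += gain * base_shape
            s += 1
        responders.append(members)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    traces = TraceSet(
        data=data,
        dt_ms=dt_ms,
        onset_idx=0,
        baseline=None,
        meta={"responders": responders, "noise_sd": noise_sd, "seed": seed},
    )
    return traces, labels


def synthetic_widefield_stack(
    field: NeuronField,
    extent_um: tuple[float, float, float],
    plane_spacing_um: float = 5.0,
    px_um: float = 2.0,
    blob_sd_um: float = 5.0,
    defocus_um_per_um: float = 0.3,
    amplitude: float = 100.0,
    photon_noise: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Widefield image stack of Gaussian somata with defocus broadening.

    Each neuron appears in every plane as a Gaussian blob whose sd grows
    with axial distance from the neuron's plane (and whose peak dims
    accordingly, conserving integrated brightness); Poisson noise emulates
    photon statistics.  Returns (nz, ny, nx) float array.
    """
    rng = np.random.default_rng(seed)
    ex, ey, ez = extent_um
    nx = max(int(round(ex / px_um)), 1)
    ny = max(int(round(ey / px_um)), 1)
    nz = max(int(round(ez / plane_spacing_um)) + 1, 1)
    xs = np.arange(nx) * px_um
    ys = np.arange(ny) * px_um
    zs = np.arange(nz) * plane_spacing_um
    stack = np.zeros((nz, ny, nx))
    xx, yy = np.meshgrid(xs, ys)
    for i in range(field.n):
        px_, py_, pz_ = field.positions[i]
        for iz, z in enumerate(zs):
            sd = blob_sd_um + defocus_um_per_um * abs(z - pz_)
            peak = amplitude * (blob_sd_um / sd) ** 2
            stack[iz] += peak * np.exp(
                -((xx - px_) ** 2 + (yy - py_) ** 2) / (2.0 * sd * sd)
            )
    if photon_noise:
        stack = rng.poisson(np.maximum(stack, 0.0) + 1.0).astype(float)
    return stack
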