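"""Hardware command-signal synthesis and stimulation scheduling.

During one stimulation epoch the two scanning mirrors sweep a full circle,
``galvo_x(t) = A·cos ϕSM(t)``, ``galvo_y(t) = A·sin ϕSM(t)``, while a TTL
trigger advances the DMD through its n_angles masks (one rising edge per
frame) and an analog line gates the laser.  The voltage amplitude A sets the
cone angle θ (volts ∝ tanθ, supplied by a user calibration) and the phase
sets ϕSM.  The galvo command is a continuous sinusoid even though the angle
is conceptually constant per frame: the per-frame sweep is small and the
resulting defocus negligible; a stepped mode emits piecewise-constant angles
for worst-case analysis.

Also here: timing/throughput arithmetic (DMD frame budget, volumetric
pattern rate), grid schedules, Poisson-disc ordering of stimulation sites,
and Poisson-disc ensemble assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GalvoCalibration",
    "StimEpoch",
    "PulseTrain",
    "WaveformSet",
    "EnsembleAssignment",
    "epoch_waveforms",
    "train_waveforms",
    "frame_budget",
    "volumetric_rate",
    "grid_schedule",
    "poisson_disc_order",
    "assign_ensembles",
]

TRIGGER_HIGH_V = 5.0
TRIGGER_WIDTH_SAMPLES = 2  # DMD latches on the rising edge


@dataclass(frozen=True)
class GalvoCalibration:
    """Command amplitude (volts) that realizes the configured θ.

    Linearity is assumed (volts ∝ tanθ); the volts↔θ mapping is rig-specific
    and must be measured by the user.
    """

    volts_at_theta: float

    def __post_init__(self) -> None:
        if self.volts_at_theta == 0:
            raise ValueError("volts_at_theta must be nonzero")


@dataclass(frozen=True)
class StimEpoch:
    """One stimulation dwell: a full azimuth sweep over ``duration_ms``."""

    duration_ms: float = 4.0
    n_angles: int = 10
    start_phase: float = math.pi
    laser_level: float = 1.0

    def __post_init__(self) -> None:
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be > 0")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if not 0.0 <= self.laser_level <= 1.0:
            raise ValueError("laser_level must be in [0, 1]")


@dataclass(frozen=True)
class PulseTrain:
    """Repeated epochs: ``n_pulses`` at ``rate_hz``, each ``pulse_ms`` long."""

    n_pulses: int
    rate_hz: float
    pulse_ms: float

    def __post_init__(self) -> None:
        if self.n_pulses < 1 or self.rate_hz <= 0 or self.pulse_ms <= 0:
            raise ValueError("invalid pulse train")
        if self.pulse_ms > 1000.0 / self.rate_hz:
            raise ValueError("pulse_ms exceeds the pulse period: pulses overlap")


@dataclass
class WaveformSet:
    """Sampled multi-channel control signals (equal length per channel)."""

    sample_rate_hz: float
    galvo_x: np.ndarray
    galvo_y: np.ndarray
    dmd_trigger: np.ndarray
    laser: np.ndarray
    epochs: list[tuple[int, int]] = field(default_factory=list)  # sample spans

    def __post_init__(self) -> None:
        n = len(self.galvo_x)
        if not (len(self.galvo_y) == len(self.dmd_trigger) == len(self.laser) == n):
            raise ValueError("all channels must have the same length")
        vals = np.unique(self.dmd_trigger)
        if not np.all(np.isin(vals, [0.0, TRIGGER_HIGH_V])):
            raise ValueError("trigger channel must be binary-valued")

    @property
    def n_samples(self) -> int:
        return len(self.galvo_x)

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def rising_edges(self) -> np.ndarray:
        """Sample indices of trigger rising edges."""
        tr = self.dmd_trigger > 0
        return np.flatnonzero(tr[1:] & ~tr[:-1]) + 1 if tr.size else np.array([], int)

    def rising_edge_count(self, span: tuple[int, int] | None = None) -> int:
        edges = self.rising_edges()
        # a high trigger at sample 0 is an edge too (signal starts low)
        tr = self.dmd_trigger > 0
        if tr.size and tr[0]:
            edges = np.concatenate([[0], edges])
        if span is not None:
            edges = edges[(edges >= span[0]) & (edges < span[1])]
        return int(edges.size)


def epoch_waveforms(
    epoch: StimEpoch,
    cal: GalvoCalibration,
    fs: float,
    *,
    stepped: bool = False,
) -> WaveformSet:
    """Synthesize one epoch's galvo sinusoids, DMD triggers, and laser gate.

    The sweep phase runs one full cycle from ``start_phase`` over the epoch;
    ``n_angles`` uniformly spaced rising edges advance the DMD.  With
    ``stepped`` the galvo command holds each frame's angle piecewise
    constant instead of sweeping continuously.
    """
    dur_s = epoch.duration_ms / 1000.0
    if fs < 20.0 * epoch.n_angles / dur_s:
        raise ValueError(
            "sample rate too low: need >= 20 samples per DMD frame "
            f"(fs >= {20.0 * epoch.n_angles / dur_s:.0f} Hz)"
        )
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    if stepped:
        frame_idx = np.minimum((t / dur_s * epoch.n_angles).astype(int), epoch.n_angles - 1)
        phi = epoch.start_phase + 2 * math.pi * frame_idx / epoch.n_angles
    else:
        phi = epoch.start_phase + 2 * math.pi * t / dur_s
    A = cal.volts_at_theta
    gx = A * np.cos(phi)
    gy = A * np.sin(phi)
    trig = np.zeros(n)
    for i in range(epoch.n_angles):
        j = int(math.floor(i * n / epoch.n_angles))
        trig[j : min(j + TRIGGER_WIDTH_SAMPLES, n)] = TRIGGER_HIGH_V
    laser = np.full(n, epoch.laser_level)
    return WaveformSet(
        sample_rate_hz=fs,
        galvo_x=gx,
        galvo_y=gy,
        dmd_trigger=trig,
        laser=laser,
        epochs=[(0, n)],
    )


def train_waveforms(
    train: PulseTrain,
    epoch: StimEpoch,
    cal: GalvoCalibration,
    fs: float,
    *,
    stepped: bool = False,
) -> WaveformSet:
    """Concatenate epochs into a pulse train with onsets at ``i/rate_hz``.

    Between epochs the galvos hold their last commanded angle, the laser is
    gated off, and the trigger is low.  Total span is
    ``(n_pulses−1)/rate_hz + pulse_ms``.
    """
    if abs(train.pulse_ms - epoch.duration_ms) > 1e-9:
        epoch = StimEpoch(
            duration_ms=train.pulse_ms,
            n_angles=epoch.n_angles,
            start_phase=epoch.start_phase,
            laser_level=epoch.laser_level,
        )
    one = epoch_waveforms(epoch, cal, fs, stepped=stepped)
    n_ep = one.n_samples
    period = int(round(fs / train.rate_hz))
    if n_ep > period:
        raise ValueError("epoch longer than pulse period: pulses overlap")
    total = (train.n_pulses - 1) * period + n_ep
    gx = np.full(total, one.galvo_x[-1])
    gy = np.full(total, one.galvo_y[-1])
    trig = np.zeros(total)
    laser = np.zeros(total)
    spans = []
    for i in range(train.n_pulses):
        s = i * period
        gx[s : s + n_ep] = one.galvo_x
        gy[s : s + n_ep] = one.galvo_y
        trig[s : s + n_ep] = one.dmd_trigger
        laser[s : s + n_ep] = one.laser
        spans.append((s, s + n_ep))
    return WaveformSet(
        sample_rate_hz=fs,
        galvo_x=gx,
        galvo_y=gy,
        dmd_trigger=trig,
        laser=laser,
        epochs=spans,
    )


def frame_budget(stim_ms: float, dmd_rate_hz: float) -> int:
    """Number of DMD frames that fit in one stimulation dwell:
    ``floor(stim_ms/1000 × dmd_rate_hz)`` (e.g. 52 frames in 4 ms at 13 kHz).
    """
    if stim_ms < 0 or dmd_rate_hz <= 0:
        raise ValueError("stim_ms must be >= 0 and dmd_rate_hz > 0")
    return int(math.floor(stim_ms / 1000.0 * dmd_rate_hz))


def volumetric_rate(dmd_rate_hz: float, masks_per_pattern: int) -> float:
    """Maximum volumetric pattern rate in kHz: DMD rate divided by the
    number of masks per pattern (13 kHz / 10 masks → 1.3 kHz)."""
    if masks_per_pattern < 1:
        raise ValueError("masks_per_pattern must be >= 1")
    return dmd_rate_hz / masks_per_pattern / 1000.0


def grid_schedule(
    nx: int,
    ny: int,
    nz: int,
    spacing_um: tuple[float, float, float],
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Raster-ordered (x fastest, then y, then z) grid of stimulation sites,
    shape (nx·ny·nz, 3), centered on ``center``."""
    if min(nx, ny, nz) < 1:
        raise ValueError("grid dimensions must be positive")
    sx, sy, sz = spacing_um
    xs = center[0] + (np.arange(nx) - (nx - 1) / 2) * sx
    ys = center[1] + (np.arange(ny) - (ny - 1) / 2) * sy
    zs = center[2] + (np.arange(nz) - (nz - 1) / 2) * sz
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def poisson_disc_order(
    sites: np.ndarray,
    d_min: float,
    *,
    lookback: int = 1,
    seed: int = 0,
    max_restarts: int = 200,
) -> np.ndarray:
    """Seed-deterministic permutation of ``sites`` in which every site is at
    least ``d_min`` away from each of the previous ``lookback`` sites.

    Sequential stimulations separated in space avoid photocurrent
    accumulation at repeatedly-lit locations.  Uses randomized greedy
    selection with restarts; raises if no ordering is found within the
    restart budget (suggesting a smaller ``d_min``).
    """
    sites = np.asarray(sites, dtype=float)
    n = len(sites)
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.array([], dtype=int)
    for _ in range(max_restarts):
        remaining = list(rng.permutation(n))
        order: list[int] = []
        ok = True
        while remaining:
            tail = order[-lookback:] if lookback > 0 else []
            pick = None
            for j, cand in enumerate(remaining):
                if all(
                    np.linalg.norm(sites[cand] - sites[p]) >= d_min for p in tail
                ):
                    pick = j
                    break
            if pick is None:
                ok = False
                break
            order.append(remaining.pop(pick))
        if ok:
            return np.array(order, dtype=int)
    raise ValueError(
        f"no ordering with d_min={d_min} found in {max_restarts} restarts; "
        "try a smaller d_min"
    )


@dataclass
class EnsembleAssignment:
    """Disjoint groups of neuron indices plus the positions they index."""

    groups: list[np.ndarray]
    positions: np.ndarray

    def min_within_distance(self) -> float:
        """Smallest within-ensemble pairwise distance across all groups."""
        best = math.inf
        for g in self.groups:
            pts = self.positions[g]
            for i in range(len(pts)):
                d = np.linalg.norm(pts[i + 1 :] - pts[i], axis=1)
                if d.size:
                    best = min(best, float(d.min()))
        return best


def assign_ensembles(
    neuron_positions: np.ndarray,
    k: int,
    size_per_ensemble: int,
    seed: int = 0,
) -> EnsembleAssignment:
    """Partition neurons into ``k`` disjoint ensembles of equal size whose
    members are mutually far apart (greedy farthest-point selection).

    Each ensemble starts from a seed-random unassigned neuron; ensembles
    then take turns claiming the unassigned neuron that maximizes the
    minimum distance to their current members, so simultaneously stimulated
    neurons are spread out Poisson-disc style.
    """
    pos = np.asarray(neuron_positions, dtype=float)
    n = len(pos)
    if k < 1 or size_per_ensemble < 1 or k * size_per_ensemble > n:
        raise ValueError("infeasible ensemble sizes")
    rng = np.random.default_rng(seed)
    unassigned = set(range(n))
    starts = rng.choice(n, size=k, replace=False)
    groups: list[list[int]] = [[int(s)] for s in starts]
    unassigned -= set(int(s) for s in starts)
    # round-robin growth keeps ensembles balanced while maximizing spread
    for _ in range(size_per_ensemble - 1):
        for g in groups:
            cands = np.array(sorted(unassigned))
            dists = np.stack(
                [np.linalg.norm(pos[cands] - pos[m], axis=1) for m in g]
            ).min(axis=0)
            best = int(cands[int(np.argmax(dists))])
            g.append(best)
            unassigned.discard(best)
    return EnsembleAssignment(
        groups=[np.array(sorted(g), dtype=int) for g in groups], positions=pos
    )
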