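"""Time-series primitives for evoked responses and calcium activity.

Electrophysiology sweeps (postsynaptic currents in pA) and fluorescence
traces share the same layout: samples along the last axis, a pre-stimulus
baseline window, and a post-stimulus response window.  The mapping
measurement for a sweep is the peak magnitude of the baseline-subtracted
current in the response window; calcium analysis z-scores each trace
against its baseline and summarizes a recording as a (pattern × ROI) matrix
of repetition-averaged peak z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TraceSet",
    "LinearSumResult",
    "peak_current",
    "linear_sum_test",
    "zscore_traces",
    "peak_zscore_matrix",
]


@dataclass
class TraceSet:
    """A stack of uniformly sampled traces.

    ``data`` has samples on the last axis; leading axes are sweeps and/or
    ROIs.  ``onset_idx`` is the stimulus-onset sample (time origin is the
    start of the recording — for blanked-stimulus calcium imaging this is
    the start of imaging, immediately after photostimulation, so the onset
    is sample 0).  ``baseline`` is the (start, stop) sample span used for
    baseline statistics.
    """

    data: np.ndarray
    dt_ms: float
    onset_idx: int = 0
    baseline: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        T = self.data.shape[-1]
        if not 0 <= self.onset_idx < T:
            raise ValueError("onset outside trace length")
        if self.baseline is None and self.onset_idx > 0:
            self.baseline = (0, self.onset_idx)

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    def window_slice(self, window_ms: float) -> slice:
        """Post-onset response window of the given duration, in samples."""
        stop = min(
            self.n_samples, self.onset_idx + int(round(window_ms / self.dt_ms))
        )
        return slice(self.onset_idx, stop)


def _baseline_stats(
    data: np.ndarray, baseline: tuple[int, int] | None
) -> tuple[np.ndarray, np.ndarray]:
    if baseline is None or baseline[1] <= baseline[0]:
        # no pre-stimulus samples: zero baseline, unit scale
        shp = data.shape[:-1] + (1,)
        return np.zeros(shp), np.ones(shp)
    seg = data[..., baseline[0] : baseline[1]]
    return seg.mean(axis=-1, keepdims=True), seg.std(axis=-1, keepdims=True)


def peak_current(
    trace: np.ndarray,
    window: tuple[int, int],
    baseline: tuple[int, int] | None = None,
) -> float:
    """Peak response magnitude: max |trace − baseline mean| over the
    post-stimulus sample window.  Sign-invariant, so EPSCs (negative
    deflections under voltage clamp) and IPSCs give the same magnitude.
    """
    trace = np.asarray(trace, dtype=float)
    lo, hi = window
    if hi <= lo or lo < 0 or hi > trace.size:
        raise ValueError("empty or out-of-range window")
    if baseline is None:
        baseline = (0, lo)
    base, _ = _baseline_stats(trace[None, :], baseline)
    return float(np.abs(trace[lo:hi] - base[0, 0]).max())


@dataclass
class LinearSumResult:
    predictor: np.ndarray  # summed baseline-subtracted single-site traces
    joint: np.ndarray  # baseline-subtracted joint trace
    charge_joint: float  # trapezoidal integral over the window
    charge_predictor: float
    ratio: float  # joint / predictor charge; > 1 means supra-linear


def linear_sum_test(
    single_traces: np.ndarray,
    joint_trace: np.ndarray,
    window: tuple[int, int],
    dt_ms: float = 1.0,
    baseline: tuple[int, int] | None = None,
) -> LinearSumResult:
    """Compare a joint multi-site response with the sum of its singles.

    The linear predictor is the elementwise sum of the baseline-subtracted
    single-site traces; charges are trapezoidal integrals of |current| over
    the response window, and the ratio quantifies supra-(>1) or
    sub-(<1) linearity of synaptic integration.
    """
    singles = np.asarray(single_traces, dtype=float)
    joint = np.asarray(joint_trace, dtype=float)
    if singles.ndim != 2 or singles.shape[1] != joint.size:
        raise ValueError("single and joint traces must share one time base")
    lo, hi = window
    if hi <= lo or lo < 0 or hi > joint.size:
        raise ValueError("empty or out-of-range window")
    if baseline is None:
        baseline = (0, lo)
    base_s, _ = _baseline_stats(singles, baseline)
    base_j, _ = _baseline_stats(joint[None, :], baseline)
    predictor = (singles - base_s).sum(axis=0)
    joint_c = joint - base_j[0]
    dt_s = dt_ms / 1000.0
    q_joint = float(np.trapezoid(np.abs(joint_c[lo:hi]), dx=dt_s))
    q_pred = float(np.trapezoid(np.abs(predictor[lo:hi]), dx=dt_s))
    ratio = q_joint / q_pred if q_pred > 0 else np.nan
    return LinearSumResult(
        predictor=predictor,
        joint=joint_c,
        charge_joint=q_joint,
        charge_predictor=q_pred,
        ratio=ratio,
    )


def zscore_traces(traces: TraceSet) -> TraceSet:
    """Per-trace z-score against the baseline window:
    z = (F − baseline mean) / baseline sd.  A zero baseline sd is an error
    naming the offending ROI."""
    base, sd = _baseline_stats(traces.data, traces.baseline)
    bad = np.flatnonzero((sd == 0).reshape(-1))
    if bad.size:
        raise ValueError(f"zero baseline sd for trace(s) {bad.tolist()}")
    return replace(traces, data=(traces.data - base) / sd)


def peak_zscore_matrix(
    traces: TraceSet,
    pattern_labels: np.ndarray,
    window_ms: float = 1000.0,
) -> np.ndarray:
    """(pattern × ROI) matrix of repetition-averaged peak z-scores.

    ``traces.data`` must be (n_sweeps, n_rois, n_samples); each sweep is
    z-scored per ROI, the max z in the post-onset window is taken, and
    sweeps sharing a pattern label are averaged.  Pattern rows follow the
    sorted unique labels.
    """
    if traces.data.ndim != 3:
        raise ValueError("expected (n_sweeps, n_rois, n_samples) data")
    labels = np.asarray(pattern_labels)
    if labels.shape[0] != traces.data.shape[0]:
        raise ValueError("one pattern label per sweep required")
    z = zscore_traces(traces)
    win = z.window_slice(window_ms)
    peaks = z.data[..., win].max(axis=-1)  # (n_sweeps, n_rois)
    pats = np.unique(labels)
    return np.stack([peaks[labels == p].mean(axis=0) for p in pats])
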