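"""Trace preprocessing: ΔF/F, event detection, high-pass, z-score, binning.

The pipeline starts from a per-session fluorescence matrix (frames × neurons)
and produces the non-negative binned activity matrix that non-negative matrix
factorization operates on:

    raw F(t)  →  ΔF/F  →  high-pass (0.01 Hz)  →  rectified z-score  →  bins

ΔF/F uses the per-neuron session-mean fluorescence as F0, i.e.
``ΔF(t)/F0 = (F(t) − F0)/F0``.  Discrete calcium events are counted on the
ΔF/F traces as upward crossings of the joint threshold
``max(amplitude_threshold, sd_multiplier × SD)`` with a refractory period so
a burst counts once.  The high-pass stage removes slow baseline drift below
0.01 Hz; z-scoring standardizes each neuron over the session and rectification
zeroes negative values, giving the non-negativity NMF requires.  Finally the
trace is averaged into 4-frame (200 ms at 20 frames/s) bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger("nmfreact")

#: processing stages a TraceMatrix can be in, in pipeline order
STAGES = ("dff", "highpassed", "zscored_rectified")


class PreprocessError(ValueError):
    """Invalid input to a preprocessing stage."""


def _as_2d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise PreprocessError(f"trace matrix must be 2-D (frames × neurons), got shape {arr.shape}")
    return arr


def _default_ids(n: int) -> np.ndarray:
    return np.arange(n, dtype=int)


@dataclass
class FluorescenceMatrix:
    """Raw per-session fluorescence, frames × neurons, in arbitrary units."""

    values: np.ndarray
    frame_rate: float = 20.0
    session_id: str = ""
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        if self.values.shape[0] < 1:
            raise PreprocessError("fluorescence matrix needs at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise PreprocessError("fluorescence matrix contains non-finite values")
        if not self.frame_rate > 0:
            raise PreprocessError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.neuron_ids is None:
            self.neuron_ids = _default_ids(self.values.shape[1])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)
            if self.neuron_ids.shape != (self.values.shape[1],):
                raise PreprocessError("neuron_ids length must match the number of columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]


@dataclass
class TraceMatrix:
    """Processed traces (dimensionless), tagged with their pipeline stage."""

    values: np.ndarray
    stage: str
    frame_rate: float = 20.0
    session_id: str = ""
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        if self.stage not in STAGES:
            raise PreprocessError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage == "zscored_rectified" and np.any(self.values < 0):
            raise PreprocessError("rectified traces must be non-negative")
        if not self.frame_rate > 0:
            raise PreprocessError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.neuron_ids is None:
            self.neuron_ids = _default_ids(self.values.shape[1])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]


@dataclass
class BinnedMatrix:
    """Non-negative binned activity matrix, bins × neurons."""

    values: np.ndarray
    bin_frames: int
    bin_duration: float
    frame_rate: float = 20.0
    session_id: str = ""
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        if np.any(self.values < 0):
            raise PreprocessError("binned matrix must be non-negative")
        if self.neuron_ids is None:
            self.neuron_ids = _default_ids(self.values.shape[1])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EventDetectionConfig:
    """Thresholds for discrete calcium-event counting on ΔF/F traces.

    An event must exceed both an absolute amplitude (0.01 a.u.) and a
    per-neuron multiple of the session standard deviation (3 SD); crossings
    within ``refractory_frames`` of the previous event are suppressed so a
    single burst is counted once.
    """

    amplitude_threshold: float = 0.01
    sd_multiplier: float = 3.0
    refractory_frames: int = 10

    def __post_init__(self) -> None:
        if not (self.amplitude_threshold > 0 and self.sd_multiplier > 0):
            raise PreprocessError("event-detection thresholds must be positive")
        if self.refractory_frames < 0:
            raise PreprocessError("refractory_frames must be >= 0")


@dataclass
class EventCounts:
    """Per-neuron calcium-event counts for one session."""

    per_neuron: np.ndarray
    per_session_mean: float
    neuron_ids: np.ndarray
    session_id: str = ""

    def __post_init__(self) -> None:
        self.per_neuron = np.asarray(self.per_neuron, dtype=int)
        if np.any(self.per_neuron < 0):
            raise PreprocessError("event counts must be non-negative")


# ---------------------------------------------------------------------------
# stage 1: ΔF/F


def compute_dff(raw: FluorescenceMatrix) -> TraceMatrix:
    """Normalized fluorescence change (F(t) − F0)/F0 with F0 the session mean.

    Raises
    ------
    PreprocessError
        If any neuron's mean fluorescence is zero (ΔF/F undefined).
    """
    f0 = raw.values.mean(axis=0)
    bad = np.flatnonzero(f0 == 0)
    if bad.size:
        ids = [int(raw.neuron_ids[i]) for i in bad]
        raise PreprocessError(f"zero mean fluorescence (F0 = 0) for neuron id(s) {ids}; ΔF/F undefined")
    dff = (raw.values - f0) / f0
    return TraceMatrix(dff, stage="dff", frame_rate=raw.frame_rate,
                       session_id=raw.session_id, neuron_ids=raw.neuron_ids)


# ---------------------------------------------------------------------------
# stage 2: event counting (on ΔF/F)


def detect_events(traces: TraceMatrix, cfg: EventDetectionConfig | None = None) -> EventCounts:
    """Count discrete calcium events per neuron.

    An event is an upward crossing from below to above the per-neuron
    effective threshold ``max(amplitude_threshold, sd_multiplier * SD)``,
    where SD is taken over the whole session.  A trace that starts above
    threshold counts as one event at frame 0.  Consecutive suprathreshold
    frames count once, and crossings closer than ``refractory_frames`` to
    the previous event are suppressed.
    """
    if cfg is None:
        cfg = EventDetectionConfig()
    if traces.stage != "dff":
        raise PreprocessError(f"event detection runs on ΔF/F traces, got stage {traces.stage!r}")
    sd = traces.values.std(axis=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        logger.info("detect_events: %d zero-variance neuron(s) (ids %s) will report 0 events",
                    zero_var.size, [int(traces.neuron_ids[i]) for i in zero_var])
    thresholds = np.maximum(cfg.amplitude_threshold, cfg.sd_multiplier * sd)
    above = traces.values > thresholds  # frames × neurons
    counts = np.zeros(traces.n_neurons, dtype=int)
    for i in range(traces.n_neurons):
        col = above[:, i]
        rising = np.flatnonzero(col & ~np.concatenate(([False], col[:-1])))
        last = -np.inf
        n = 0
        for t in rising:
            if t - last >= cfg.refractory_frames:
                n += 1
                last = t
        counts[i] = n
    return EventCounts(per_neuron=counts, per_session_mean=float(counts.mean()),
                       neuron_ids=traces.neuron_ids, session_id=traces.session_id)


# ---------------------------------------------------------------------------
# stage 3: high-pass filtering


def highpass_filter(traces: TraceMatrix, cutoff_hz: float = 0.01, order: int = 4) -> TraceMatrix:
    """Zero-phase Butterworth high-pass per neuron; removes drift below cutoff.

    Forward-backward (zero-phase) filtering is used so event times are not
    shifted relative to ground truth.
    """
    if not traces.frame_rate > 2 * cutoff_hz:
        raise PreprocessError(
            f"frame_rate {traces.frame_rate} Hz must exceed twice the cutoff {cutoff_hz} Hz")
    # one filter time constant ~ 1/(2π·cutoff); very short sessions give edge-dominated output
    t_const_frames = traces.frame_rate / (2.0 * np.pi * cutoff_hz)
    if traces.n_frames < 3 * t_const_frames:
        warnings.warn(
            f"session of {traces.n_frames} frames is shorter than ~3 filter time constants "
            f"({3 * t_const_frames:.0f} frames) for a {cutoff_hz} Hz high-pass; "
            "edge effects may dominate", stacklevel=2)
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=traces.frame_rate, output="sos")
    # default sosfiltfilt padding (~a dozen frames) is far too short for a
    # cutoff whose time constant spans hundreds of frames; pad to ~3 time
    # constants so edge transients do not leak correlated artifacts
    padlen = min(traces.n_frames - 1, int(round(3 * t_const_frames)))
    filtered = signal.sosfiltfilt(sos, traces.values, axis=0, padlen=padlen)
    return TraceMatrix(filtered, stage="highpassed", frame_rate=traces.frame_rate,
                       session_id=traces.session_id, neuron_ids=traces.neuron_ids)


# ---------------------------------------------------------------------------
# stage 4: z-score + rectification


def zscore_rectify(traces: TraceMatrix) -> TraceMatrix:
    """Per-neuron session z-score with negative values replaced by zero.

    A zero-SD neuron cannot be standardized; its column is set to all zeros
    and the case is logged.
    """
    if traces.stage != "highpassed":
        raise PreprocessError(f"z-scoring expects high-passed traces, got stage {traces.stage!r}")
    mean = traces.values.mean(axis=0)
    sd = traces.values.std(axis=0)
    zero_var = sd == 0
    if np.any(zero_var):
        logger.info("zscore_rectify: zero-SD neuron(s) %s set to all zeros",
                    [int(traces.neuron_ids[i]) for i in np.flatnonzero(zero_var)])
    safe_sd = np.where(zero_var, 1.0, sd)
    z = (traces.values - mean) / safe_sd
    z[:, zero_var] = 0.0
    np.clip(z, 0.0, None, out=z)
    return TraceMatrix(z, stage="zscored_rectified", frame_rate=traces.frame_rate,
                       session_id=traces.session_id, neuron_ids=traces.neuron_ids)


# ---------------------------------------------------------------------------
# stage 5: temporal binning


def bin_traces(traces: TraceMatrix, bin_frames: int = 4, agg: str = "mean") -> BinnedMatrix:
    """Average (or sum) every ``bin_frames`` frames; the trailing partial bin is dropped.

    With the 20 frames/s default rate and 4-frame bins each bin spans 200 ms.
    ``agg="mean"`` keeps values on the z-score scale regardless of bin size;
    ``agg="sum"`` is available for total-activity bins.
    """
    if traces.stage != "zscored_rectified":
        raise PreprocessError(f"binning expects rectified z-scores, got stage {traces.stage!r}")
    if bin_frames < 1:
        raise PreprocessError("bin_frames must be >= 1")
    if traces.n_frames < bin_frames:
        raise PreprocessError(
            f"cannot bin {traces.n_frames} frames into bins of {bin_frames}")
    if agg not in ("mean", "sum"):
        raise PreprocessError(f"agg must be 'mean' or 'sum', got {agg!r}")
    n_bins = traces.n_frames // bin_frames
    trimmed = traces.values[: n_bins * bin_frames]
    reshaped = trimmed.reshape(n_bins, bin_frames, traces.n_neurons)
    binned = reshaped.mean(axis=1) if agg == "mean" else reshaped.sum(axis=1)
    return BinnedMatrix(binned, bin_frames=bin_frames,
                        bin_duration=bin_frames / traces.frame_rate,
                        frame_rate=traces.frame_rate,
                        session_id=traces.session_id, neuron_ids=traces.neuron_ids)


def preprocess_session(raw: FluorescenceMatrix, cutoff_hz: float = 0.01,
                       bin_frames: int = 4) -> BinnedMatrix:
    """Run the full chain raw → ΔF/F → high-pass → rectified z-score → bins."""
    return bin_traces(zscore_rectify(highpass_filter(compute_dff(raw), cutoff_hz)),
                      bin_frames=bin_frames)
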