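"""Force/marker signal containers, zero-lag filtering, onset detection, windowing.

The measurement chain this mirrors: uniaxial load cells sampled at 1 MHz and
optical motion capture at 4 kHz.  Impact onset is the first sample at which
the cranial force, referenced to its pre-impact baseline (the constant
preload), strictly exceeds a 200 N threshold; the analysis window is the
5 ms after onset, which contains the cranial load peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "ForceTrace",
    "MarkerTrajectories",
    "zero_lag_lowpass",
    "detect_impact_onset",
    "align_and_window",
    "DEFAULT_FORCE_FS",
    "DEFAULT_MARKER_FS",
    "DEFAULT_ONSET_THRESHOLD_N",
    "DEFAULT_WINDOW_S",
    "DEFAULT_FORCE_CUTOFF_HZ",
    "DEFAULT_MARKER_CUTOFF_HZ",
]

DEFAULT_FORCE_FS = 1.0e6
DEFAULT_MARKER_FS = 4.0e3
DEFAULT_ONSET_THRESHOLD_N = 200.0
DEFAULT_WINDOW_S = 0.005
DEFAULT_FORCE_CUTOFF_HZ = 5000.0
DEFAULT_MARKER_CUTOFF_HZ = 150.0
#: span used to estimate the pre-impact baseline (median of the first 10 ms)
BASELINE_SPAN_S = 0.010


@dataclass
class ForceTrace:
    """Uniformly sampled axial force. Compressive force is stored positive."""

    samples: np.ndarray
    fs: float = DEFAULT_FORCE_FS
    t0: float = 0.0
    label: str = "cranial"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("force samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("force samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.fs

    def slice_time(self, start: float, stop: float) -> "ForceTrace":
        """Samples with timestamps in the half-open interval [start, stop)."""
        t = self.times
        idx = np.flatnonzero((t >= start - 1e-12) & (t < stop - 1e-12))
        if idx.size == 0:
            raise ValueError("empty force window")
        return ForceTrace(self.samples[idx], fs=self.fs,
                          t0=float(t[idx[0]]), label=self.label)


@dataclass
class MarkerTrajectories:
    """3D marker positions on a shared uniform time base (metres).

    ``positions`` has shape (n_frames, n_markers, 3); gaps (NaN frames) are
    an input error.
    """

    names: list[str]
    positions: np.ndarray
    fs: float = DEFAULT_MARKER_FS
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[1] != len(self.names):
            raise ValueError("marker name count does not match position columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("marker names must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("marker positions contain gaps (non-finite frames)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fs

    def reordered(self, names: list[str]) -> "MarkerTrajectories":
        idx = [self.names.index(n) for n in names]
        return MarkerTrajectories(list(names), self.positions[:, idx, :],
                                  fs=self.fs, t0=self.t0)

    def slice_time(self, start: float, stop: float) -> "MarkerTrajectories":
        """Frames with timestamps in the closed interval [start, stop]."""
        t = self.times
        idx = np.flatnonzero((t >= start - 1e-9) & (t <= stop + 1e-9))
        if idx.size == 0:
            raise ValueError("empty marker window")
        return MarkerTrajectories(self.names, self.positions[idx],
                                  fs=self.fs, t0=float(t[idx[0]]))

    def filtered(self, cutoff: float, order: int = 4) -> "MarkerTrajectories":
        flat = self.positions.reshape(self.n_frames, -1)
        out = np.column_stack([
            zero_lag_lowpass(flat[:, c], self.fs, cutoff, order=order)
            for c in range(flat.shape[1])
        ])
        return replace(self, positions=out.reshape(self.positions.shape))


def zero_lag_lowpass(x: np.ndarray, fs: float, cutoff: float,
                     order: int = 4, net_order: bool = True) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward + backward pass).

    With ``net_order=True`` (the conventional biomechanics reading of a
    "zero-lag fourth-order" filter) a Butterworth of ``order / 2`` is applied
    once forward and once backward so the combined response has the stated
    order; with ``net_order=False`` the stated order is applied per pass.
    Edges are handled by reflective padding of three filter lengths.
    """
    x = np.asarray(x, dtype=float)
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    if net_order:
        if order % 2 != 0:
            raise ValueError("net filter order must be even")
        design_order = order // 2
    else:
        design_order = order
    padlen = 3 * max(12, 2 * design_order)
    if x.shape[0] <= padlen:
        padlen = x.shape[0] - 1
    if padlen < 3 * design_order:
        raise ValueError("signal too short for edge padding")
    sos = _sig.butter(design_order, cutoff, btype="low", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x, padlen=padlen)


def _baseline(trace: ForceTrace, span_s: float = BASELINE_SPAN_S,
              threshold_N: float = DEFAULT_ONSET_THRESHOLD_N) -> float:
    """Pre-impact baseline: median of the leading quiet span.

    The span is the first ``span_s`` of the recording, truncated at the
    first sample whose raw value exceeds the onset threshold so that the
    impact itself never contaminates the estimate.
    """
    above = np.flatnonzero(trace.samples > threshold_N)
    n = min(trace.n, int(round(span_s * trace.fs)))
    if above.size:
        n = min(n, int(above[0]))
    return float(np.median(trace.samples[:max(1, n)]))


def detect_impact_onset(trace: ForceTrace,
                        threshold_N: float = DEFAULT_ONSET_THRESHOLD_N,
                        baseline_span_s: float = BASELINE_SPAN_S) -> int:
    """Index of the first sample strictly exceeding the onset threshold.

    The threshold is applied to the baseline-referenced trace: the constant
    preload (estimated as the median of the first ``baseline_span_s`` of the
    recording) is subtracted first, so that a 152 N preload sitting just
    below a 200 N threshold cannot mask or fake an onset.
    """
    rel = trace.samples - _baseline(trace, baseline_span_s)
    above = np.flatnonzero(rel > threshold_N)
    if above.size == 0:
        raise ValueError("no impact detected: threshold never exceeded")
    return int(above[0])


def align_and_window(
    force: ForceTrace,
    markers: MarkerTrajectories,
    onset: int,
    window_s: float = DEFAULT_WINDOW_S,
    subtract_baseline: bool = True,
) -> tuple[ForceTrace, MarkerTrajectories]:
    """Cut the synchronized analysis window starting at the onset sample.

    The force window is half-open ``[t_onset, t_onset + window_s)`` at the
    force rate; the marker window keeps every frame whose timestamp falls in
    the closed interval (21 frames for a 5 ms window at 4 kHz when the onset
    lands on a frame).  With ``subtract_baseline`` the pre-onset force
    baseline (the preload) is removed from the returned force window, making
    it the net impact drive force.
    """
    if onset < 0 or onset >= force.n:
        raise ValueError("onset outside the force recording")
    t_on = float(force.times[onset])
    t_end = t_on + window_s
    if t_end > force.times[-1] + 0.5 / force.fs:
        raise ValueError("window extends past the end of the force recording")
    if t_end > markers.times[-1] + 0.5 / markers.fs:
        raise ValueError("window extends past the end of the marker recording")
    fwin = force.slice_time(t_on, t_end)
    if subtract_baseline:
        fwin = ForceTrace(fwin.samples - _baseline(force), fs=fwin.fs,
                          t0=fwin.t0, label=fwin.label)
    mwin = markers.slice_time(t_on, t_end)
    return fwin, mwin
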