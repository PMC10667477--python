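"""Automated signal conditioning: filtering, average re-reference,
distance-weighted bad-channel interpolation, amplitude-threshold
artifact-span rejection.

The "48-52 Hz" stage is implemented as a band-STOP around the 50 Hz
mains frequency; a literal band-pass reading is available behind
``literal_bandpass=True`` for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Montage, Recording

__all__ = [
    "FilterSpec",
    "apply_filters",
    "rereference_average",
    "interpolate_channels",
    "reject_artifact_spans",
    "drop_episodes_in_spans",
]


@dataclass(frozen=True)
class FilterSpec:
    highpass_hz: float = 0.5
    notch_band_hz: tuple[float, float] = (48.0, 52.0)
    order: int = 4
    literal_bandpass: bool = False  # treat the notch band as a pass band

    def __post_init__(self):
        if self.highpass_hz <= 0:
            raise ValueError("highpass_hz must be positive")
        lo, hi = self.notch_band_hz
        if not lo < hi:
            raise ValueError("notch band must be ordered (low, high)")


def apply_filters(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass plus 50 Hz band-stop.

    Forward-backward (``sosfiltfilt``) filtering keeps decision-time
    alignment intact. Requires ``sampling_rate > 2 * notch upper edge``.
    """
    fs = recording.sampling_rate
    lo, hi = spec.notch_band_hz
    if fs <= 2 * hi:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {lo}-{hi} Hz stage (need > {2 * hi})"
        )
    if spec.literal_bandpass:
        sos = sps.butter(spec.order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos, recording.data, axis=1)
    else:
        sos_hp = sps.butter(spec.order, spec.highpass_hz, btype="highpass", fs=fs, output="sos")
        sos_notch = sps.butter(spec.order, [lo, hi], btype="bandstop", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos_hp, recording.data, axis=1)
        out = sps.sosfiltfilt(sos_notch, out, axis=1)
    return recording.copy_with(data=out)


def rereference_average(recording: Recording, exclude: set[str] = frozenset()) -> Recording:
    """Re-reference to the average over all included measurement channels.

    After this the mean over included channels is zero at every sample.
    Excluded (e.g. rejected) channels have the same average subtracted so
    the recording stays in a single reference frame.
    """
    included = [i for i, ch in enumerate(recording.channel_names) if ch not in exclude]
    if len(included) < 2:
        raise ValueError("average reference needs at least 2 included channels")
    avg = recording.data[included].mean(axis=0, keepdims=True)
    return recording.copy_with(data=recording.data - avg, reference_state="average")


def interpolate_channels(recording: Recording, bad: set[str], montage: Montage) -> Recording:
    """Replace bad channels by the inverse-distance weighted average of
    their good montage neighbors; good channels are untouched."""
    index = {ch: i for i, ch in enumerate(recording.channel_names)}
    unknown = [ch for ch in bad if ch not in index]
    if unknown:
        raise ValueError(f"bad channels not in recording: {sorted(unknown)}")
    out = recording.data.copy()
    for ch in sorted(bad):
        nbrs = [
            (other, dist)
            for other, dist in montage.neighbor_graph.get(ch, ())
            if other in index and other not in bad
        ]
        if not nbrs:
            raise ValueError(f"channel {ch!r} has no good neighbors to interpolate from")
        weights = np.array([1.0 / dist for _, dist in nbrs])
        stack = np.stack([recording.data[index[other]] for other, _ in nbrs])
        out[index[ch]] = weights @ stack / weights.sum()
    return recording.copy_with(data=out)


def reject_artifact_spans(recording: Recording, threshold_uv: float) -> list[tuple[float, float]]:
    """Flag time spans where any channel exceeds ``±threshold_uv``.

    Returns merged half-open ``(start, end)`` spans in seconds; episodes
    overlapping a flagged span should be dropped downstream (see
    :func:`drop_episodes_in_spans`).
    """
    if not threshold_uv > 0:
        raise ValueError("threshold must be positive")
    exceeded = np.any(np.abs(recording.data) > threshold_uv, axis=0)
    if not exceeded.any():
        return []
    idx = np.flatnonzero(exceeded)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1
    fs = recording.sampling_rate
    t0 = recording.start_time
    return [(t0 + s / fs, t0 + e / fs) for s, e in zip(starts, ends)]


def drop_episodes_in_spans(episodes, spans):
    """Split episodes into (kept, dropped) by overlap with flagged spans.

    An episode ``[start_time, decision_time)`` is dropped when it
    intersects any flagged span.
    """
    kept, dropped = [], []
    for ep in episodes:
        hit = any(ep.start_time < end and start < ep.decision_time for start, end in spans)
        (dropped if hit else kept).append(ep)
    return kept, dropped
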