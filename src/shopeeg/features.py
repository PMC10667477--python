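"""Feature extraction: temporal-jitter augmentation, global-field-power
anchoring, tau-window extraction, Hjorth parameters and the Morlet
wavelet band-power baseline.

Every labeled episode with decision time ``t`` is augmented into four
100-ms seed windows ``[t-200, t-100)``, ``[t-100, t)``, ``[t, t+100)``
and ``[t+100, t+200)`` (milliseconds), absorbing the ~200 ms human error
in marking page-leave times. Inside each seed window the sample of
maximum global field power (GFP, the spatial standard deviation across
electrodes) anchors a tau-long snippet (tau in {1200, 1400, 1600, 1800,
2000} ms) from which per-channel Hjorth parameters are computed:

    activity   m0 = <f^2>                (signal variance, µV²)
    m2         = <(df/dt)^2>
    m4         = <(d²f/dt²)^2>
    mobility   = sqrt(m2/m0)             (mean spectral frequency, rad/s)
    complexity = sqrt(m4/m2)/sqrt(m2/m0) (bandwidth; 1 for a pure sinusoid)

Derivatives are finite differences scaled by the sampling interval, so
mobility is in rad/s; the classic unscaled per-sample variant is
available via ``scale_derivatives=False`` (a monotone rescaling that
leaves classification unchanged). The per-snippet feature vector is
min-max normalized across channels to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Recording
from .segment import LabeledEpisode

__all__ = [
    "JITTER_OFFSETS_MS",
    "SEED_WINDOW_MS",
    "TAUS_MS",
    "DegenerateSignalError",
    "JitterWindow",
    "Snippet",
    "make_jitter_windows",
    "gfp",
    "find_gfp_peak",
    "extract_snippet",
    "hjorth_parameters",
    "feature_vector",
    "minmax_normalize",
    "wavelet_band_power",
    "build_feature_table",
    "FREQUENCY_BANDS",
]

logger = logging.getLogger(__name__)

JITTER_OFFSETS_MS = (-200, -100, 0, 100)
SEED_WINDOW_MS = 100
TAUS_MS = (1200, 1400, 1600, 1800, 2000)
FREQUENCY_BANDS = {"theta": (5.0, 7.0), "alpha": (8.0, 13.0)}
HJORTH_PARAMETERS = ("activity", "mobility", "complexity")


class DegenerateSignalError(ValueError):
    """Signal is constant: Hjorth mobility/complexity undefined."""


@dataclass(frozen=True)
class JitterWindow:
    """A 100-ms augmentation seed window anchored at ``t + offset``."""

    episode_id: str
    offset_ms: int
    start: float  # s, inclusive
    end: float    # s, exclusive
    gfp_peak_time: float | None = None


@dataclass(frozen=True)
class Snippet:
    """A tau-long multi-channel segment anchored on a GFP peak."""

    episode_id: str
    offset_ms: int
    tau_ms: int
    signal: np.ndarray  # (n_channels, tau*rate/1000)
    sampling_rate: float
    label: str | None = None
    subject_id: str | None = None
    shifted: bool = False  # window moved to fit recording bounds


def make_jitter_windows(episode, recording: Recording) -> list[JitterWindow]:
    """Four 100-ms seed windows at offsets {-200, -100, 0, +100} ms.

    Returns [] (and logs why) when the recording does not cover
    ``[t - 200 ms, t + 200 ms]``.
    """
    t = episode.decision_time
    lo = t + JITTER_OFFSETS_MS[0] / 1000.0
    hi = t + (JITTER_OFFSETS_MS[-1] + SEED_WINDOW_MS) / 1000.0
    rec_end = recording.start_time + recording.duration
    if lo < recording.start_time or hi > rec_end:
        logger.info(
            "episode %s skipped: seed windows [%.3f, %.3f) outside recording [%.3f, %.3f)",
            episode.episode_id, lo, hi, recording.start_time, rec_end,
        )
        return []
    return [
        JitterWindow(
            episode_id=episode.episode_id,
            offset_ms=off,
            start=t + off / 1000.0,
            end=t + (off + SEED_WINDOW_MS) / 1000.0,
        )
        for off in JITTER_OFFSETS_MS
    ]


def gfp(signal: np.ndarray) -> np.ndarray:
    """Global field power: population std across channels per sample."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[0] < 2:
        raise ValueError("GFP needs a (channels >= 2) x samples array")
    return signal.std(axis=0, ddof=0)


def find_gfp_peak(window: JitterWindow, recording: Recording) -> float:
    """Time of maximum GFP within the seed window; ties -> earliest."""
    i0 = recording.time_to_sample(window.start)
    i1 = recording.time_to_sample(window.end)
    if i0 < 0 or i1 > recording.n_samples or i1 <= i0:
        raise ValueError(f"window [{window.start}, {window.end}) outside recording")
    trace = gfp(recording.data[:, i0:i1])
    peak = int(np.argmax(trace))  # argmax returns the first maximum
    return recording.sample_to_time(i0 + peak)


def extract_snippet(
    peak_time: float,
    tau_ms: int,
    recording: Recording,
    placement: str = "centered",
) -> tuple[np.ndarray, bool] | None:
    """Cut a half-open tau-long window anchored on ``peak_time``.

    ``centered`` places the window symmetrically around the peak;
    ``causal`` ends it at the peak (real-time reading). Windows that
    would cross the recording bounds are shifted minimally to fit
    (never zero-padded); returns ``(signal, shifted)`` or None when the
    recording is shorter than tau.
    """
    n = int(round(tau_ms * recording.sampling_rate / 1000.0))
    if n > recording.n_samples:
        logger.info("snippet skipped: recording shorter than tau=%d ms", tau_ms)
        return None
    peak_idx = recording.time_to_sample(peak_time)
    if placement == "centered":
        start = peak_idx - n // 2
    elif placement == "causal":
        start = peak_idx - n + 1
    else:
        raise ValueError(f"unknown placement {placement!r}")
    shifted = False
    if start < 0:
        start, shifted = 0, True
    elif start + n > recording.n_samples:
        start, shifted = recording.n_samples - n, True
    if shifted:
        logger.info("snippet at %.3f s shifted to fit recording bounds", peak_time)
    return recording.data[:, start:start + n].copy(), shifted


def hjorth_parameters(
    signal: np.ndarray,
    rate: float,
    scale_derivatives: bool = True,
    demean: bool = True,
) -> tuple[float, float, float]:
    """(activity, mobility, complexity) of a single-channel window.

    The window mean is removed first so activity equals the variance;
    finite-difference derivatives are scaled by the sampling interval
    when ``scale_derivatives`` (mobility then in rad/s).
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if demean:
        x = x - x.mean()
    m0 = float(np.mean(x * x))
    if m0 == 0.0:
        raise DegenerateSignalError("constant signal: Hjorth parameters undefined")
    scale = rate if scale_derivatives else 1.0
    d1 = np.diff(x) * scale
    d2 = np.diff(x, 2) * scale * scale
    m2 = float(np.mean(d1 * d1))
    m4 = float(np.mean(d2 * d2))
    mobility = np.sqrt(m2 / m0)
    if m2 == 0.0:
        raise DegenerateSignalError("zero first-derivative power: complexity undefined")
    complexity = np.sqrt(m4 / m2) / mobility
    return m0, float(mobility), float(complexity)


def hjorth_matrix(signal: np.ndarray, rate: float, scale_derivatives: bool = True) -> np.ndarray:
    """Vectorized per-channel Hjorth parameters.

    Returns an (n_channels, 3) array of (activity, mobility, complexity).
    """
    x = np.asarray(signal, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    m0 = np.mean(x * x, axis=1)
    if np.any(m0 == 0.0):
        raise DegenerateSignalError("constant channel in snippet")
    scale = rate if scale_derivatives else 1.0
    d1 = np.diff(x, axis=1) * scale
    d2 = np.diff(x, 2, axis=1) * scale * scale
    m2 = np.mean(d1 * d1, axis=1)
    m4 = np.mean(d2 * d2, axis=1)
    mobility = np.sqrt(m2 / m0)
    complexity = np.sqrt(m4 / m2) / mobility
    return np.column_stack([m0, mobility, complexity])


def feature_vector(
    snippet: Snippet,
    parameter: str = "mobility",
    scale_derivatives: bool = True,
) -> np.ndarray:
    """One Hjorth parameter per signal channel, in montage channel order."""
    if parameter not in HJORTH_PARAMETERS:
        raise ValueError(f"unknown Hjorth parameter {parameter!r}")
    mat = hjorth_matrix(snippet.signal, snippet.sampling_rate, scale_derivatives)
    return mat[:, HJORTH_PARAMETERS.index(parameter)]


def minmax_normalize(vector: np.ndarray) -> np.ndarray:
    """Scale one feature vector to [0, 1] across channels."""
    v = np.asarray(vector, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateSignalError("constant feature vector: min-max undefined")
    return (v - lo) / (hi - lo)


def wavelet_band_power(snippet: Snippet, band: str) -> np.ndarray:
    """Mean Morlet (7-cycle) power in the theta (5-7 Hz) or alpha
    (8-13 Hz) band, per channel, on a 1 Hz frequency grid.

    Errors when the snippet is too short to hold 7 cycles of the band's
    lowest frequency (a 1200 ms window cannot carry 5 Hz theta).

    The complex Morlet wavelets (Gaussian sd ``n_cycles/(2*pi*f)``,
    truncated at ±3 sd) are convolved in 'same' mode, so a window of at
    least 7 cycles always accommodates the wavelet.
    """
    from scipy.signal import fftconvolve

    if band not in FREQUENCY_BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {sorted(FREQUENCY_BANDS)}")
    lo, hi = FREQUENCY_BANDS[band]
    n_cycles = 7.0
    fs = snippet.sampling_rate
    n_samp = snippet.signal.shape[1]
    duration = n_samp / fs
    if duration < n_cycles / lo:
        raise ValueError(
            f"window of {duration * 1000:.0f} ms too short for {n_cycles:.0f} cycles "
            f"at {lo:g} Hz (needs {1000 * n_cycles / lo:.0f} ms)"
        )
    sig = snippet.signal - snippet.signal.mean(axis=1, keepdims=True)
    freqs = np.arange(lo, hi + 0.5, 1.0)
    band_power = np.zeros(sig.shape[0])
    for f in freqs:
        sigma_t = n_cycles / (2.0 * np.pi * f)
        half = int(np.floor(3.0 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        wavelet = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
        wavelet /= np.sqrt(0.5) * np.linalg.norm(wavelet)
        conv = fftconvolve(sig, wavelet[np.newaxis, :], mode="same", axes=1)
        band_power += np.mean(np.abs(conv) ** 2, axis=1)
    return band_power / len(freqs)


def build_feature_table(
    recording: Recording,
    labeled_episodes: list[LabeledEpisode],
    taus_ms=(1200,),
    parameter: str = "mobility",
    normalize: bool = True,
    placement: str = "centered",
    scale_derivatives: bool = True,
    feature: str = "hjorth",
) -> pd.DataFrame:
    """Augment, anchor and featurize all episodes of one session.

    Returns one row per (eligible episode x offset x tau) with columns
    ``subject_id, episode_id, offset_ms, tau_ms, label, ch_<name>...``.
    Bookkeeping (eligible/skipped counts) lands in ``df.attrs``.
    """
    rows = []
    n_skipped_episodes = 0
    n_shifted = 0
    ch_cols = [f"ch_{name}" for name in recording.channel_names]
    for le in labeled_episodes:
        windows = make_jitter_windows(le.episode, recording)
        if not windows:
            n_skipped_episodes += 1
            continue
        for win in windows:
            peak_time = find_gfp_peak(win, recording)
            for tau in taus_ms:
                cut = extract_snippet(peak_time, tau, recording, placement)
                if cut is None:
                    continue
                sig, shifted = cut
                n_shifted += int(shifted)
                snip = Snippet(
                    episode_id=le.episode.episode_id,
                    offset_ms=win.offset_ms,
                    tau_ms=tau,
                    signal=sig,
                    sampling_rate=recording.sampling_rate,
                    label=le.label,
                    subject_id=le.episode.subject_id,
                )
                if feature == "hjorth":
                    vec = feature_vector(snip, parameter, scale_derivatives)
                elif feature in FREQUENCY_BANDS:
                    vec = wavelet_band_power(snip, feature)
                else:
                    raise ValueError(f"unknown feature {feature!r}")
                if normalize:
                    vec = minmax_normalize(vec)
                row = {
                    "subject_id": le.episode.subject_id,
                    "episode_id": le.episode.episode_id,
                    "offset_ms": win.offset_ms,
                    "tau_ms": tau,
                    "label": le.label,
                }
                row.update(zip(ch_cols, vec))
                rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", "episode_id", "offset_ms", "tau_ms", "label"] + ch_cols)
    df.attrs["n_episodes"] = len(labeled_episodes)
    df.attrs["n_skipped_episodes"] = n_skipped_episodes
    df.attrs["n_shifted_snippets"] = n_shifted
    return df
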