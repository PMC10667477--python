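"""Synthetic EEG shopping-session generator.

Emulates the statistical structure the decoding pipeline assumes: each
subject browses ~8 product pages (lognormal viewing times, mean 9.82 s),
views carry buy/cart/no-buy fates mixed 24/25/51 at the view level, and
the continuous 61-channel 500 Hz EEG is pink (1/f) background plus
band-limited alpha (~10 Hz, occipital topography) and theta (~6 Hz,
frontal topography) oscillations plus white sensor noise.

The label-dependent signal is a shift of the alpha *center frequency*
during the final ``min(view duration, 2 s)`` before each decision time:
``f_alpha = 10 + subject_offset + effect_size * delta_label`` with
deltas (no_buy, cart, buy) = (-1, +0.5, +1), cart lying close to buy
because both express a positive attitude toward the product (the
rationale for merging them in two-class tagging). Hjorth mobility is
the power
spectrum's mean frequency, so the planted effect is analytically
recoverable by the feature the pipeline extracts; the generator makes
no claim of biological realism beyond that.

Product-view grammar: each product receives 1-6 views (capped
geometric); its fate is none / cart-only / buy, a bought product having
passed through the cart (at an earlier view) with probability
``cart_given_buy``. Cart-removal never occurs. Fate probabilities are
solved analytically so the *expected view-level* label fractions equal
``label_probs`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Montage, Recording

__all__ = ["GeneratorConfig", "SessionBundle", "generate_session", "generate_cohort"]

# cart sits close to buy: both express a positive purchase attitude,
# which is the stated rationale for merging them in the two-class scheme
LABEL_DELTAS = {"no_buy": -1.0, "cart": 0.5, "buy": 1.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_subjects: int = 12
    pages_per_subject_mean: float = 8.38
    view_duration_mean_s: float = 9.82
    view_duration_sd_s: float = 10.89
    label_probs: tuple[float, float, float] = (0.24, 0.25, 0.51)  # buy, cart, no_buy
    sampling_rate: float = 500.0
    effect_size_hz: float = 1.0
    subject_sd_hz: float = 0.5
    noise_sd_uv: float = 0.75
    noise_lowpass_hz: float = 45.0
    alpha_amp_uv: float = 10.0
    theta_amp_uv: float = 4.0
    pink_sd_uv: float = 2.0
    alpha_freq_hz: float = 10.0
    theta_freq_hz: float = 6.0
    decision_window_s: float = 2.0
    views_per_product_geom_p: float = 0.5
    max_views_per_product: int = 6
    cart_given_buy: float = 0.4
    min_view_duration_s: float = 0.6
    gap_mean_s: float = 1.5
    pad_start_s: float = 5.0
    pad_end_s: float = 3.0
    subject_label_kappa: float | None = None  # Dirichlet concentration: per-subject label bias
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.label_probs) - 1.0) > 1e-12:
            raise ValueError("label_probs must sum to 1")
        if min(self.label_probs) < 0:
            raise ValueError("label_probs must be non-negative")
        if self.n_subjects < 1 or self.max_views_per_product < 1:
            raise ValueError("counts must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.effect_size_hz < 0:
            raise ValueError("effect_size_hz must be >= 0")
        if self.view_duration_mean_s <= 0 or self.min_view_duration_s <= 0:
            raise ValueError("durations must be positive")


@dataclass
class SessionBundle:
    """One subject's recording, event log and ground-truth view labels."""

    recording: Recording
    events: pd.DataFrame
    subject_id: str
    ground_truth_labels: list[str]  # three-class label per event row
    montage: Montage = field(repr=False, default=None)


def _views_pmf(cfg: GeneratorConfig) -> np.ndarray:
    """PMF of views per product: geometric(p) capped at max views."""
    p, m = cfg.views_per_product_geom_p, cfg.max_views_per_product
    pmf = np.array([p * (1 - p) ** (n - 1) for n in range(1, m)])
    return np.append(pmf, 1.0 - pmf.sum())


def _fate_probs(cfg: GeneratorConfig, label_probs, clip: bool = False) -> tuple[float, float, float]:
    """Product-fate probabilities (buy, cart-only, none) chosen so the
    expected view-level label mix equals ``label_probs``.

    A carted-then-bought product splits its views exactly half/half in
    expectation (cart view K uniform on 1..n-1 has E[K] = n/2), so with
    mu = E[n] and mu2 = E[n; n>=2]:
        pi_buy * (mu - r*mu2/2) = p_buy * mu.
    """
    p_buy, p_cart, p_nobuy = label_probs
    pmf = _views_pmf(cfg)
    ns = np.arange(1, cfg.max_views_per_product + 1)
    mu = float(pmf @ ns)
    mu2 = float(pmf[1:] @ ns[1:])
    r = cfg.cart_given_buy
    pi_buy = p_buy * mu / (mu - r * mu2 / 2.0)
    pi_none = p_nobuy
    pi_cart = 1.0 - pi_buy - pi_none
    if pi_cart < 0:
        if not clip:
            raise ValueError("cart_given_buy too large for the requested label mix")
        pi_buy, pi_cart = 1.0 - pi_none, 0.0  # extreme per-subject bias draw
    return pi_buy, pi_cart, pi_none


def _session_structure(rng: np.random.Generator, cfg: GeneratorConfig, subject_id: str):
    """Draw the event-log skeleton (no EEG): interleaved product views
    with enter/leave/action times and ground-truth three-class labels."""
    label_probs = cfg.label_probs
    biased = cfg.subject_label_kappa is not None
    if biased:
        alpha = np.asarray(cfg.label_probs) * cfg.subject_label_kappa
        label_probs = tuple(rng.dirichlet(alpha))
    pi = _fate_probs(cfg, label_probs, clip=biased)
    pmf = _views_pmf(cfg)
    mu = float(pmf @ np.arange(1, cfg.max_views_per_product + 1))
    n_products = max(1, int(rng.poisson(cfg.pages_per_subject_mean / mu)))

    products = []
    for g in range(n_products):
        n_views = 1 + int(rng.choice(cfg.max_views_per_product, p=pmf))
        fate = rng.choice(3, p=pi)  # 0 buy, 1 cart-only, 2 none
        cart_view = buy_view = None
        if fate == 0:
            if n_views >= 2 and rng.random() < cfg.cart_given_buy:
                cart_view = int(rng.integers(1, n_views))          # 1..n-1
                buy_view = int(rng.integers(cart_view + 1, n_views + 1))
            else:
                buy_view = int(rng.integers(1, n_views + 1))
        elif fate == 1:
            cart_view = int(rng.integers(1, n_views + 1))
        if cart_view is None and buy_view is None:
            labels = ["no_buy"] * n_views
        elif buy_view is None:
            labels = ["cart"] * n_views
        elif cart_view is None:
            labels = ["buy"] * n_views
        else:
            labels = ["cart"] * cart_view + ["buy"] * (n_views - cart_view)
        products.append({"n_views": n_views, "cart_view": cart_view,
                         "buy_view": buy_view, "labels": labels})

    # interleave: shuffle a token list; the j-th token of product g is view j
    tokens = np.repeat(np.arange(n_products), [p["n_views"] for p in products])
    rng.shuffle(tokens)

    rows, labels = [], []
    t = cfg.pad_start_s
    seen: dict[int, int] = {}
    for g in tokens:
        view = seen.get(g, 0) + 1
        seen[int(g)] = view
        duration = max(
            cfg.min_view_duration_s,
            float(rng.lognormal(*_lognormal_params(cfg.view_duration_mean_s, cfg.view_duration_sd_s))),
        )
        enter, leave = t, t + duration
        prod = products[int(g)]
        action, action_time = "none", np.nan
        if prod["cart_view"] == view:
            action = "cart"
        elif prod["buy_view"] == view:
            action = "buy"
        if action != "none":
            action_time = enter + duration * float(rng.uniform(0.5, 0.95))
        rows.append({
            "subject_id": subject_id,
            "product_id": f"{subject_id}-P{int(g) + 1:02d}",
            "view_index": view,
            "enter_time": enter,
            "leave_time": leave,
            "action": action,
            "action_time": action_time,
        })
        labels.append(prod["labels"][view - 1])
        t = leave + float(rng.exponential(cfg.gap_mean_s)) + 0.2
    events = pd.DataFrame(rows)
    return events, labels


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, sd: float, fs: float) -> np.ndarray:
    """Independent 1/f background noise per channel, scaled to sd.

    Power spectral density falls as 1/f^2 (amplitude 1/f) above 0.5 Hz,
    the steep decay typical of broadband EEG background; without it the
    omega^2-weighted spectral moments the pipeline extracts would be
    dominated by physically implausible near-Nyquist power.
    """
    white = rng.standard_normal((n_ch, n))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.maximum(freqs, 0.5)
    scale[0] = 0.0
    scale[freqs > 45.0] = 0.0  # amplifier/anti-aliasing roll-off stand-in
    out = np.fft.irfft(spectrum * scale, n=n, axis=1)
    out *= sd / out.std(axis=1, keepdims=True)
    return out


def _bandlimited_white(rng: np.random.Generator, n_ch: int, n: int, sd: float,
                       fs: float, cutoff_hz: float) -> np.ndarray:
    """Flat-spectrum measurement noise, band-limited below ``cutoff_hz``
    (anti-aliasing / amplifier roll-off stand-in)."""
    white = rng.standard_normal((n_ch, n))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[:, freqs > cutoff_hz] = 0.0
    out = np.fft.irfft(spectrum, n=n, axis=1)
    out *= sd / out.std(axis=1, keepdims=True)
    return out


def _smooth_envelope(rng: np.random.Generator, n: int, rate: float, knot_s: float = 0.5) -> np.ndarray:
    """Slow positive amplitude modulation around 1 (piecewise linear)."""
    n_knots = max(2, int(n / rate / knot_s) + 2)
    knots = 1.0 + 0.15 * rng.standard_normal(n_knots)
    env = np.interp(np.arange(n), np.linspace(0, n - 1, n_knots), knots)
    return np.clip(env, 0.2, None)


def _scalp_weights(montage: Montage, channels, center: str, width: float = 0.05) -> np.ndarray:
    """Smooth Gaussian topography centred on an electrode."""
    c = montage.position_of(center)
    pos = np.array([montage.position_of(ch) for ch in channels])
    d = np.linalg.norm(pos - c, axis=1)
    return np.exp(-(d ** 2) / (2.0 * width ** 2))


def generate_session(
    config: GeneratorConfig,
    subject_id: str,
    rng: np.random.Generator | None = None,
    montage: Montage | None = None,
) -> SessionBundle:
    """Generate one subject's continuous EEG plus view-event log."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _subject_key(subject_id)]))
    if montage is None:
        montage = Montage.standard_63()
    channels = montage.signal_channels

    events, labels = _session_structure(rng, config, subject_id)
    fs = config.sampling_rate
    total = float(events["leave_time"].iloc[-1]) + config.pad_end_s
    n = int(round(total * fs))
    n_ch = len(channels)

    data = _pink_noise(rng, n_ch, n, config.pink_sd_uv, fs)
    data += _bandlimited_white(rng, n_ch, n, config.noise_sd_uv, fs, config.noise_lowpass_hz)

    subject_offset = float(rng.normal(0.0, config.subject_sd_hz))

    # alpha source: instantaneous frequency trace with label-dependent
    # shifts in the decision window preceding each page leave
    freq = np.full(n, config.alpha_freq_hz + subject_offset)
    for row, label in zip(events.itertuples(index=False), labels):
        w0 = max(row.enter_time, row.leave_time - config.decision_window_s)
        i0, i1 = int(w0 * fs), int(row.leave_time * fs)
        freq[i0:i1] += config.effect_size_hz * LABEL_DELTAS[label]
    phase = 2.0 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    alpha = _smooth_envelope(rng, n, fs) * np.sin(phase)
    data += config.alpha_amp_uv * _scalp_weights(montage, channels, "Oz")[:, None] * alpha

    theta_phase = (
        2.0 * np.pi * (config.theta_freq_hz + 0.3 * subject_offset) * np.arange(n) / fs
        + rng.uniform(0, 2 * np.pi)
    )
    theta = _smooth_envelope(rng, n, fs) * np.sin(theta_phase)
    data += config.theta_amp_uv * _scalp_weights(montage, channels, "Fz")[:, None] * theta

    recording = Recording(
        data=data, sampling_rate=fs, channel_names=channels, start_time=0.0,
    )
    return SessionBundle(
        recording=recording,
        events=events,
        subject_id=subject_id,
        ground_truth_labels=labels,
        montage=montage,
    )


def _subject_key(subject_id: str) -> int:
    import zlib

    return zlib.crc32(subject_id.encode()) % (2 ** 31)


def generate_cohort(config: GeneratorConfig, montage: Montage | None = None) -> list[SessionBundle]:
    """One bundle per subject with sub-seeds spawned deterministically
    from ``config.seed``; subject k is reproducible independently."""
    if montage is None:
        montage = Montage.standard_63()
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    bundles = []
    for k, seq in enumerate(seqs):
        subject_id = f"S{k + 1:02d}"
        rng = np.random.default_rng(seq)
        bundles.append(generate_session(config, subject_id, rng=rng, montage=montage))
    return bundles


def simulate_views(config: GeneratorConfig, n_subjects: int, seed: int | None = None):
    """Fast path: draw only event-log skeletons (no EEG synthesis).

    Returns (events, labels) concatenated over ``n_subjects`` synthetic
    subjects; used for checks of the label mix and pages-per-subject
    statistics where signal synthesis would be waste.
    """
    cfg = replace(config, n_subjects=n_subjects)
    seqs = np.random.SeedSequence(cfg.seed if seed is None else seed).spawn(n_subjects)
    frames, all_labels = [], []
    for k, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        events, labels = _session_structure(rng, cfg, f"S{k + 1:04d}")
        frames.append(events)
        all_labels.extend(labels)
    return pd.concat(frames, ignore_index=True), all_labels
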