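"""Data model and file formats shared by all pipeline stages.

Conventions fixed repo-wide: times are seconds (float) from recording
start, sample indices are 0-based, every time window is half-open
``[start, end)``, and signal amplitudes are microvolts.

Three on-disk recording dialects are supported:

* ``matrix`` — the native interchange: a raw little-endian float32
  channels-by-samples matrix plus a JSON sidecar (lossless, used for all
  synthetic fixtures);
* ``edf`` — European Data Format (16-bit, so round-trips are exact only
  up to the quantization step);
* ``brainvision`` — read-only (``.vhdr``/``.vmrk``/``.eeg``).

View-event logs are plain CSV with the header
``subject_id,product_id,view_index,enter_time,leave_time,action,action_time``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MontageError",
    "ValidationError",
    "Montage",
    "Recording",
    "EVENT_COLUMNS",
    "ACTIONS",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "validate_events",
]


class FormatError(ValueError):
    """Unknown or malformed file format."""


class MontageError(ValueError):
    """Channel labels cannot be resolved against the montage."""


class ValidationError(ValueError):
    """An event log violates the schema invariants."""


# 63 scalp positions of the international 10/10 system as used by a
# standard 64-channel EasyCap layout (mastoid-free).  AFz carries the
# ground and FCz the recording reference, leaving 61 signal channels.
CHANNELS_63 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]

DEFAULT_GROUND = "AFz"
DEFAULT_REFERENCE = "FCz"


@dataclass(frozen=True)
class Montage:
    """Electrode layout: names, unit-sphere-ish scalp positions (meters,
    head frame), ground/reference labels and a symmetric neighbor graph
    with scalp distances."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n, 3) meters
    ground: str = DEFAULT_GROUND
    reference: str = DEFAULT_REFERENCE
    neighbor_graph: dict[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.channel_names) != len(self.positions):
            raise MontageError("positions and channel_names length mismatch")
        for ch, nbrs in self.neighbor_graph.items():
            for other, d in nbrs:
                back = dict(self.neighbor_graph.get(other, ()))
                if ch not in back:
                    raise MontageError(f"neighbor graph not symmetric at {ch}-{other}")

    @property
    def signal_channels(self) -> tuple[str, ...]:
        """Measurement channels: everything except ground and reference."""
        excluded = {self.ground, self.reference}
        return tuple(ch for ch in self.channel_names if ch not in excluded)

    def position_of(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError as exc:
            raise MontageError(f"unknown channel {name!r}") from exc
        return self.positions[idx]

    @classmethod
    def standard_63(cls) -> "Montage":
        """The default 63-electrode 10/10 montage (61 signal channels)."""
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            try:
                std_montage = mne.channels.make_standard_montage("colin27_1005")
            except ValueError:
                std_montage = mne.channels.make_standard_montage("standard_1005")
        std = std_montage.get_positions()["ch_pos"]
        missing = [ch for ch in CHANNELS_63 if ch not in std]
        if missing:  # pragma: no cover - depends only on mne's tables
            raise MontageError(f"channels missing from standard_1005: {missing}")
        positions = np.array([std[ch] for ch in CHANNELS_63])
        graph = _neighbor_graph(CHANNELS_63, positions)
        return cls(tuple(CHANNELS_63), positions, DEFAULT_GROUND, DEFAULT_REFERENCE, graph)

    def to_json(self, path) -> None:
        payload = {
            "channel_names": list(self.channel_names),
            "positions": self.positions.tolist(),
            "ground": self.ground,
            "reference": self.reference,
            "neighbor_graph": {
                ch: [[other, d] for other, d in nbrs]
                for ch, nbrs in self.neighbor_graph.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(payload["channel_names"]),
            np.asarray(payload["positions"], dtype=float),
            payload["ground"],
            payload["reference"],
            {
                ch: tuple((other, float(d)) for other, d in nbrs)
                for ch, nbrs in payload["neighbor_graph"].items()
            },
        )


def _neighbor_graph(names, positions, scale: float = 1.6):
    """Symmetric distance-threshold neighbor graph.

    Two electrodes are neighbors when their Euclidean scalp distance is
    below ``scale`` times the median nearest-neighbor distance, which on
    a regular 10/10 grid captures the first ring of electrodes.
    """
    positions = np.asarray(positions, dtype=float)
    dists = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    np.fill_diagonal(dists, np.inf)
    threshold = scale * float(np.median(dists.min(axis=1)))
    graph: dict[str, tuple[tuple[str, float], ...]] = {}
    for i, ch in enumerate(names):
        nbrs = [
            (names[j], float(dists[i, j]))
            for j in np.flatnonzero(dists[i] < threshold)
        ]
        graph[ch] = tuple(nbrs)
    return graph


@dataclass
class Recording:
    """A continuous multi-channel EEG recording in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), µV
    sampling_rate: float
    channel_names: tuple[str, ...]
    start_time: float = 0.0
    reference_state: str = "as-recorded"  # or "average"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) == 0:
            raise MontageError("empty channel list")
        if self.data.shape[0] != len(self.channel_names):
            raise MontageError(
                f"{self.data.shape[0]} data rows vs {len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_names = tuple(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def time_to_sample(self, t: float) -> int:
        """0-based sample index of time ``t`` (floor convention)."""
        return int(math.floor((t - self.start_time) * self.sampling_rate + 1e-9))

    def sample_to_time(self, idx: int) -> float:
        return self.start_time + idx / self.sampling_rate

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Recording readers/writers


def write_recording(recording: Recording, path, format: str = "matrix") -> Path:
    """Write a recording; returns the path of the primary file written.

    ``matrix``: ``<path>.json`` sidecar + ``<path>.dat`` float32 matrix.
    ``edf``: 16-bit EDF (``<path>.edf`` if no suffix given).
    """
    path = Path(path)
    if format == "matrix":
        return _write_matrix(recording, path)
    if format == "edf":
        return _write_edf(recording, path if path.suffix else path.with_suffix(".edf"))
    raise FormatError(f"unknown format {format!r}")


def read_recording(path, format: str | None = None, montage: Montage | None = None) -> Recording:
    """Read a recording from ``edf``, ``brainvision`` or ``matrix`` files.

    When ``format`` is None it is inferred from the file suffix. If a
    montage is given, channel labels are checked against it.
    """
    path = Path(path)
    if format is None:
        format = {
            ".edf": "edf",
            ".vhdr": "brainvision",
            ".json": "matrix",
            ".dat": "matrix",
        }.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from {path.name!r}")
    if format == "matrix":
        rec = _read_matrix(path)
    elif format == "edf":
        rec = _read_mne(path, "edf")
    elif format == "brainvision":
        rec = _read_mne(path, "brainvision")
    else:
        raise FormatError(f"unknown format {format!r}")
    if montage is not None:
        known = set(montage.channel_names)
        unknown = [ch for ch in rec.channel_names if ch not in known]
        if unknown:
            raise MontageError(f"channels not in montage: {unknown}")
    return rec


def _write_matrix(recording: Recording, path: Path) -> Path:
    base = path.with_suffix("") if path.suffix in {".json", ".dat"} else path
    datafile = base.with_suffix(".dat")
    sidecar = base.with_suffix(".json")
    recording.data.astype("<f4").tofile(datafile)
    sidecar.write_text(json.dumps({
        "format": "shopeeg-matrix-v1",
        "dtype": "<f4",
        "units": "uV",
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "sampling_rate": recording.sampling_rate,
        "channel_names": list(recording.channel_names),
        "start_time": recording.start_time,
        "reference_state": recording.reference_state,
    }, indent=1))
    return sidecar


def _read_matrix(path: Path) -> Recording:
    base = path.with_suffix("")
    sidecar = base.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("format") != "shopeeg-matrix-v1":
        raise FormatError(f"not a shopeeg matrix sidecar: {sidecar}")
    data = np.fromfile(base.with_suffix(".dat"), dtype=meta["dtype"])
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return Recording(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channel_names=tuple(meta["channel_names"]),
        start_time=float(meta.get("start_time", 0.0)),
        reference_state=meta.get("reference_state", "as-recorded"),
    )


def _read_mne(path: Path, kind: str) -> Recording:
    import mne

    if kind == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        data=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        start_time=0.0,
    )


def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(recording: Recording, path: Path) -> Path:
    """Minimal EDF writer: one data record holding the whole signal,
    16-bit samples with per-channel symmetric physical scaling."""
    n_ch, n_samp = recording.data.shape
    if n_samp < 1:
        raise FormatError("cannot write empty recording")
    record_dur = n_samp / recording.sampling_rate
    header = bytearray()
    header += _ascii_field(0, 8)                       # version
    header += _ascii_field("shopeeg", 80)              # patient id
    header += _ascii_field("shopeeg synthetic", 80)    # recording id
    header += _ascii_field("01.01.20", 8)              # start date
    header += _ascii_field("00.00.00", 8)              # start time
    header += _ascii_field(256 + 256 * n_ch, 8)        # header bytes
    header += _ascii_field("", 44)                     # reserved
    header += _ascii_field(1, 8)                       # number of records
    header += _ascii_field(f"{record_dur:.6f}"[:8], 8)  # record duration (s)
    header += _ascii_field(n_ch, 4)                    # number of signals

    pmaxs = []
    for ch in range(n_ch):
        amax = float(np.max(np.abs(recording.data[ch])))
        pmaxs.append(amax if amax > 0 else 1.0)

    for ch in range(n_ch):
        header += _ascii_field(recording.channel_names[ch], 16)
    for _ in range(n_ch):
        header += _ascii_field("AgAgCl electrode", 80)
    for _ in range(n_ch):
        header += _ascii_field("uV", 8)
    for ch in range(n_ch):
        header += _ascii_field(f"{-pmaxs[ch]:.6g}"[:8], 8)   # physical min
    for ch in range(n_ch):
        header += _ascii_field(f"{pmaxs[ch]:.6g}"[:8], 8)    # physical max
    for _ in range(n_ch):
        header += _ascii_field(-32767, 8)                    # digital min
    for _ in range(n_ch):
        header += _ascii_field(32767, 8)                     # digital max
    for _ in range(n_ch):
        header += _ascii_field("", 80)                       # prefilter
    for _ in range(n_ch):
        header += _ascii_field(n_samp, 8)                    # samples/record
    for _ in range(n_ch):
        header += _ascii_field("", 32)                       # reserved

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for ch in range(n_ch):
            # use the *parsed* physical max (8-char ASCII) so that the
            # round-trip scaling matches what a reader reconstructs
            pmax = float(f"{pmaxs[ch]:.6g}"[:8])
            digital = np.clip(
                np.round(recording.data[ch] / pmax * 32767), -32767, 32767
            ).astype("<i2")
            fh.write(digital.tobytes())
    return path


def edf_quantization_step(recording: Recording) -> np.ndarray:
    """Per-channel worst-case amplitude error of a 16-bit EDF round trip."""
    amax = np.max(np.abs(recording.data), axis=1)
    amax = np.where(amax > 0, amax, 1.0)
    return amax / 32767.0


# ---------------------------------------------------------------------------
# View-event logs

EVENT_COLUMNS = [
    "subject_id", "product_id", "view_index",
    "enter_time", "leave_time", "action", "action_time",
]
ACTIONS = ("none", "cart", "buy")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate a view-event log against the schema invariants.

    Raises :class:`ValidationError` naming the offending 0-based row
    numbers. Returns a copy sorted by (subject, enter_time) with
    normalized dtypes.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    df = events.loc[:, EVENT_COLUMNS].copy()
    df["view_index"] = df["view_index"].astype(int)
    df["enter_time"] = df["enter_time"].astype(float)
    df["leave_time"] = df["leave_time"].astype(float)
    df["action"] = df["action"].fillna("none").astype(str)
    df["action_time"] = pd.to_numeric(df["action_time"], errors="coerce")

    problems = []
    bad_action = df.index[~df["action"].isin(ACTIONS)]
    for row in bad_action:
        problems.append(f"row {row}: unknown action {df.at[row, 'action']!r}")
    bad_order = df.index[df["leave_time"] <= df["enter_time"]]
    for row in bad_order:
        problems.append(f"row {row}: leave_time <= enter_time")
    for subject, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("enter_time")
        overlap = grp.index[1:][
            grp["enter_time"].to_numpy()[1:] < grp["leave_time"].to_numpy()[:-1]
        ]
        for row in overlap:
            problems.append(f"row {row}: overlapping view interval (subject {subject})")
        for (subj, prod), pgrp in grp.groupby(["subject_id", "product_id"], sort=False):
            buys = pgrp[pgrp["action"] == "buy"]
            if len(buys) > 1:
                problems.append(
                    f"rows {sorted(buys.index.tolist())}: multiple buys for product {prod}"
                )
            carts = pgrp[pgrp["action"] == "cart"]
            if len(buys) == 1 and len(carts) > 0:
                if carts["view_index"].max() >= buys["view_index"].iloc[0]:
                    problems.append(
                        f"row {int(carts.index[-1])}: cart does not precede buy for product {prod}"
                    )
    if problems:
        raise ValidationError("; ".join(problems))
    out = df.sort_values(["subject_id", "enter_time"], kind="stable").reset_index(drop=True)
    return out


def read_events(path) -> pd.DataFrame:
    """Read and validate a view-event CSV."""
    df = pd.read_csv(path)
    return validate_events(df)


def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events).to_csv(path, index=False)
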