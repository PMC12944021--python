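"""Signal I/O: labelled-recording files, windowing, resampling and channel selection.

Recordings are dual-accelerometer time series — three axes from a lower-back
sensor and three from a right-thigh sensor, in units of g — with one integer
activity label per frame.  The on-disk format is a plain CSV with a header row
``timestamp,back_x,back_y,back_z,thigh_x,thigh_y,thigh_z,label``, '.' decimal,
one row per frame, plus an optional sidecar label map.  Three-channel files
(single sensor site) are accepted when the dialect declares them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import firwin, resample_poly

#: canonical channel order for the dual-sensor configuration
CANONICAL_CHANNELS: tuple[str, ...] = (
    "back_x", "back_y", "back_z", "thigh_x", "thigh_y", "thigh_z",
)

SITE_CHANNELS: dict[str, tuple[str, ...]] = {
    "lower_back": ("back_x", "back_y", "back_z"),
    "thigh": ("thigh_x", "thigh_y", "thigh_z"),
    "both": CANONICAL_CHANNELS,
}

DEFAULT_RATE_HZ = 50.0


class FormatError(ValueError):
    """A file does not match the declared CSV dialect."""


@dataclass(frozen=True)
class SignalWindow:
    """A channels-by-time acceleration matrix.

    ``values`` has shape (n, T): one row per channel (units g), one column per
    frame.  ``channel_names`` gives the semantics of each row in canonical
    order; ``rate`` is the sampling rate in Hz.
    """

    values: np.ndarray
    channel_names: tuple[str, ...] = CANONICAL_CHANNELS
    rate: float = DEFAULT_RATE_HZ

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("signal values must be a 2-D (channels x time) matrix")
        if values.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{values.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if values.shape[1] < 1:
            raise ValueError("a signal window must contain at least one frame")
        if not np.isfinite(values).all():
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate


@dataclass(frozen=True)
class LabelSequence:
    """Per-frame integer activity labels with an id -> name map."""

    labels: np.ndarray
    label_map: dict[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        unknown = set(np.unique(labels)) - set(self.label_map)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from label_map")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class CsvDialect:
    """Descriptor for the recording CSV layout.

    ``channel_columns`` lists the acceleration columns expected in the file
    (default: the canonical six).  An adapter for other public column namings
    can be expressed by instantiating a dialect with renamed columns mapped
    onto canonical names via ``column_aliases``.
    """

    channel_columns: tuple[str, ...] = CANONICAL_CHANNELS
    timestamp_column: str = "timestamp"
    label_column: str = "label"
    column_aliases: dict[str, str] = field(default_factory=dict)
    rate: float = DEFAULT_RATE_HZ
    on_unknown_label: str = "error"  # or "drop"


def _check_aligned(signal: SignalWindow, labels: LabelSequence) -> None:
    if signal.n_frames != len(labels):
        raise ValueError(
            f"signal has {signal.n_frames} frames but {len(labels)} labels"
        )


def write_recording(signal: SignalWindow, labels: LabelSequence, path: str | Path) -> Path:
    """Write one row per frame in the HARTH-style CSV dialect.

    A sidecar ``<path>.labels`` table (``id,name`` per line) stores the label
    map so a round-trip restores activity names.
    """
    _check_aligned(signal, labels)
    path = Path(path)
    frame = pd.DataFrame(
        {"timestamp": np.arange(signal.n_frames) / signal.rate}
        | {name: signal.values[i] for i, name in enumerate(signal.channel_names)}
        | {"label": labels.labels}
    )
    frame.to_csv(path, index=False, float_format="%.9f")
    sidecar = path.with_suffix(path.suffix + ".labels")
    with open(sidecar, "w") as fh:
        for lid in sorted(labels.label_map):
            fh.write(f"{lid},{labels.label_map[lid]}\n")
    return path


def read_recording(
    path: str | Path,
    dialect: CsvDialect | None = None,
    label_map: dict[int, str] | None = None,
) -> tuple[SignalWindow, LabelSequence]:
    """Load a labelled recording, normalising channel order to canonical.

    The label map is taken from (in order of precedence) the ``label_map``
    argument, the sidecar file written by :func:`write_recording`, or the set
    of ids present in the file.  Rows whose label is outside the map are
    rejected (default) or dropped, per ``dialect.on_unknown_label``.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    if table.empty:
        raise ValueError(f"{path} contains no data rows")
    if dialect.column_aliases:
        table = table.rename(columns=dialect.column_aliases)
    required = [dialect.timestamp_column, *dialect.channel_columns, dialect.label_column]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path} is missing required columns {missing}")
    ts = table[dialect.timestamp_column].to_numpy(dtype=float)
    if np.any(np.diff(ts) < 0):
        warnings.warn(f"{path}: non-monotone timestamps; applying stable sort")
        table = table.iloc[np.argsort(ts, kind="stable")].reset_index(drop=True)

    if label_map is None:
        sidecar = path.with_suffix(path.suffix + ".labels")
        if sidecar.exists():
            label_map = {}
            for line in sidecar.read_text().splitlines():
                lid, name = line.split(",", 1)
                label_map[int(lid)] = name
        else:
            label_map = {int(v): str(v) for v in np.unique(table[dialect.label_column])}

    raw_labels = table[dialect.label_column].to_numpy(dtype=np.int64)
    unknown_mask = ~np.isin(raw_labels, list(label_map))
    if unknown_mask.any():
        if dialect.on_unknown_label == "drop":
            table = table.loc[~unknown_mask].reset_index(drop=True)
            raw_labels = raw_labels[~unknown_mask]
        else:
            raise ValueError(
                f"{path}: labels {sorted(set(raw_labels[unknown_mask]))} not in label map"
            )
    if table.empty:
        raise ValueError(f"{path}: no rows left after label filtering")

    # normalise channel ordering to canonical order (for the subset present)
    ordered = tuple(c for c in CANONICAL_CHANNELS if c in dialect.channel_columns)
    if set(ordered) != set(dialect.channel_columns):
        ordered = tuple(dialect.channel_columns)  # non-canonical names: keep as declared
    values = table[list(ordered)].to_numpy(dtype=float).T
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: missing or non-finite acceleration values")
    signal = SignalWindow(values=values, channel_names=ordered, rate=dialect.rate)
    labels = LabelSequence(labels=raw_labels, label_map=dict(label_map))
    return signal, labels


def window_recording(
    signal: SignalWindow, labels: LabelSequence, window_len: int
) -> list[tuple[SignalWindow, LabelSequence]]:
    """Cut consecutive non-overlapping windows of ``window_len`` frames.

    The final shorter remainder window is kept — the sequence labellers accept
    variable-length input, and dropping it would lose frames.  Windows are
    half-open [start, end) on 0-indexed frames, so concatenating the outputs
    reconstructs the input exactly.
    """
    _check_aligned(signal, labels)
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    out: list[tuple[SignalWindow, LabelSequence]] = []
    for start in range(0, signal.n_frames, window_len):
        end = min(start + window_len, signal.n_frames)
        out.append(
            (
                replace(signal, values=signal.values[:, start:end]),
                replace(labels, labels=labels.labels[start:end]),
            )
        )
    return out


def downsample(
    signal: SignalWindow,
    labels: LabelSequence,
    target_rate: float,
    method: str = "polyphase",
) -> tuple[SignalWindow, LabelSequence]:
    """Resample to a lower rate; labels follow by nearest-source-frame mapping.

    The default is rational-factor polyphase resampling with an anti-alias
    low-pass, which protects gait harmonics from aliasing.  ``method="decimate"``
    takes every (source/target)-th frame without filtering, for sensitivity
    checks; it requires an integer factor.  Output length is
    round(T * target / source); each output frame's label is the label of its
    nearest source frame, so transitions move by at most one output frame.
    """
    _check_aligned(signal, labels)
    if not 0 < target_rate < signal.rate:
        raise ValueError(
            f"target rate must be in (0, {signal.rate}); got {target_rate}"
        )
    frac = Fraction(target_rate / signal.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    n_out = int(round(signal.n_frames * target_rate / signal.rate))
    if n_out < 1:
        raise ValueError("downsampling would leave fewer than one frame")
    if method == "polyphase":
        # sharp Kaiser-windowed FIR (64 taps per phase): high stop-band
        # attenuation so cascaded and direct rational resampling agree closely
        ntaps = 2 * 64 * max(up, down) + 1
        h = firwin(ntaps, 1.0 / down, window=("kaiser", 14.0))
        values = resample_poly(signal.values, up, down, axis=1, window=h * up)
        values = values[:, :n_out]
        if values.shape[1] < n_out:  # short inputs: pad with edge value
            pad = np.repeat(values[:, -1:], n_out - values.shape[1], axis=1)
            values = np.concatenate([values, pad], axis=1)
    elif method == "decimate":
        if down % up:
            raise ValueError("decimate requires an integer downsampling factor")
        values = signal.values[:, :: down // up][:, :n_out]
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    src_idx = np.clip(
        np.round(np.arange(n_out) * signal.rate / target_rate).astype(int),
        0,
        signal.n_frames - 1,
    )
    return (
        replace(signal, values=values, rate=float(target_rate)),
        replace(labels, labels=labels.labels[src_idx]),
    )


def select_channels(signal: SignalWindow, site: str) -> SignalWindow:
    """Keep the channels of one sensor site (or both), preserving order."""
    if site not in SITE_CHANNELS:
        raise ValueError(f"unknown site {site!r}; expected one of {sorted(SITE_CHANNELS)}")
    wanted = SITE_CHANNELS[site]
    missing = [c for c in wanted if c not in signal.channel_names]
    if missing:
        raise ValueError(f"channels {missing} absent from signal")
    idx = [signal.channel_names.index(c) for c in wanted]
    return replace(signal, values=signal.values[idx], channel_names=wanted)


def concatenate_windows(
    windows: list[tuple[SignalWindow, LabelSequence]]
) -> tuple[SignalWindow, LabelSequence]:
    """Invert :func:`window_recording` (used by tests and evaluation)."""
    if not windows:
        raise ValueError("no windows to concatenate")
    sig0, lab0 = windows[0]
    values = np.concatenate([w.values for w, _ in windows], axis=1)
    labels = np.concatenate([l.labels for _, l in windows])
    return replace(sig0, values=values), replace(lab0, labels=labels)
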