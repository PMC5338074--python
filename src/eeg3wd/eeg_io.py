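"""EEG data model, CSV serialization, and a periodogram utility.

The on-disk format is a plain CSV dialect: ``#``-prefixed ``key=value``
metadata lines (``fs``, ``subject_id``, ``label``), then a header row
naming the channels, then one time sample per row with channels as
columns. Values are written with 17 significant digits so a
write-then-read round trip is lossless at float64 precision.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

#: Canonical 10-electrode layout: frontal, central, temporal, parietal,
#: occipital pairs. Recordings flagged as canonical must use exactly this
#: order.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "F3", "F4", "C3", "C4", "T3", "T4", "P3", "P4", "O1", "O2",
)

LABEL_NORMAL = 0
LABEL_PD = 1

_LABEL_TOKENS = {
    "0": LABEL_NORMAL,
    "normal": LABEL_NORMAL,
    "1": LABEL_PD,
    "pd": LABEL_PD,
    "unknown": None,
}


class RecordingFormatError(ValueError):
    """Raised for malformed, ragged, or metadata-incomplete recording files."""


@dataclass
class EEGRecording:
    """One subject's multichannel EEG signal.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    label : int or None
        Class label: 0 = normal, 1 = PD, ``None`` = unknown.
    fs : float
        Sampling rate in Hz, strictly positive.
    channels : tuple of str
        Ordered channel names, one per data row.
    data : ndarray, shape (n_channels, n_samples)
        Potentials, one row per channel.
    canonical : bool
        If True, ``channels`` must equal :data:`CANONICAL_CHANNELS`
        exactly (names and order).
    """

    subject_id: str
    label: int | None
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray
    canonical: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=float)
        if not self.channels:
            raise ValueError("recording needs at least one channel")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows for "
                f"{len(self.channels)} channel names"
            )
        if self.data.shape[1] < 1:
            raise ValueError("each channel needs at least one sample")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in (LABEL_NORMAL, LABEL_PD, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")
        if self.canonical and self.channels != CANONICAL_CHANNELS:
            raise ValueError(
                "canonical layout requires channels exactly "
                f"{list(CANONICAL_CHANNELS)}, got {list(self.channels)}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass
class PowerSpectrum:
    """One-sided power spectrum on a uniform frequency grid.

    ``power`` sums to the mean square of the originating signal
    (Parseval), so it is a power *distribution* over [0, fs/2].
    """

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


def _label_from_token(token: str) -> int | None:
    try:
        return _LABEL_TOKENS[token.strip().lower()]
    except KeyError:
        raise RecordingFormatError(
            f"unknown label token {token!r}; expected one of "
            f"{sorted(_LABEL_TOKENS)}"
        ) from None


def _label_to_token(label: int | None) -> str:
    return {LABEL_NORMAL: "normal", LABEL_PD: "pd", None: "unknown"}[label]


def write_recording_csv(rec: EEGRecording, path) -> None:
    """Write a recording in the package CSV dialect.

    Metadata goes into ``#`` comment lines; the numeric block is one
    sample per row, channels as columns, 17 significant digits.
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# label={_label_to_token(rec.label)}\n")
        fh.write(",".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=",")


def read_recording_csv(path, canonical: bool = False) -> EEGRecording:
    """Read a recording written by :func:`write_recording_csv`.

    Raises
    ------
    RecordingFormatError
        If ``fs`` metadata is missing (there is no default sampling
        rate), a numeric cell is malformed (the error names the data row
        and column), rows are ragged, or the label token is unknown.
    """
    meta: dict[str, str] = {}
    with open(path, newline="") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                pos = fh.tell()
                continue
            fh.seek(pos)
            break
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordingFormatError(f"{path}: no header row") from None
        channels = tuple(name.strip() for name in header)
        columns: list[list[float]] = [[] for _ in channels]
        for i, row in enumerate(reader):
            if not row:
                continue
            if len(row) != len(channels):
                raise RecordingFormatError(
                    f"{path}: ragged row {i + 1}: expected "
                    f"{len(channels)} cells, got {len(row)}"
                )
            for j, cell in enumerate(row):
                try:
                    columns[j].append(float(cell))
                except ValueError:
                    raise RecordingFormatError(
                        f"{path}: malformed numeric cell {cell!r} at data "
                        f"row {i + 1}, column {channels[j]!r}"
                    ) from None
    if not columns or not columns[0]:
        raise RecordingFormatError(f"{path}: no data rows")
    if "fs" not in meta:
        raise RecordingFormatError(
            f"{path}: missing required '# fs=<Hz>' metadata line"
        )
    try:
        fs = float(meta["fs"])
    except ValueError:
        raise RecordingFormatError(
            f"{path}: malformed fs metadata {meta['fs']!r}"
        ) from None
    label = _label_from_token(meta.get("label", "unknown"))
    return EEGRecording(
        subject_id=meta.get("subject_id", ""),
        label=label,
        fs=fs,
        channels=channels,
        data=np.array(columns, dtype=float),
        canonical=canonical,
    )


def recording_to_csv_text(rec: EEGRecording) -> str:
    """Render a recording to CSV text in memory (used by the CLI)."""
    buf = io.StringIO()
    buf.write(f"# subject_id={rec.subject_id}\n")
    buf.write(f"# fs={rec.fs!r}\n")
    buf.write(f"# label={_label_to_token(rec.label)}\n")
    buf.write(",".join(rec.channels) + "\n")
    np.savetxt(buf, rec.data.T, fmt="%.17g", delimiter=",")
    return buf.getvalue()


def periodogram(x, fs: float) -> PowerSpectrum:
    """Plain FFT periodogram, normalized so total power equals mean square.

    No windowing or segment averaging is applied; the spectrum is a
    sanity-check utility, not an estimator tuned for variance. The
    one-sided convention doubles all interior bins, so
    ``sum(power) == mean(x**2)`` exactly (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("periodogram needs a 1-D signal of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if not (fs > 0):
        raise ValueError("fs must be positive")
    n = x.size
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    # fold negative frequencies into the interior bins
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return PowerSpectrum(freqs=freqs, power=power)
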