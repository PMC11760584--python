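"""Reading and writing pen-tablet recordings in SVC-style text format.

An SVC file is a plain-text table with one line per sample. Each sample
carries the seven channels a digitising tablet reports: x/y coordinates
(integer tablet units), a timestamp, the button status (0 = pen in air,
1 = pen on surface), the azimuth and tilt angles of the pen barrel in
degrees, and the axial pressure in device units (Wacom-class tablets use
8192 levels). Published SVC dialects differ in column order and in whether
the first line carries the sample count, so both are configurable through
:class:`SvcDialect`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "SvcDialect",
    "PAHAW_DIALECT",
    "HandwritingSample",
    "SvcFormatError",
    "read_svc",
    "write_svc",
]

#: canonical channel order used internally
CHANNEL_NAMES = ("x", "y", "t", "button", "azimuth", "tilt", "pressure")

MAX_PRESSURE = 8192  # device levels; valid values are 0 .. 8191


class SvcFormatError(ValueError):
    """Raised when an SVC file violates its declared dialect."""


@dataclasses.dataclass(frozen=True)
class SvcDialect:
    """On-disk layout of an SVC file.

    Parameters
    ----------
    columns:
        Permutation of the seven channel names giving the column order in
        the file. Must cover every channel exactly once.
    header:
        Whether the first line holds the number of body lines.
    tick_duration:
        Duration of one timestamp unit in seconds, if known. When ``None``
        timestamps are rescaled to seconds from the recording's declared
        sampling frequency.
    """

    columns: Sequence[str] = CHANNEL_NAMES
    header: bool = True
    tick_duration: float | None = None

    def __post_init__(self) -> None:
        if sorted(self.columns) != sorted(CHANNEL_NAMES):
            raise ValueError(
                f"dialect columns must be a permutation of {CHANNEL_NAMES}, "
                f"got {tuple(self.columns)}"
            )


#: PaHaW-style layout: optional count header then "x y t button azimuth tilt pressure"
PAHAW_DIALECT = SvcDialect()

DIALECTS = {"pahaw": PAHAW_DIALECT, "headerless": SvcDialect(header=False)}


@dataclasses.dataclass
class HandwritingSample:
    """One subject-task recording: seven equal-length channel arrays.

    ``x``, ``y``, ``button`` and ``pressure`` are integer-valued; ``azimuth``
    and ``tilt`` are degrees; ``t`` is the raw timestamp column (device
    ticks). Use :meth:`time_seconds` for a physical time axis.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    button: np.ndarray
    azimuth: np.ndarray
    tilt: np.ndarray
    pressure: np.ndarray
    subject_id: str = ""
    task_id: str = ""
    label: str | None = None
    fs: float = 200.0
    tick_duration: float | None = None

    def __post_init__(self) -> None:
        for name in CHANNEL_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.x)
        if n < 1:
            raise ValueError("a recording needs at least one sample")
        for name in CHANNEL_NAMES:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from x")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if not np.isin(self.button, (0.0, 1.0)).all():
            raise ValueError("button status must be 0 (in air) or 1 (on surface)")
        if np.any(self.pressure < 0):
            raise ValueError("pressure must be non-negative")

    def __len__(self) -> int:
        return len(self.x)

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def time_seconds(self) -> np.ndarray:
        """Time axis in seconds, starting at 0.

        If the tick duration is known timestamps are scaled directly;
        otherwise the raw timestamps are rescaled so that their median step
        equals the nominal sampling period 1/fs.
        """
        t = self.t - self.t[0]
        if self.tick_duration is not None:
            return t * self.tick_duration
        if len(t) < 2:
            return t
        steps = np.diff(t)
        med = np.median(steps[steps > 0]) if np.any(steps > 0) else 1.0
        return t * (1.0 / self.fs) / med

    def equals(self, other: "HandwritingSample") -> bool:
        return all(
            np.array_equal(self.channel(c), other.channel(c)) for c in CHANNEL_NAMES
        )


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_svc(
    path: str | Path,
    dialect: SvcDialect = PAHAW_DIALECT,
    *,
    subject_id: str = "",
    task_id: str = "",
    label: str | None = None,
    fs: float = 200.0,
) -> HandwritingSample:
    """Parse an SVC file into a :class:`HandwritingSample`.

    Raises :class:`SvcFormatError` on a header/body count mismatch or a
    non-numeric token (the error message carries the offending line number).
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    declared = None
    body_start = 0
    if dialect.header:
        if not lines:
            raise SvcFormatError(f"{path}: empty file, expected a count header")
        try:
            declared = int(lines[0].split()[0])
        except ValueError as exc:
            raise SvcFormatError(f"{path}:1: header is not an integer count") from exc
        body_start = 1
    body = lines[body_start:]
    if declared is not None and len(body) != declared:
        raise SvcFormatError(
            f"{path}: header declares {declared} samples but file has {len(body)}"
        )
    cols: dict[str, list[float]] = {name: [] for name in CHANNEL_NAMES}
    for lineno, line in enumerate(body, start=body_start + 1):
        tokens = line.split()
        if len(tokens) != 7:
            raise SvcFormatError(
                f"{path}:{lineno}: expected 7 fields, found {len(tokens)}"
            )
        for name, tok in zip(dialect.columns, tokens):
            try:
                cols[name].append(float(tok))
            except ValueError as exc:
                raise SvcFormatError(
                    f"{path}:{lineno}: non-numeric token {tok!r} in column {name!r}"
                ) from exc
    return HandwritingSample(
        subject_id=subject_id or path.stem,
        task_id=task_id,
        label=label,
        fs=fs,
        tick_duration=dialect.tick_duration,
        **{name: np.array(vals) for name, vals in cols.items()},
    )


def write_svc(
    sample: HandwritingSample,
    path: str | Path,
    dialect: SvcDialect = PAHAW_DIALECT,
) -> Path:
    """Write a sample to disk; the file parses back to an equal sample."""
    sample.validate()
    path = Path(path)
    out: list[str] = []
    if dialect.header:
        out.append(str(len(sample)))
    arrays = [sample.channel(name) for name in dialect.columns]
    for i in range(len(sample)):
        out.append(" ".join(_format_value(a[i]) for a in arrays))
    path.write_text("\n".join(out) + "\n")
    return path
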