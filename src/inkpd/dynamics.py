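"""Derivation of the 19 dynamic channels from a raw pen-tablet recording.

Four families of per-sample signals are derived from the seven raw tablet
channels:

* kinematic (14): the x and y traces, the Euclidean displacement between
  consecutive sampling points, its first three time-derivatives (velocity,
  acceleration, jerk), and the horizontal (x-based) and vertical (y-based)
  component chains of all four;
* pressure (2): pen pressure and its first time-derivative;
* angle (2): tilt and azimuth, kept in the degrees the tablet reports;
* moment (1): a torque-like channel ``M_i = P_i cos(theta_i) r_i sin(phi_i)``
  where ``P`` is pressure, ``theta`` tilt, ``phi`` azimuth and ``r_i`` the
  distance from sampling point i to the centroid of the whole trace. The
  in-plane component of the pen force is ``P cos(theta)``; taking the
  handwriting centroid as the centre of rotation, ``r sin(phi)`` is the
  lever arm, so ``M`` couples kinematic, pressure and angle information in
  a single signal.

Angles are converted to radians only inside the moment formula; the Tilt
and Azimuth feature channels keep their recorded units (a monotone unit
change cannot alter rank statistics, but trigonometry needs radians).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io import HandwritingSample

__all__ = [
    "ChannelConfig",
    "ChannelSet",
    "FAMILY_SIZES",
    "compute_displacement",
    "compute_kinematics",
    "compute_pressure_angle",
    "compute_moment",
    "build_channelset",
]

FAMILY_SIZES = {"kinematic": 14, "pressure": 2, "angle": 2, "moment": 1}

KINEMATIC_NAMES = (
    "X", "Y",
    "Displacement", "Velocity", "Acceleration", "Jerk",
    "Displacement_h", "Velocity_h", "Acceleration_h", "Jerk_h",
    "Displacement_v", "Velocity_v", "Acceleration_v", "Jerk_v",
)


@dataclasses.dataclass(frozen=True)
class ChannelConfig:
    """Switches for channel derivation.

    include_moment:
        The moment-channel ablation toggle; with ``False`` the set has 18
        channels and an empty moment family.
    on_surface_only:
        Restrict every channel to samples with button = 1. Default keeps
        in-air samples (pressure is 0 in air by device behaviour).
    use_timestamps:
        Divide derivatives by actual timestamp differences in seconds.
        With ``False``, unit-step differences are used instead.
    """

    include_moment: bool = True
    on_surface_only: bool = False
    use_timestamps: bool = True


@dataclasses.dataclass
class ChannelSet:
    """Named, family-tagged signals of common length for one recording."""

    signals: dict[str, np.ndarray]
    families: dict[str, str]
    fs: float

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        for name, sig in self.signals.items():
            if not np.all(np.isfinite(sig)):
                raise ValueError(f"channel {name!r} contains non-finite values")

    def __len__(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def names(self) -> list[str]:
        return list(self.signals)

    def family(self, tag: str) -> list[str]:
        return [n for n, f in self.families.items() if f == tag]


def _dt(sample: HandwritingSample, n: int, cfg: ChannelConfig) -> np.ndarray:
    """Per-step time increments (length n-1), guarded against stutter.

    Real tablet logs occasionally repeat a timestamp; a zero or negative
    step is replaced by the nominal sampling period so derivative chains
    never divide by zero.
    """
    if not cfg.use_timestamps:
        return np.ones(max(n - 1, 0))
    t = sample.time_seconds()
    dt = np.diff(t[:n]) if n > 1 else np.zeros(0)
    bad = dt <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-positive timestamp step(s); "
            "substituting the nominal sampling period",
            stacklevel=3,
        )
        dt = np.where(bad, 1.0 / sample.fs, dt)
    return dt


def _derivative(signal: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """First time-derivative, length-preserved by prepending a 0."""
    if len(signal) < 2:
        return np.zeros_like(signal)
    return np.concatenate(([0.0], np.diff(signal) / dt))


def compute_displacement(sample: HandwritingSample) -> np.ndarray:
    """Euclidean distance between consecutive sampling points; 0 at i=1."""
    dx = np.diff(sample.x)
    dy = np.diff(sample.y)
    return np.concatenate(([0.0], np.hypot(dx, dy)))


def _chain(disp: np.ndarray, dt: np.ndarray) -> tuple[np.ndarray, ...]:
    """Velocity, acceleration, jerk from a per-step displacement signal.

    Velocity is displacement per unit time (d_i / dt_i, i.e. the rate of
    position change over each step, so uniform motion gives a constant
    velocity); acceleration and jerk are successive time-derivatives.
    """
    if len(disp) < 2:
        z = np.zeros_like(disp)
        return z, z.copy(), z.copy()
    v = np.concatenate(([0.0], disp[1:] / dt))
    a = _derivative(v, dt)
    j = _derivative(a, dt)
    return v, a, j


def compute_kinematics(
    sample: HandwritingSample, config: ChannelConfig = ChannelConfig()
) -> dict[str, np.ndarray]:
    """The 14 kinematic channels (positions, displacement chains)."""
    n = len(sample)
    dt = _dt(sample, n, config)
    disp = compute_displacement(sample)
    disp_h = np.concatenate(([0.0], np.diff(sample.x)))
    disp_v = np.concatenate(([0.0], np.diff(sample.y)))
    vel, acc, jerk = _chain(disp, dt)
    vel_h, acc_h, jerk_h = _chain(disp_h, dt)
    vel_v, acc_v, jerk_v = _chain(disp_v, dt)
    return {
        "X": sample.x.copy(),
        "Y": sample.y.copy(),
        "Displacement": disp,
        "Velocity": vel,
        "Acceleration": acc,
        "Jerk": jerk,
        "Displacement_h": disp_h,
        "Velocity_h": vel_h,
        "Acceleration_h": acc_h,
        "Jerk_h": jerk_h,
        "Displacement_v": disp_v,
        "Velocity_v": vel_v,
        "Acceleration_v": acc_v,
        "Jerk_v": jerk_v,
    }


def compute_pressure_angle(
    sample: HandwritingSample, config: ChannelConfig = ChannelConfig()
) -> dict[str, np.ndarray]:
    """Pressure, its first time-derivative, and the two pen angles."""
    dt = _dt(sample, len(sample), config)
    return {
        "Pressure": sample.pressure.copy(),
        "Pressure_d": _derivative(sample.pressure, dt),
        "Tilt": sample.tilt.copy(),
        "Azimuth": sample.azimuth.copy(),
    }


def compute_moment(sample: HandwritingSample) -> np.ndarray:
    """Moment channel M_i = P_i cos(theta_i) r_i sin(phi_i).

    r_i is the distance from point i to the centroid (mean x, mean y) of
    all sampling points of the recording; tilt theta and azimuth phi are
    converted from degrees to radians for the trigonometry. A point at the
    centroid has r = 0 and hence M = 0.
    """
    r = np.hypot(sample.x - sample.x.mean(), sample.y - sample.y.mean())
    theta = np.deg2rad(sample.tilt)
    phi = np.deg2rad(sample.azimuth)
    return sample.pressure * np.cos(theta) * r * np.sin(phi)


def build_channelset(
    sample: HandwritingSample, config: ChannelConfig = ChannelConfig()
) -> ChannelSet:
    """Assemble the full family-tagged channel set for one recording."""
    work = sample
    if config.on_surface_only:
        mask = sample.button == 1
        if not mask.any():
            raise ValueError("no on-surface samples in recording")
        work = HandwritingSample(
            subject_id=sample.subject_id,
            task_id=sample.task_id,
            label=sample.label,
            fs=sample.fs,
            tick_duration=sample.tick_duration,
            **{c: sample.channel(c)[mask] for c in
               ("x", "y", "t", "button", "azimuth", "tilt", "pressure")},
        )
    signals = compute_kinematics(work, config)
    families = {name: "kinematic" for name in signals}
    pa = compute_pressure_angle(work, config)
    signals.update(pa)
    families.update({"Pressure": "pressure", "Pressure_d": "pressure",
                     "Tilt": "angle", "Azimuth": "angle"})
    if config.include_moment:
        signals["Moment"] = compute_moment(work)
        families["Moment"] = "moment"
    return ChannelSet(signals=signals, families=families, fs=work.fs)
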