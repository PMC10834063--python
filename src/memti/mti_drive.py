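"""Synthetic coil excitation: DC bias plus two high-frequency tones.

The device sits at the midpoint of a symmetric pair of circular current
loops.  Each loop carries one sinusoidal tone (f1 or f2); superposed with a
DC bias they produce the on-axis drive

    B(t) = B_bias + a1·cos(2π f1 t) + a2·cos(2π f2 t)

whose envelope beats at |f2 − f1| — the magnetic temporal interference
(MTI) signal.  A linear medium (the air control) transmits this waveform
unchanged: only a nonlinear transducer converts the beat into a real
spectral line at the difference frequency.

Drive synthesis is deterministic and seedless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import MU0
from .materials import CoreShellGeometry

__all__ = [
    "DriveSpec",
    "Waveform",
    "loop_axial_field",
    "synthesize_drive",
    "air_control",
    "DriveConfigError",
]


class DriveConfigError(ValueError):
    """Invalid drive configuration (e.g. Nyquist violation)."""


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled time series with a declared unit."""

    time: np.ndarray  # s
    values: np.ndarray
    unit: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and values must be 1-D arrays of equal length")
        if len(t) >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
                raise ValueError("waveform must be uniformly sampled")
        if not np.all(np.isfinite(v)):
            raise ValueError("waveform values must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + self.dt

    def with_values(self, values: np.ndarray, unit: str | None = None,
                    label: str | None = None) -> "Waveform":
        return Waveform(
            time=self.time,
            values=values,
            unit=self.unit if unit is None else unit,
            label=self.label if label is None else label,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time, f"value_{self.unit or 'au'}": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Waveform":
        df = pd.read_csv(path)
        vcol = [c for c in df.columns if c.startswith("value")][0]
        unit = vcol.split("_", 1)[1] if "_" in vcol else ""
        return cls(time=df["time_s"].to_numpy(), values=df[vcol].to_numpy(), unit=unit)

    def to_hdf5(self, path: str | Path, name: str = "waveform") -> None:
        """Compact binary container for long records (requires h5py)."""
        import h5py

        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            g = f.create_group(name)
            g.create_dataset("time", data=self.time)
            g.create_dataset("values", data=self.values)
            g.attrs["unit"] = self.unit
            g.attrs["label"] = self.label

    @classmethod
    def from_hdf5(cls, path: str | Path, name: str = "waveform") -> "Waveform":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[name]
            return cls(
                time=g["time"][:],
                values=g["values"][:],
                unit=str(g.attrs.get("unit", "")),
                label=str(g.attrs.get("label", "")),
            )


def _default_duration() -> float:
    return 20.0 / abs(188e6 - 126e6)


@dataclass(frozen=True)
class DriveSpec:
    """Two-tone coil drive specification.

    Defaults follow the reference configuration: tones at 126 and 188 MHz,
    100 mA loop current, 400 um loop radius, 800 um coil separation, 293 mT
    DC bias, 20 beat periods sampled at 16·f2.  ``amplitude_override`` (T)
    replaces the Biot–Savart tone amplitudes; a scalar applies to both
    tones, a pair (a1, a2) sets them individually.
    """

    f1: float = 126e6
    f2: float = 188e6
    coil_current: float = 0.1
    coil_radius: float = 400e-6
    coil_separation: float = 800e-6
    bias_B: float = 0.293
    duration: float = field(default_factory=_default_duration)
    sample_rate: float = 16 * 188e6
    amplitude_override: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.f1 == self.f2:
            raise DriveConfigError("f1 and f2 must differ")
        if self.sample_rate <= 4.0 * max(self.f1, self.f2):
            raise DriveConfigError(
                f"sample_rate {self.sample_rate:g} Hz violates the 4x Nyquist margin "
                f"for max tone {max(self.f1, self.f2):g} Hz"
            )
        if self.duration < 10.0 / abs(self.f2 - self.f1):
            raise DriveConfigError("duration must cover at least 10 beat periods")

    @property
    def delta_f(self) -> float:
        return abs(self.f2 - self.f1)

    @classmethod
    def from_geometry(cls, geom: CoreShellGeometry, **kwargs) -> "DriveSpec":
        return cls(
            coil_current=geom.coil_current_amplitude,
            coil_radius=geom.coil_radius,
            coil_separation=geom.coil_separation,
            **kwargs,
        )

    @classmethod
    def paper_time_step_preset(cls, **kwargs) -> "DriveSpec":
        """Preset using the reference study's own time step 0.1·0.05/f2."""
        f2 = kwargs.get("f2", 188e6)
        return cls(sample_rate=f2 / (0.1 * 0.05), **kwargs)

    def tone_amplitudes(self) -> tuple[float, float]:
        """Peak tone amplitudes (T) at the device center."""
        if self.amplitude_override is not None:
            if np.isscalar(self.amplitude_override):
                return float(self.amplitude_override), float(self.amplitude_override)
            a1, a2 = self.amplitude_override
            return float(a1), float(a2)
        a = loop_axial_field(self.coil_current, self.coil_radius, self.coil_separation / 2.0)
        return a, a


def loop_axial_field(current: float, loop_radius: float, axial_distance: float) -> float:
    """On-axis field of a circular current loop, B = μ0 I R² / (2 (R²+z²)^{3/2}), T."""
    if loop_radius <= 0:
        raise ValueError("loop_radius must be > 0")
    r2 = loop_radius**2
    return MU0 * current * r2 / (2.0 * (r2 + axial_distance**2) ** 1.5)


def synthesize_drive(spec: DriveSpec) -> Waveform:
    """Total applied flux density B(t) along the device axis (T).

    Deterministic: B(t) = bias + a1·cos(2π f1 t) + a2·cos(2π f2 t), with the
    tone amplitudes from the on-axis loop field at the core center (each
    coil at half the separation) unless overridden.
    """
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    a1, a2 = spec.tone_amplitudes()
    b = (
        spec.bias_B
        + a1 * np.cos(2.0 * np.pi * spec.f1 * t)
        + a2 * np.cos(2.0 * np.pi * spec.f2 * t)
    )
    return Waveform(time=t, values=b, unit="T", label="two-tone drive")


def air_control(spec: DriveSpec) -> Waveform:
    """Drive passed through a linear, non-magnetostrictive medium (identity).

    The negative control for demodulation: its spectrum contains the two
    applied tones only; the beat envelope carries no real line at |f2 − f1|.
    """
    w = synthesize_drive(spec)
    return w.with_values(w.values, label="air control")
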