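"""Equivalent-circuit forward model for bone impedance spectra.

The circuit is a bulk resistance ``R_b`` in series with a parallel
combination of an interfacial charge-transfer resistance ``R_Ct`` and a
constant phase element (CPE)::

    Z(f) = R_b + 1 / (1/R_Ct + Q * (j*2*pi*f)**alpha)

The CPE follows the universal convention ``Z_CPE = 1/(Q (j omega)^alpha)``
with ``Q`` in S.s^alpha; ``alpha = 1`` recovers an ideal capacitor. Phase
angles are stored signed (negative for capacitive behaviour); Bode-style
reporting of ``|theta|`` is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "FrequencyGrid",
    "CircuitParams",
    "ImpedanceSpectrum",
    "make_grid",
    "cpe_impedance",
    "circuit_impedance",
    "to_polar",
    "to_rectangular",
    "DEFAULT_F_MIN",
    "DEFAULT_F_MAX",
    "DEFAULT_N_POINTS",
]

#: Default measurement band: 60 log-spaced points over 1 Hz .. 100 kHz.
DEFAULT_F_MIN = 1.0
DEFAULT_F_MAX = 1.0e5
DEFAULT_N_POINTS = 60


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly ascending, positive measurement frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise InvalidArgumentError("frequency grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise InvalidArgumentError("frequencies must be finite and > 0")
        if np.any(np.diff(f) <= 0):
            raise InvalidArgumentError("frequencies must be strictly ascending")
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return int(self.frequencies.size)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies, ``omega = 2*pi*f`` (rad/s)."""
        return 2.0 * np.pi * self.frequencies


@dataclass(frozen=True)
class CircuitParams:
    """Four-parameter equivalent-circuit state.

    Attributes
    ----------
    r_b : float
        Bulk bone resistance, ohm.
    r_ct : float
        Interfacial charge-transfer resistance, ohm.
    q : float
        CPE magnitude, S.s^alpha.
    alpha : float
        CPE exponent in (0, 1]; 1 is an ideal capacitor.
    """

    r_b: float
    r_ct: float
    q: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("r_b", "r_ct", "q"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidArgumentError(f"{name} must be finite and > 0, got {v!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise InvalidArgumentError(f"alpha must lie in (0, 1], got {self.alpha!r}")

    def as_array(self) -> np.ndarray:
        """Log-space parameter vector used by the fitter:
        ``[log10 r_b, log10 r_ct, log10 q, alpha]``."""
        return np.array(
            [np.log10(self.r_b), np.log10(self.r_ct), np.log10(self.q), self.alpha]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "CircuitParams":
        return cls(
            r_b=10.0 ** x[0], r_ct=10.0 ** x[1], q=10.0 ** x[2],
            alpha=float(np.clip(x[3], 1e-12, 1.0)),
        )


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance sampled on a frequency grid.

    ``z_real``/``z_imag`` are in ohm; the polar views ``modulus`` (ohm) and
    ``phase_deg`` (signed degrees, ``arctan2(z_imag, z_real)``) are derived.
    """

    grid: FrequencyGrid
    z_real: np.ndarray
    z_imag: np.ndarray

    def __post_init__(self) -> None:
        zr = np.asarray(self.z_real, dtype=float)
        zi = np.asarray(self.z_imag, dtype=float)
        n = len(self.grid)
        if zr.shape != (n,) or zi.shape != (n,):
            raise InvalidArgumentError(
                f"z_real/z_imag must have length {n} matching the grid"
            )
        object.__setattr__(self, "z_real", zr)
        object.__setattr__(self, "z_imag", zi)

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def z(self) -> np.ndarray:
        """Complex impedance values, ohm."""
        return self.z_real + 1j * self.z_imag

    @property
    def modulus(self) -> np.ndarray:
        return np.hypot(self.z_real, self.z_imag)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.arctan2(self.z_imag, self.z_real))


def make_grid(
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    n_points: int = DEFAULT_N_POINTS,
) -> FrequencyGrid:
    """Logarithmically equispaced frequency grid from ``f_min`` to ``f_max``
    inclusive.

    The default reproduces the measurement design: 60 points over
    [1 Hz, 100 kHz].
    """
    if not (np.isfinite(f_min) and f_min > 0):
        raise InvalidArgumentError(f"f_min must be > 0, got {f_min!r}")
    if not (np.isfinite(f_max) and f_max > f_min):
        raise InvalidArgumentError(f"f_max must exceed f_min, got {f_max!r}")
    if n_points < 2:
        raise InvalidArgumentError(f"n_points must be >= 2, got {n_points!r}")
    f = np.logspace(np.log10(f_min), np.log10(f_max), int(n_points))
    # force exact endpoints against logspace round-off
    f[0], f[-1] = f_min, f_max
    return FrequencyGrid(f)


def cpe_impedance(q: float, alpha: float, f) -> np.ndarray:
    """Constant-phase-element impedance ``1/(Q (j 2 pi f)^alpha)``.

    The result has phase ``-alpha * 90`` degrees at every frequency and
    modulus ``1/(Q (2 pi f)^alpha)``.
    """
    if not (np.isfinite(q) and q > 0):
        raise InvalidArgumentError(f"Q must be > 0, got {q!r}")
    if not (0.0 < alpha <= 1.0):
        raise InvalidArgumentError(f"alpha must lie in (0, 1], got {alpha!r}")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise InvalidArgumentError("frequencies must be > 0")
    omega = 2.0 * np.pi * f
    return 1.0 / (q * (1j * omega) ** alpha)


def circuit_impedance(params: CircuitParams, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Forward model: ``Z(f) = R_b + 1/(1/R_Ct + Q (j 2 pi f)^alpha)``.

    High-frequency limit is ``R_b`` (CPE shorts the parallel branch); the
    zero-frequency limit is ``R_b + R_Ct`` (CPE open).
    """
    omega = grid.omega
    y_branch = 1.0 / params.r_ct + params.q * (1j * omega) ** params.alpha
    z = params.r_b + 1.0 / y_branch
    return ImpedanceSpectrum(grid=grid, z_real=z.real, z_imag=z.imag)


def to_polar(spectrum: ImpedanceSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(|Z| in ohm, theta in signed degrees)``."""
    return spectrum.modulus, spectrum.phase_deg


def to_rectangular(z_mod, phase_deg) -> tuple[np.ndarray, np.ndarray]:
    """Convert polar ``(|Z|, theta in degrees)`` to ``(z_real, z_imag)``."""
    z_mod = np.asarray(z_mod, dtype=float)
    phase_deg = np.asarray(phase_deg, dtype=float)
    if z_mod.shape != phase_deg.shape:
        raise InvalidArgumentError("modulus and phase arrays must have equal length")
    theta = np.radians(phase_deg)
    return z_mod * np.cos(theta), z_mod * np.sin(theta)
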