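"""Fractional-order respiratory impedance model.

The respiratory input impedance measured by the forced oscillation
technique (FOT) is modelled as a two-term fractional-order network

    Z(jw) = FrL * (jw)**alpha + 1 / (FrC * (jw)**beta)

where ``FrL`` is a fractional inertance capturing the joint resistive and
inertial behaviour of the airways (exponent ``alpha``) and ``FrC`` is a
constant-phase fractional compliance capturing peripheral/tissue behaviour
(exponent ``beta``).  On the principal branch ``(jw)**x = w**x *
exp(j*x*pi/2)``, so the model separates into closed-form real (resistance,
``Zr``) and imaginary (reactance, ``Zx``) parts.

The tissue compartment is summarised by three derived quantities:

* damping ``G = cos(pi*beta/2) / FrC`` — dissipative tissue coefficient,
* elastance ``H = sin(pi*beta/2) / FrC`` — elastic tissue coefficient,
* hysteresivity ``eta = G / H = cot(pi*beta/2)`` — a dimensionless index
  of tissue heterogeneity that depends on ``beta`` only.

Impedance values are expressed in cmH2O.s/L throughout; frequencies are
entered in Hz and converted internally to angular frequency ``w = 2*pi*f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateParameterError",
    "FrequencyGrid",
    "FrOrParameters",
    "TissueParameters",
    "ImpedanceSpectrum",
    "default_grid",
    "evaluate_model",
    "derive_tissue",
    "hysteresivity_of_beta",
]

#: exponents closer than this to zero are treated as degenerate
DEGENERACY_EPS = 1e-6

HALF_PI = np.pi / 2.0


class DegenerateParameterError(ValueError):
    """Raised when a parameter lies in a degenerate corner of the domain.

    ``beta == 0`` makes the tissue compartment purely resistive (``H = 0``)
    and hysteresivity undefined; ``alpha == 0`` collapses the inertance
    term to a constant.  Both are excluded from the model domain.
    """


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing set of oscillation frequencies in Hz."""

    freqs_hz: np.ndarray

    #: minimum number of points for a usable spectrum
    MIN_POINTS = 3
    #: minimum number of points for parameter estimation
    MIN_POINTS_FIT = 6

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        object.__setattr__(self, "freqs_hz", f)
        if f.ndim != 1 or f.size < self.MIN_POINTS:
            raise ValueError(
                f"frequency grid needs >= {self.MIN_POINTS} points, got {f.size}"
            )
        if not np.all(np.isfinite(f)):
            raise ValueError("frequency grid contains non-finite values")
        if np.any(f <= 0):
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies ``2*pi*f`` in rad/s."""
        return 2.0 * np.pi * self.freqs_hz

    def __len__(self) -> int:
        return int(self.freqs_hz.size)


def default_grid() -> FrequencyGrid:
    """Conventional FOT measurement grid: 4–32 Hz in 2-Hz steps."""
    return FrequencyGrid(np.arange(4.0, 33.0, 2.0))


@dataclass(frozen=True)
class FrOrParameters:
    """Parameters of the fractional-order impedance model.

    ``FrL > 0`` and ``FrC > 0`` carry units such that each impedance term
    is in cmH2O.s/L; ``alpha`` and ``beta`` are dimensionless exponents in
    (0, 1] and [0, 1] respectively.
    """

    FrL: float
    alpha: float
    FrC: float
    beta: float

    def __post_init__(self) -> None:
        if not all(
            np.isfinite([self.FrL, self.alpha, self.FrC, self.beta])
        ):
            raise ValueError("parameters must be finite")
        if self.FrL <= 0:
            raise ValueError(f"FrL must be positive, got {self.FrL}")
        if self.FrC <= 0:
            raise ValueError(f"FrC must be positive, got {self.FrC}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not 0 <= self.beta <= 1:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.FrL, self.alpha, self.FrC, self.beta])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "FrOrParameters":
        return cls(FrL=float(x[0]), alpha=float(x[1]), FrC=float(x[2]), beta=float(x[3]))


@dataclass(frozen=True)
class TissueParameters:
    """Derived tissue mechanics: damping G, elastance H, hysteresivity eta."""

    G: float
    H: float
    eta: float

    def __post_init__(self) -> None:
        if self.G < 0 or self.H < 0:
            raise ValueError("G and H must be non-negative")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """One subject's measured (or simulated) impedance spectrum.

    ``zr`` (resistance) and ``zx`` (reactance) hold one value per grid
    frequency, in cmH2O.s/L.  With ``strict=True`` (default) non-finite
    values are rejected; relaxed construction exists so that corrupt
    records can be carried through batch fitting and flagged there.
    """

    subject_id: str
    grid: FrequencyGrid
    zr: np.ndarray
    zx: np.ndarray
    strict: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        zr = np.asarray(self.zr, dtype=float)
        zx = np.asarray(self.zx, dtype=float)
        object.__setattr__(self, "zr", zr)
        object.__setattr__(self, "zx", zx)
        n = len(self.grid)
        if zr.shape != (n,) or zx.shape != (n,):
            raise ValueError(
                f"zr/zx must have exactly one value per frequency ({n}), "
                f"got shapes {zr.shape} and {zx.shape}"
            )
        if self.strict and not self.is_finite():
            raise ValueError("spectrum contains non-finite values")

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.zr)) and np.all(np.isfinite(self.zx)))


def _check_positive_omega(omega: np.ndarray) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0) or not np.all(np.isfinite(omega)):
        raise ValueError("angular frequencies must be positive and finite")
    return omega


def impedance_components(
    params: FrOrParameters, omega: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Real and imaginary model impedance at angular frequencies ``omega``.

    Uses the principal branch of the fractional power,
    ``(jw)**x = w**x * (cos(x*pi/2) + j*sin(x*pi/2))``, giving

    ``Zr = FrL*w**alpha*cos(alpha*pi/2) + cos(beta*pi/2)/(FrC*w**beta)``
    ``Zx = FrL*w**alpha*sin(alpha*pi/2) - sin(beta*pi/2)/(FrC*w**beta)``
    """
    omega = _check_positive_omega(omega)
    a, b = params.alpha, params.beta
    airway = params.FrL * omega**a
    tissue = 1.0 / (params.FrC * omega**b)
    zr = airway * np.cos(HALF_PI * a) + tissue * np.cos(HALF_PI * b)
    zx = airway * np.sin(HALF_PI * a) - tissue * np.sin(HALF_PI * b)
    return zr, zx


def evaluate_model(
    params: FrOrParameters, grid: FrequencyGrid, subject_id: str = "model"
) -> ImpedanceSpectrum:
    """Evaluate the fractional-order model on ``grid``."""
    zr, zx = impedance_components(params, grid.omega)
    return ImpedanceSpectrum(subject_id=subject_id, grid=grid, zr=zr, zx=zx)


def derive_tissue(params: FrOrParameters) -> TissueParameters:
    """Tissue damping, elastance and hysteresivity from the compliance term.

    ``G = cos(pi*beta/2)/FrC``, ``H = sin(pi*beta/2)/FrC``, ``eta = G/H``.
    ``beta`` at (or numerically indistinguishable from) zero makes ``H``
    vanish and ``eta`` undefined and is rejected explicitly rather than
    silently returning infinities.
    """
    if params.beta < DEGENERACY_EPS:
        raise DegenerateParameterError(
            f"beta={params.beta} is degenerate: H -> 0 and hysteresivity undefined"
        )
    inv_c = 1.0 / params.FrC
    g = inv_c * np.cos(HALF_PI * params.beta)
    h = inv_c * np.sin(HALF_PI * params.beta)
    return TissueParameters(G=float(g), H=float(h), eta=float(g / h))


def hysteresivity_of_beta(beta: float) -> float:
    """Hysteresivity ``eta = cot(pi*beta/2)`` as a function of ``beta`` alone.

    Strictly decreasing on (0, 1]; independent of ``FrC``.
    """
    if not np.isfinite(beta) or beta < DEGENERACY_EPS:
        raise DegenerateParameterError(f"beta={beta} outside the domain (0, 1]")
    if beta > 1:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    return float(np.cos(HALF_PI * beta) / np.sin(HALF_PI * beta))
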