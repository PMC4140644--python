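"""Analytic impedance of uniform quasi-active cables.

For a uniform cylinder of diameter ``d`` and axial resistivity ``R_a``
carrying a membrane of specific impedance ``z_m(f)``, the frequency-
dependent propagation constant is

    gamma(f) = sqrt( 4 * R_a / (d * z_m(f)) )        [1/length]

(principal branch, Re gamma > 0), the space constant is
``lambda(f) = 1 / Re gamma(f)``, and the input impedance of the
semi-infinite cable is

    Z_in(f) = (4 * R_a / (pi * d^2)) / gamma(f).

The transfer impedance between an injection site at path distance ``x``
and the recording end is ``K(x, f) = Z_in(f) * exp(-gamma(f) * x)``, so
``|K|`` decays as ``exp(-x / lambda(f))``.  Because the resonance of
``lambda(f)`` (call it f_lambda) generally differs from the resonance of
``Z_in`` (f_R at x=0), the peak of ``|K(x, .)|`` drifts from f_R(0)
toward f_lambda with distance: the spatial profile of resonance
frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .membrane import (MembraneSpec, OperatingPoint, ResonanceMetrics,
                       default_grid, resonance_of, resting_state)


class CableError(ValueError):
    pass


@dataclass(frozen=True)
class CableSpec:
    """Uniform cylindrical cable (possibly semi-infinite)."""

    diam_um: float = 2.0
    r_a: float = 150.0                       # Ohm*cm
    length_um: float = math.inf
    membrane: MembraneSpec = field(default_factory=MembraneSpec)

    def __post_init__(self):
        if self.diam_um <= 0:
            raise CableError("diameter must be > 0")
        if self.r_a <= 0:
            raise CableError("axial resistivity must be > 0")
        if self.length_um <= 0:
            raise CableError("length must be > 0")

    def operating_point(self) -> OperatingPoint:
        return resting_state(self.membrane)


def propagation_constant(cable: CableSpec, f_hz, op: OperatingPoint | None = None,
                         mode: str = "full"):
    """Complex propagation constant gamma(f) in 1/um (Re > 0)."""
    if op is None:
        op = cable.operating_point()
    z_m = units.specific_impedance_ohm_cm2(op.admittance(f_hz, mode=mode))  # Ohm*cm^2
    d_cm = units.um_to_cm(cable.diam_um)
    gamma_cm = np.sqrt(4.0 * cable.r_a / (d_cm * z_m))                      # 1/cm
    return gamma_cm * units.CM_PER_UM                                       # 1/um


def space_constant(cable: CableSpec, f_hz, op=None, mode: str = "full"):
    """lambda(f) = 1/Re(gamma) in um."""
    return 1.0 / np.real(propagation_constant(cable, f_hz, op=op, mode=mode))


def characteristic_impedance(cable: CableSpec, f_hz, op=None, mode: str = "full"):
    """Input impedance of the semi-infinite cable, in MOhm (complex)."""
    gamma_um = propagation_constant(cable, f_hz, op=op, mode=mode)
    gamma_cm = gamma_um / units.CM_PER_UM
    d_cm = units.um_to_cm(cable.diam_um)
    z_ohm = 4.0 * cable.r_a / (np.pi * d_cm ** 2) / gamma_cm
    return z_ohm * units.MOHM_PER_OHM


def transfer_semi_infinite(cable: CableSpec, x_um, f_hz, op=None, mode: str = "full"):
    """Transfer impedance K(x, f) = Z_in * exp(-gamma x), MOhm (complex)."""
    if np.any(np.asarray(x_um) < 0):
        raise CableError("x must be >= 0")
    if op is None:
        op = cable.operating_point()
    gamma = propagation_constant(cable, f_hz, op=op, mode=mode)
    z_in = characteristic_impedance(cable, f_hz, op=op, mode=mode)
    return z_in * np.exp(-gamma * np.asarray(x_um, float))


@dataclass(frozen=True)
class SpatialProfile:
    """Resonance metrics of the transfer impedance along a path.

    ``x_um`` is path distance from the recording site (x = 0 at the
    electrode).  ``section_id`` is used by tree profiles; -1 for cables.
    """

    x_um: np.ndarray
    f_r_hz: np.ndarray
    q: np.ndarray              # NaN where an edge is missing
    k_max: np.ndarray          # MOhm
    is_resonant: np.ndarray
    section_id: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd
        data = {"x_um": self.x_um, "f_r_hz": self.f_r_hz, "q": self.q,
                "k_max_mohm": self.k_max, "is_resonant": self.is_resonant}
        if self.section_id is not None:
            data = {"section_id": self.section_id, **data}
        return pd.DataFrame(data)


def _profile_from_metrics(xs, metrics, section_id=None) -> SpatialProfile:
    return SpatialProfile(
        x_um=np.asarray(xs, float),
        f_r_hz=np.array([m.f_r for m in metrics]),
        q=np.array([np.nan if m.q is None else m.q for m in metrics]),
        k_max=np.array([m.z_max for m in metrics]),
        is_resonant=np.array([m.is_resonant for m in metrics]),
        section_id=None if section_id is None else np.asarray(section_id))


def spatial_profile_semi_infinite(cable: CableSpec, xs_um, grid=None,
                                  mode: str = "full") -> SpatialProfile:
    """Resonance frequency, Q and |K|max at each recording distance."""
    xs = np.asarray(xs_um, float)
    if np.any(np.diff(xs) <= 0):
        raise CableError("positions must be strictly increasing")
    op = cable.operating_point()
    metrics = [resonance_of(lambda f, x=x: transfer_semi_infinite(cable, x, f, op=op, mode=mode),
                            grid=grid) for x in xs]
    return _profile_from_metrics(xs, metrics)


def lambda_resonance(cable: CableSpec, grid=None, op=None, mode: str = "full") -> ResonanceMetrics:
    """Peak of the space constant lambda(f) (treated as a 'magnitude')."""
    if op is None:
        op = cable.operating_point()
    return resonance_of(lambda f: space_constant(cable, f, op=op, mode=mode), grid=grid)


@dataclass(frozen=True)
class Mismatch:
    delta_f_hz: float
    f_lambda_hz: float
    f_r_input_hz: float
    is_resonant: bool


def mismatch(cable: CableSpec, grid=None, mode: str = "full") -> Mismatch:
    """Delta f = f_lambda - f_R(Z_in), the driver of the spatial profile."""
    op = cable.operating_point()
    m_in = resonance_of(lambda f: characteristic_impedance(cable, f, op=op, mode=mode),
                        grid=grid)
    m_lam = lambda_resonance(cable, grid=grid, op=op, mode=mode)
    resonant = m_in.is_resonant
    if not resonant:
        return Mismatch(delta_f_hz=0.0, f_lambda_hz=m_lam.f_r,
                        f_r_input_hz=m_in.f_r, is_resonant=False)
    return Mismatch(delta_f_hz=m_lam.f_r - m_in.f_r, f_lambda_hz=m_lam.f_r,
                    f_r_input_hz=m_in.f_r, is_resonant=True)
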