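"""Point-membrane model: KLT kinetics, resting state, quasi-active linearization.

The membrane carries three currents: an ohmic leak, a static
hyperpolarization-activated (H) conductance treated as a second leak
because its kinetics are far slower than the signals of interest, and a
low-threshold potassium current (KLT)

    I_KLT = gbar * w^p * z^q * (V - E_K),      p = 4, q = 1 by default,

with fast activation ``w`` and slow inactivation ``z`` relaxing
first-order toward their voltage-dependent steady states.  Linearizing
the current-balance equation about rest yields the quasi-active
admittance (per unit area)

    Y(f) = i*omega*C + G_eff + gamma_w / (1 + i*omega*tau_w)
                             + gamma_z / (1 + i*omega*tau_z)

where ``G_eff = g_L + g_H + gbar*w_inf^p*z_inf^q`` is the slope-free
(ohmic) conductance and ``gamma_w`` / ``gamma_z`` are the signed gating
conductances produced by the voltage dependence of the open fractions.
``gamma_w > 0`` (restorative) creates the impedance resonance;
``gamma_z < 0`` (regenerative) slightly amplifies it at low frequency.
The ``simplified`` mode drops the inactivation term, whose corner
frequency ``1/(2*pi*tau_z)`` (~12.5 Hz at rest) lies far below the
resonance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import units


class MembraneError(ValueError):
    """Raised for non-physical membrane parameters or failed root searches."""


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KLTKinetics:
    """Low-threshold potassium channel: ``gbar * w^p * z^q * (V - e_k)``.

    ``w_inf^p`` is a rising Boltzmann with half-activation ``w_half`` and
    slope ``w_slope`` (mV); ``z_inf`` is a falling Boltzmann with a floor
    ``z_floor`` (non-inactivating fraction).  Both time constants are
    bell-shaped in voltage and divided by the dimensionless ``rate_scale``
    (temperature / channel-speed factor, frozen with the calibration set).
    """

    gbar: float = 1.0          # mS/cm^2
    e_k: float = -90.0         # mV
    p: int = 4
    q: int = 1
    w_half: float = -48.0      # mV, half-activation of w^p
    w_slope: float = 6.0       # mV
    z_half: float = -71.0      # mV
    z_slope: float = 10.0      # mV
    z_floor: float = 0.5
    # tau_w(V) = (tau_w_min + tau_w_amp/(exp((V-v0)/k1)+exp(-(V-v0)/k2))) / rate_scale
    tau_w_min: float = 0.10    # ms (before rate scaling)
    tau_w_amp: float = 10.0    # ms
    tau_w_v0: float = -60.0    # mV
    tau_w_k1: float = 6.0      # mV
    tau_w_k2: float = 45.0     # mV
    tau_z_min: float = 10.0    # ms
    tau_z_amp: float = 80.0    # ms
    tau_z_v0: float = -60.0    # mV
    tau_z_k1: float = 20.0     # mV
    tau_z_k2: float = 8.0      # mV
    rate_scale: float = 1.0

    def __post_init__(self):
        if self.gbar < 0:
            raise MembraneError("gbar must be >= 0")
        if self.rate_scale <= 0:
            raise MembraneError("rate_scale must be > 0")

    # -- steady states -----------------------------------------------------
    def w_inf(self, v):
        b = 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - self.w_half) / self.w_slope))
        return b ** (1.0 / self.p)

    def z_inf(self, v):
        s = 1.0 / (1.0 + np.exp((np.asarray(v, float) - self.z_half) / self.z_slope))
        return self.z_floor + (1.0 - self.z_floor) * s

    def d_wp_dv(self, v):
        """d(w_inf^p)/dV — derivative of the Boltzmann itself."""
        b = 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - self.w_half) / self.w_slope))
        return b * (1.0 - b) / self.w_slope

    def d_zq_dv(self, v):
        """d(z_inf^q)/dV for q = 1 (general q uses the chain rule)."""
        s = 1.0 / (1.0 + np.exp((np.asarray(v, float) - self.z_half) / self.z_slope))
        dz = -(1.0 - self.z_floor) * s * (1.0 - s) / self.z_slope
        if self.q == 1:
            return dz
        return self.q * self.z_inf(v) ** (self.q - 1) * dz

    # -- time constants ----------------------------------------------------
    def tau_w(self, v):
        v = np.asarray(v, float)
        u = v - self.tau_w_v0
        bell = self.tau_w_amp / (np.exp(u / self.tau_w_k1) + np.exp(-u / self.tau_w_k2))
        return (self.tau_w_min + bell) / self.rate_scale

    def tau_z(self, v):
        v = np.asarray(v, float)
        u = v - self.tau_z_v0
        bell = self.tau_z_amp / (np.exp(u / self.tau_z_k1) + np.exp(-u / self.tau_z_k2))
        return (self.tau_z_min + bell) / self.rate_scale

    def conductance(self, w, z):
        """Instantaneous KLT conductance density (mS/cm^2)."""
        return self.gbar * w ** self.p * z ** self.q


@dataclass(frozen=True)
class MembraneSpec:
    """Per-unit-area membrane at a point: passive + static H + KLT."""

    c_m: float = 1.0           # uF/cm^2
    g_l: float = 0.1           # mS/cm^2
    e_l: float = -65.0         # mV
    g_h: float = 1.0           # mS/cm^2
    e_h: float = -43.0         # mV
    klt: KLTKinetics = field(default_factory=KLTKinetics)

    def __post_init__(self):
        if self.c_m <= 0:
            raise MembraneError("c_m must be > 0")
        if self.g_l < 0 or self.g_h < 0:
            raise MembraneError("conductance densities must be >= 0")

    def with_updates(self, **kwargs) -> "MembraneSpec":
        """Copy with scalar fields replaced; ``klt_<field>`` updates kinetics."""
        klt_kw = {k[4:]: v for k, v in kwargs.items() if k.startswith("klt_")}
        other = {k: v for k, v in kwargs.items() if not k.startswith("klt_")}
        klt = replace(self.klt, **klt_kw) if klt_kw else self.klt
        return replace(self, klt=klt, **other)

    def steady_current(self, v):
        """Steady-state ionic current density (uA/cm^2, outward positive)."""
        k = self.klt
        return (self.g_l * (v - self.e_l)
                + self.g_h * (v - self.e_h)
                + k.conductance(k.w_inf(v), k.z_inf(v)) * (v - k.e_k))


# ---------------------------------------------------------------------------
# operating point / linearization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    """Resting state and quasi-active coefficients of a membrane patch."""

    spec: MembraneSpec
    v_rest: float              # mV
    w_inf: float
    z_inf: float
    tau_w: float               # ms
    tau_z: float               # ms
    g_eff: float               # mS/cm^2  (slope-free conductance)
    tau_eff: float             # ms       (C_m / G_eff)
    gamma_w: float             # mS/cm^2  (>0, restorative)
    gamma_z: float             # mS/cm^2  (<0, regenerative)
    f_eff: float               # Hz       (G_eff / (2*pi*C_m))

    def admittance(self, f_hz, mode: str = "full"):
        """Quasi-active admittance Y(f) in mS/cm^2 (complex).

        ``mode='full'`` keeps both gating terms; ``mode='simplified'``
        drops the slow inactivation term.
        """
        w = units.omega(f_hz)
        y = 1j * w * self.spec.c_m + self.g_eff \
            + self.gamma_w / (1.0 + 1j * w * self.tau_w)
        if mode == "full":
            y = y + self.gamma_z / (1.0 + 1j * w * self.tau_z)
        elif mode != "simplified":
            raise ValueError(f"unknown mode {mode!r}")
        return y

    def impedance(self, f_hz, mode: str = "full"):
        """Specific impedance z_m(f) in kOhm*cm^2 (complex)."""
        y = self.admittance(f_hz, mode=mode)
        if np.any(y == 0):
            raise MembraneError("zero admittance: non-physical parameters")
        return 1.0 / y


def _bisect(fun, lo, hi, xtol=1e-12, maxiter=200):
    flo = fun(lo)
    for _ in range(maxiter):
        mid = 0.5 * (lo + hi)
        fm = fun(mid)
        if fm == 0.0 or (hi - lo) < xtol:
            return mid
        if (flo < 0) == (fm < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def resting_state(spec: MembraneSpec, bracket=(-120.0, 0.0)) -> OperatingPoint:
    """Solve the steady-state current balance and linearize about rest.

    The bracket is scanned on a 0.25 mV grid for sign changes; each is
    refined by bisection to 1e-12 mV.  If several roots exist the most
    hyperpolarized is returned with a warning (the depolarized roots of a
    KLT membrane are unstable or non-physiological).
    """
    lo, hi = bracket
    grid = np.arange(lo, hi + 0.25, 0.25)
    cur = spec.steady_current(grid)
    sign = np.sign(cur)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise MembraneError(
            f"no resting potential in bracket [{lo}, {hi}] mV: steady current "
            f"does not change sign")
    if len(idx) > 1:
        warnings.warn(
            f"{len(idx)} roots of the steady-state current in [{lo}, {hi}] mV;"
            " using the most hyperpolarized", stacklevel=2)
    i = idx[0]
    v_rest = _bisect(spec.steady_current, grid[i], grid[i + 1])

    k = spec.klt
    w = float(k.w_inf(v_rest))
    z = float(k.z_inf(v_rest))
    g_klt = k.conductance(w, z)
    g_eff = spec.g_l + spec.g_h + g_klt
    driving = v_rest - k.e_k
    gamma_w = k.gbar * (z ** k.q) * float(k.d_wp_dv(v_rest)) * driving
    gamma_z = k.gbar * (w ** k.p) * float(k.d_zq_dv(v_rest)) * driving
    tau_eff = spec.c_m / g_eff
    return OperatingPoint(
        spec=spec, v_rest=v_rest, w_inf=w, z_inf=z,
        tau_w=float(k.tau_w(v_rest)), tau_z=float(k.tau_z(v_rest)),
        g_eff=g_eff, tau_eff=tau_eff, gamma_w=gamma_w, gamma_z=gamma_z,
        f_eff=units.f_hz_from_rate(1.0 / tau_eff) )


def linearized_admittance(op: OperatingPoint, f_hz, mode: str = "full"):
    """Functional wrapper around :meth:`OperatingPoint.admittance`."""
    return op.admittance(f_hz, mode=mode)


def nonlinear_rhs(spec: MembraneSpec, v, w, z, i_inj=0.0):
    """Time derivatives (dV/dt, dw/dt, dz/dt) of the point membrane.

    ``i_inj`` is an injected current density in uA/cm^2 (inward positive).
    """
    k = spec.klt
    i_ion = (spec.g_l * (v - spec.e_l) + spec.g_h * (v - spec.e_h)
             + k.conductance(w, z) * (v - k.e_k))
    dv = (i_inj - i_ion) / spec.c_m
    dw = (k.w_inf(v) - w) / k.tau_w(v)
    dz = (k.z_inf(v) - z) / k.tau_z(v)
    return dv, dw, dz


# ---------------------------------------------------------------------------
# spectra and resonance metrics
# ---------------------------------------------------------------------------

def default_grid(f_min=0.5, f_max=2000.0, n=2000):
    """Logarithmic frequency grid (Hz) covering the resonance range."""
    return np.geomspace(f_min, f_max, n)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance sampled on a frequency grid.

    ``area`` is ``'specific'`` (values in kOhm*cm^2) or a membrane area in
    cm^2 (values in MOhm).  ``mode`` records the linearization variant.
    """

    f_hz: np.ndarray
    z: np.ndarray
    area: object = "specific"
    mode: str = "full"

    def __post_init__(self):
        f = np.asarray(self.f_hz, float)
        z = np.asarray(self.z, complex)
        if f.size == 0:
            raise MembraneError("empty frequency grid")
        if f.size != z.size:
            raise MembraneError("grid/impedance size mismatch")
        if np.any(np.diff(f) <= 0) or f[0] < 0:
            raise MembraneError("frequency grid must be >= 0 and strictly increasing")
        if not np.all(np.isfinite(z)):
            raise MembraneError("impedance not finite on the grid")
        object.__setattr__(self, "f_hz", f)
        object.__setattr__(self, "z", z)


def impedance_spectrum(spec: MembraneSpec, grid=None, mode: str = "full",
                       op: OperatingPoint | None = None) -> ImpedanceSpectrum:
    """Quasi-active impedance spectrum of a membrane patch."""
    if grid is None:
        grid = default_grid()
    if op is None:
        op = resting_state(spec)
    return ImpedanceSpectrum(f_hz=np.asarray(grid, float),
                             z=op.impedance(grid, mode=mode),
                             area="specific", mode=mode)


@dataclass(frozen=True)
class ResonanceMetrics:
    f_r: float                 # Hz (0 when not resonant)
    q: float | None            # f_r / (f_plus - f_minus); None if an edge is missing
    z_max: float               # same units as the spectrum
    is_resonant: bool
    f_minus: float | None = None
    f_plus: float | None = None

    @property
    def bandwidth(self):
        if self.f_minus is None or self.f_plus is None:
            return None
        return self.f_plus - self.f_minus


def _parabolic_peak(f, mag, i):
    """Quadratic interpolation of the peak through three grid points."""
    if i == 0 or i == len(f) - 1:
        return f[i], mag[i]
    x0, x1, x2 = f[i - 1], f[i], f[i + 1]
    y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:
        return f[i], mag[i]
    xp = -b / (2 * a)
    if not (x0 <= xp <= x2):
        return f[i], mag[i]
    c = (x1 * x2 * (x1 - x2) * y0 + x2 * x0 * (x2 - x0) * y1
         + x0 * x1 * (x0 - x1) * y2) / denom
    return xp, a * xp * xp + b * xp + c


def resonance_metrics(spectrum: ImpedanceSpectrum) -> ResonanceMetrics:
    """Peak frequency, half-power bandwidth and Q of an impedance magnitude.

    The peak is refined by parabolic interpolation; the half-power
    (|Z|max / sqrt(2)) edges are linearly interpolated between grid
    points.  A spectrum whose magnitude peaks at the lowest grid
    frequency (low-pass, peak effectively at DC) is flagged non-resonant
    with ``f_r = 0``.  A genuine interior peak whose low-frequency side
    never drops to the half-power level keeps its f_R but has no
    bandwidth, hence ``q=None``.
    """
    f = spectrum.f_hz
    mag = np.abs(spectrum.z)
    i = int(np.argmax(mag))
    if i == 0 or mag[i] <= mag[0] * (1.0 + 1e-9):
        return ResonanceMetrics(f_r=0.0, q=None, z_max=float(mag[0]), is_resonant=False)
    f_r, z_pk = _parabolic_peak(f, mag, i)
    level = z_pk / np.sqrt(2.0)

    def interp(j0, j1):
        m0, m1 = mag[j0], mag[j1]
        t = (level - m0) / (m1 - m0)
        return f[j0] + t * (f[j1] - f[j0])

    f_minus = None
    for j in range(i, 0, -1):
        if mag[j - 1] < level <= mag[j]:
            f_minus = interp(j - 1, j)
            break
    f_plus = None
    for j in range(i, len(f) - 1):
        if mag[j + 1] < level <= mag[j]:
            f_plus = interp(j + 1, j)
            break
    q = f_r / (f_plus - f_minus) if (f_plus is not None and f_minus is not None) else None
    return ResonanceMetrics(f_r=float(f_r), q=q, z_max=float(z_pk),
                            is_resonant=True,
                            f_minus=None if f_minus is None else float(f_minus),
                            f_plus=None if f_plus is None else float(f_plus))


def resonance_of(zfun, grid=None, refine=True) -> ResonanceMetrics:
    """Resonance metrics of an arbitrary impedance function ``zfun(f_hz)``.

    Evaluates on a coarse log grid, then (by default) adds a dense linear
    refinement within +/-10% of the coarse peak so f_R is resolved to
    ~0.1 Hz regardless of the log spacing.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, float)
    z = np.asarray(zfun(grid), complex)
    mag = np.abs(z)
    i = int(np.argmax(mag))
    if refine and 0 < i < len(grid) - 1:
        f0 = grid[i]
        fine = np.linspace(0.9 * f0, 1.1 * f0, 401)
        allf = np.unique(np.concatenate([grid, fine]))
        z = np.asarray(zfun(allf), complex)
        grid = allf
    return resonance_metrics(ImpedanceSpectrum(f_hz=grid, z=z))
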