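"""Finite cables with lumped boundaries and full dendritic trees.

A finite uniform cable of length L, characteristic impedance ``Z_c`` and
propagation constant ``gamma`` terminated by a lumped impedance
``Z_term`` has input impedance (two-port / Koch-Poggio composition)

    Z_in = Z_c * (Z_term + Z_c tanh(gamma L)) / (Z_c + Z_term tanh(gamma L))

and the voltage attenuation from the proximal end to position x (with no
current drawn at x) is

    A(x) = [Z_term cosh(gamma (L-x)) + Z_c sinh(gamma (L-x))]
           / [Z_term cosh(gamma L) + Z_c sinh(gamma L)].

All hyperbolic ratios are evaluated through exponentials with
non-positive real part, so arbitrarily long (electrotonically) segments
are handled without overflow; a sealed end is treated symbolically
(``Z_term = inf``) rather than as a large float.

A dendritic tree is collapsed recursively: every branch sees, at its
distal end, the parallel combination of its daughters' input impedances
(leaves are sealed), and the recording node combines the soma lump (a
quasi-active isopotential sphere) with all root branches.  By
reciprocity, the transfer impedance from any dendritic position x to the
recording node equals the recording-node input impedance times the
product of attenuations along the path from the node to x.  Parameter
gradients along a section are handled by piecewise-uniform
sub-segmentation, each sub-segment linearized about its own local
resting state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import units
from .cable import CableSpec, SpatialProfile, _profile_from_metrics
from .membrane import (MembraneSpec, OperatingPoint, resonance_of,
                       resting_state)


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# lumped boundaries
# ---------------------------------------------------------------------------

class LumpedBoundary:
    """Frequency-to-impedance mapping terminating a cable end.

    ``kind`` is one of ``sealed``, ``semi-infinite``, ``soma-lump``,
    ``resonant-lump``, ``subtree`` or ``custom``; sealed ends are
    symbolic (infinite impedance), never a large float.
    """

    def __init__(self, zfun=None, kind="custom"):
        self.zfun = zfun
        self.kind = kind

    @property
    def is_sealed(self):
        return self.zfun is None

    def __call__(self, f_hz):
        if self.is_sealed:
            raise TreeError("sealed boundary has no numeric impedance")
        return np.asarray(self.zfun(f_hz), complex)

    # -- constructors ------------------------------------------------------
    @classmethod
    def sealed(cls):
        return cls(None, kind="sealed")

    @classmethod
    def semi_infinite(cls, cable: CableSpec, op: OperatingPoint | None = None,
                      mode: str = "full"):
        from .cable import characteristic_impedance
        if op is None:
            op = cable.operating_point()
        return cls(lambda f: characteristic_impedance(cable, f, op=op, mode=mode),
                   kind="semi-infinite")

    @classmethod
    def membrane_patch(cls, membrane: MembraneSpec, area_cm2: float,
                       mode: str = "full", kind: str = "resonant-lump"):
        """Isopotential quasi-active patch of the given area (MOhm)."""
        op = resting_state(membrane)
        # Y mS/cm^2 * cm^2 = mS -> Z = 1/Y kOhm = 1e-3 MOhm
        return cls(lambda f: 1e-3 / (op.admittance(f, mode=mode) * area_cm2),
                   kind=kind)

    @classmethod
    def soma_lump(cls, radius_um: float, membrane: MembraneSpec,
                  mode: str = "full"):
        return cls.membrane_patch(membrane, units.sphere_area_cm2(radius_um),
                                  mode=mode, kind="soma-lump")


def parallel(*impedances):
    """Parallel combination of complex impedance arrays (sealed = absent)."""
    zs = [z for z in impedances if z is not None]
    if not zs:
        return None
    y = sum(1.0 / z for z in zs)
    return 1.0 / y


# ---------------------------------------------------------------------------
# two-port pieces
# ---------------------------------------------------------------------------

def _piece_input(zc, gl, z_term):
    """Input impedance of one uniform piece; z_term None = sealed."""
    e2 = np.exp(-2.0 * gl)
    t = (1.0 - e2) / (1.0 + e2)          # tanh(gamma L), stable
    if z_term is None:
        return zc / t
    return zc * (z_term + zc * t) / (zc + z_term * t)


def _piece_attenuation(zc, gl, z_term, gx):
    """Voltage attenuation from the proximal face to gamma*x = gx."""
    ex = np.exp(-gx)
    exc = np.exp(-(2.0 * gl - gx))
    e2 = np.exp(-2.0 * gl)
    if z_term is None:
        return (ex + exc) / (1.0 + e2)
    num = z_term * (ex + exc) + zc * (ex - exc)
    den = z_term * (1.0 + e2) + zc * (1.0 - e2)
    return num / den


def finite_input_impedance(cable: CableSpec, f_hz, z_term=None,
                           op: OperatingPoint | None = None, mode: str = "full"):
    """Input impedance (MOhm) of a finite uniform cable with a lumped end.

    ``z_term`` may be ``None`` (sealed), a :class:`LumpedBoundary`, or a
    complex array matching ``f_hz``.
    """
    if not math.isfinite(cable.length_um):
        raise TreeError("cable must be finite; use characteristic_impedance")
    from .cable import characteristic_impedance, propagation_constant
    if op is None:
        op = cable.operating_point()
    zc = characteristic_impedance(cable, f_hz, op=op, mode=mode)
    gl = propagation_constant(cable, f_hz, op=op, mode=mode) * cable.length_um
    zt = _term_values(z_term, f_hz)
    return _piece_input(zc, gl, zt)


def _term_values(z_term, f_hz):
    if z_term is None:
        return None
    if isinstance(z_term, LumpedBoundary):
        return None if z_term.is_sealed else z_term(f_hz)
    return np.asarray(z_term, complex)


def transfer_finite(cable: CableSpec, x_um, f_hz, z_term=None,
                    op: OperatingPoint | None = None, mode: str = "full"):
    """Transfer impedance between position x and the (sealed) proximal end.

    The recording electrode sits at x = 0 and draws no current; the
    distal end at x = L carries the lumped boundary.  By reciprocity the
    same value is the voltage at x per unit current injected at the
    proximal end.
    """
    x = np.asarray(x_um, float)
    if np.any(x < 0) or np.any(x > cable.length_um):
        raise TreeError("x outside the segment")
    from .cable import characteristic_impedance, propagation_constant
    if op is None:
        op = cable.operating_point()
    zc = characteristic_impedance(cable, f_hz, op=op, mode=mode)
    g = propagation_constant(cable, f_hz, op=op, mode=mode)
    gl = g * cable.length_um
    zt = _term_values(z_term, f_hz)
    z_in = _piece_input(zc, gl, zt)
    return z_in * _piece_attenuation(zc, gl, zt, g * x)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def _interp_membrane(m0: MembraneSpec, m1: MembraneSpec, t: float) -> MembraneSpec:
    """Linear interpolation of densities/reversals between two specs."""
    if m1 is None or m0 is m1:
        return m0
    if m0.klt is not m1.klt and (
            replace(m0.klt, gbar=0.0) != replace(m1.klt, gbar=0.0)):
        raise TreeError("membrane gradient may only vary gbar, not kinetics shape")
    lerp = lambda a, b: a + (b - a) * t
    klt = replace(m0.klt, gbar=lerp(m0.klt.gbar, m1.klt.gbar))
    return replace(m0, klt=klt,
                   c_m=lerp(m0.c_m, m1.c_m),
                   g_l=lerp(m0.g_l, m1.g_l), e_l=lerp(m0.e_l, m1.e_l),
                   g_h=lerp(m0.g_h, m1.g_h), e_h=lerp(m0.e_h, m1.e_h))


@dataclass(frozen=True)
class Section:
    """Tapered cylindrical section with optional linear parameter gradients.

    ``parent`` is the index of the parent section (-1 = attached to the
    root/soma node).  ``membrane_distal`` (if given) defines linear
    gradients of the conductance densities and reversals from the
    proximal to the distal end; ``diam_distal_um`` a linear taper.
    ``terminal`` optionally replaces the sealed end of a terminal
    section by a lumped boundary.
    """

    length_um: float
    diam_um: float
    r_a: float = 150.0
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    parent: int = -1
    diam_distal_um: float | None = None
    membrane_distal: MembraneSpec | None = None
    terminal: LumpedBoundary | None = None

    def __post_init__(self):
        if self.length_um <= 0:
            raise TreeError("section length must be > 0")
        if self.diam_um <= 0:
            raise TreeError("section diameter must be > 0")
        d1 = self.diam_um if self.diam_distal_um is None else self.diam_distal_um
        if d1 > self.diam_um + 1e-12:
            raise TreeError("diameter must be non-increasing distally")

    def diam_at(self, t: float) -> float:
        d1 = self.diam_um if self.diam_distal_um is None else self.diam_distal_um
        return self.diam_um + (d1 - self.diam_um) * t

    def membrane_at(self, t: float) -> MembraneSpec:
        return _interp_membrane(self.membrane, self.membrane_distal, t)


@dataclass(frozen=True)
class Soma:
    radius_um: float
    membrane: MembraneSpec


@dataclass(frozen=True)
class Morphology:
    """Rooted tree of sections, optionally with a spherical soma lump.

    The recording site is the root node (the soma, or the shared
    proximal end of the root sections when there is no soma).
    """

    sections: tuple
    soma: Soma | None = None

    def __post_init__(self):
        object.__setattr__(self, "sections", tuple(self.sections))
        n = len(self.sections)
        if n == 0:
            raise TreeError("morphology needs at least one section")
        seen_root = False
        for i, s in enumerate(self.sections):
            if s.parent == -1:
                seen_root = True
            elif not (0 <= s.parent < n) or s.parent >= i:
                raise TreeError(
                    "sections must be ordered parent-before-child with valid indices")
        if not seen_root:
            raise TreeError("no root section")

    def children(self):
        ch = [[] for _ in self.sections]
        roots = []
        for i, s in enumerate(self.sections):
            (roots if s.parent == -1 else ch[s.parent]).append(i)
        return roots, ch

    def path_distance(self, sec: int, offset_um: float = 0.0) -> float:
        """Path distance (um) from the root node to a point on a section."""
        d = offset_um
        s = self.sections[sec]
        while s.parent != -1:
            s = self.sections[s.parent]
            d += s.length_um
        return d


# ---------------------------------------------------------------------------
# collapse
# ---------------------------------------------------------------------------

@dataclass
class _Piece:
    sec: int
    x0: float                  # proximal offset within section (um)
    length: float
    zc: np.ndarray
    gamma: np.ndarray          # 1/um
    z_distal: np.ndarray | None = None   # load at the distal face
    a_prox: np.ndarray | None = None     # attenuation root node -> proximal face


class TreeTransfer:
    """Collapsed quasi-active tree on a fixed frequency grid.

    Exposes the input impedance at the recording node and the transfer
    impedance K(x -> node) for any position, evaluated analytically.
    """

    def __init__(self, morph: Morphology, f_hz, seg_len_um: float = 5.0,
                 mode: str = "full"):
        self.morph = morph
        self.f_hz = np.asarray(f_hz, float)
        self.mode = mode
        self.seg_len_um = seg_len_um
        self._build()

    # -- construction ------------------------------------------------------
    def _make_pieces(self, i_sec):
        s = self.morph.sections[i_sec]
        n = max(1, int(math.ceil(s.length_um / self.seg_len_um)))
        dl = s.length_um / n
        pieces = []
        for j in range(n):
            t_mid = (j + 0.5) / n
            mem = s.membrane_at(t_mid)
            d = s.diam_at(t_mid)
            cab = CableSpec(diam_um=d, r_a=s.r_a, length_um=dl, membrane=mem)
            op = resting_state(mem)
            from .cable import characteristic_impedance, propagation_constant
            zc = characteristic_impedance(cab, self.f_hz, op=op, mode=self.mode)
            g = propagation_constant(cab, self.f_hz, op=op, mode=self.mode)
            pieces.append(_Piece(sec=i_sec, x0=j * dl, length=dl, zc=zc, gamma=g))
        return pieces

    def _build(self):
        morph = self.morph
        roots, children = morph.children()
        self.pieces = {i: self._make_pieces(i) for i in range(len(morph.sections))}
        # inward pass: input impedance looking distally, children first
        z_prox = {}
        for i in reversed(range(len(morph.sections))):
            s = morph.sections[i]
            if children[i]:
                if s.terminal is not None:
                    raise TreeError("terminal boundary on a non-terminal section")
                z = parallel(*[z_prox[c] for c in children[i]])
            else:
                z = _term_values(s.terminal, self.f_hz)
            for p in reversed(self.pieces[i]):
                p.z_distal = z
                z = _piece_input(p.zc, p.gamma * p.length, z)
            z_prox[i] = z
        self.z_prox = z_prox
        z_soma = None
        if morph.soma is not None:
            z_soma = LumpedBoundary.soma_lump(
                morph.soma.radius_um, morph.soma.membrane, mode=self.mode)(self.f_hz)
        self.z_node = parallel(z_soma, *[z_prox[i] for i in roots])
        # outward pass: attenuation from the node into every piece
        a_enter = {i: np.ones_like(self.z_node) for i in roots}
        order = roots + [i for i in range(len(morph.sections))
                         if morph.sections[i].parent != -1]
        for i in order:
            a = a_enter[i]
            for p in self.pieces[i]:
                p.a_prox = a
                a = a * _piece_attenuation(p.zc, p.gamma * p.length, p.z_distal,
                                           p.gamma * p.length)
            for c in children[i]:
                a_enter[c] = a

    # -- queries -----------------------------------------------------------
    def input_impedance(self):
        """Input impedance at the recording node (MOhm, complex array)."""
        return self.z_node

    def transfer(self, sec: int, offset_um: float):
        """K(f) between a point on a section and the recording node (MOhm)."""
        s = self.morph.sections[sec]
        if not (0.0 <= offset_um <= s.length_um + 1e-9):
            raise TreeError("offset outside section")
        for p in self.pieces[sec]:
            if offset_um <= p.x0 + p.length + 1e-9:
                x = min(max(offset_um - p.x0, 0.0), p.length)
                a = _piece_attenuation(p.zc, p.gamma * p.length, p.z_distal,
                                       p.gamma * x)
                return self.z_node * p.a_prox * a
        raise TreeError("offset outside section")  # pragma: no cover


def collapse_tree(morph: Morphology, f_hz, seg_len_um: float = 5.0,
                  mode: str = "full") -> TreeTransfer:
    """Collapse the tree; returns a :class:`TreeTransfer` query object."""
    return TreeTransfer(morph, f_hz, seg_len_um=seg_len_um, mode=mode)


def tree_positions(morph: Morphology, spacing_um: float = 10.0):
    """(section, offset) sample points spaced along each section."""
    out = []
    for i, s in enumerate(morph.sections):
        n = max(1, int(round(s.length_um / spacing_um)))
        for j in range(n + 1):
            out.append((i, s.length_um * j / n))
    return out


def spatial_profile_tree(morph: Morphology, positions=None, grid=None,
                         seg_len_um: float = 5.0, mode: str = "full",
                         spacing_um: float = 10.0) -> SpatialProfile:
    """Resonance metrics of K(x -> recording node) over tree positions.

    ``positions`` is a list of (section, offset_um); default samples
    every section at ``spacing_um`` intervals.  Positions are reported
    as path distance from the recording node together with section ids;
    rows are ordered by (section, offset).
    """
    from .membrane import ImpedanceSpectrum, default_grid, resonance_metrics
    if positions is None:
        positions = tree_positions(morph, spacing_um=spacing_um)
    f = default_grid() if grid is None else np.asarray(grid, float)

    # pass 1: coarse peaks on the base grid
    tt = TreeTransfer(morph, f, seg_len_um=seg_len_um, mode=mode)
    coarse = [np.abs(tt.transfer(sec, off)) for sec, off in positions]
    peaks = [f[int(np.argmax(m))] for m in coarse]

    # pass 2: one collapse on the union grid with +/-10% refinement windows
    windows = [np.linspace(0.9 * p, 1.1 * p, 81) for p in peaks
               if 0 < p < f[-1]]
    f2 = np.unique(np.concatenate([f] + windows)) if windows else f
    tt2 = TreeTransfer(morph, f2, seg_len_um=seg_len_um, mode=mode)
    metrics = [resonance_metrics(ImpedanceSpectrum(f_hz=f2, z=tt2.transfer(sec, off)))
               for sec, off in positions]
    xs = np.array([morph.path_distance(sec, off) for sec, off in positions])
    sec_ids = np.array([sec for sec, _ in positions])
    return _profile_from_metrics(xs, metrics, section_id=sec_ids)
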