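"""Abstract morphology builders: cable, ball-and-stick, bipolar, Y, multipolar.

Every builder guarantees a soma-to-tip path length of 200 um (the
multipolar fixture relaxes this per dendrite to widen its resonance
range).  Default membranes derive from the frozen reference patch;
conductance-gradient builders accept per-branch (proximal, distal)
endpoint values so the evolutionary optimizer can drive them.
"""

from __future__ import annotations

import numpy as np

from .membrane import MembraneSpec
from .tree import Morphology, Section, Soma

#: Allowed optimization ranges for the conductance-based models
#: (densities mS/cm^2, geometry um).
PARAM_RANGES = {
    "gbar_klt": (0.5, 30.0),
    "g_h": (0.02, 2.0),
    "diam": (0.5, 4.0),
    "soma_radius": (3.0, 15.0),
}

PATH_LENGTH_UM = 200.0


def _ref_membrane():
    from .workbench import reference_patch
    return reference_patch()


def _graded(base: MembraneSpec, gbar, g_h):
    """(proximal, distal) membranes with endpoint gbar/g_h values."""
    g0, g1 = (gbar, gbar) if np.isscalar(gbar) else gbar
    h0, h1 = (g_h, g_h) if np.isscalar(g_h) else g_h
    m0 = base.with_updates(g_h=h0, klt_gbar=g0)
    m1 = base.with_updates(g_h=h1, klt_gbar=g1)
    return m0, (None if (g0 == g1 and h0 == h1) else m1)


def build_cable(gbar=None, g_h=None, diam=2.0, r_a=150.0,
                membrane: MembraneSpec | None = None,
                length_um: float = PATH_LENGTH_UM) -> Morphology:
    base = membrane or _ref_membrane()
    gbar = base.klt.gbar if gbar is None else gbar
    g_h = base.g_h if g_h is None else g_h
    m0, m1 = _graded(base, gbar, g_h)
    d0, d1 = (diam, diam) if np.isscalar(diam) else diam
    return Morphology(sections=[Section(
        length_um=length_um, diam_um=d0, diam_distal_um=d1, r_a=r_a,
        membrane=m0, membrane_distal=m1)])


def build_ballstick(gbar=None, g_h=None, diam=2.0, r_a=150.0,
                    soma_radius=8.0, membrane: MembraneSpec | None = None,
                    length_um: float = PATH_LENGTH_UM) -> Morphology:
    cab = build_cable(gbar=gbar, g_h=g_h, diam=diam, r_a=r_a,
                      membrane=membrane, length_um=length_um)
    base = membrane or _ref_membrane()
    return Morphology(sections=cab.sections,
                      soma=Soma(radius_um=soma_radius, membrane=base))


def build_bipolar(gbar=(None, None), g_h=(None, None), diam=(2.0, 2.0),
                  r_a=150.0, soma_radius=8.0,
                  membrane: MembraneSpec | None = None) -> Morphology:
    """Two dendrites on opposite poles of the soma, each 200 um to tip."""
    base = membrane or _ref_membrane()
    secs = []
    for b in range(2):
        gb = base.klt.gbar if gbar[b] is None else gbar[b]
        gh = base.g_h if g_h[b] is None else g_h[b]
        m0, m1 = _graded(base, gb, gh)
        d = diam[b]
        d0, d1 = (d, d) if np.isscalar(d) else d
        secs.append(Section(length_um=PATH_LENGTH_UM, diam_um=d0,
                            diam_distal_um=d1, r_a=r_a,
                            membrane=m0, membrane_distal=m1, parent=-1))
    return Morphology(sections=secs, soma=Soma(radius_um=soma_radius, membrane=base))


def build_y(gbar=(None, None, None), g_h=(None, None, None),
            diam=(2.0, 1.5, 1.5), r_a=150.0, soma_radius=8.0,
            parent_frac=0.5, membrane: MembraneSpec | None = None) -> Morphology:
    """Y-dendrite: parent branch splitting into two daughters.

    Parent length = ``parent_frac`` * 200 um; daughters make the
    soma-to-tip path exactly 200 um.
    """
    base = membrane or _ref_membrane()
    lp = PATH_LENGTH_UM * parent_frac
    ld = PATH_LENGTH_UM - lp
    secs = []
    for b, (length, parent) in enumerate([(lp, -1), (ld, 0), (ld, 0)]):
        gb = base.klt.gbar if gbar[b] is None else gbar[b]
        gh = base.g_h if g_h[b] is None else g_h[b]
        m0, m1 = _graded(base, gb, gh)
        d = diam[b]
        d0, d1 = (d, d) if np.isscalar(d) else d
        secs.append(Section(length_um=length, diam_um=d0, diam_distal_um=d1,
                            r_a=r_a, membrane=m0, membrane_distal=m1,
                            parent=parent))
    return Morphology(sections=secs, soma=Soma(radius_um=soma_radius, membrane=base))


#: Frozen synthetic multipolar (stellate-like) classification fixture:
#: per-dendrite (length um, diam um, conductance scale (prox, dist)).
#: Scales multiply both gbar_KLT and g_H of the reference patch; the
#: soma scale places the somatic patch resonance near 205 Hz, the
#: gradients spread the transfer-resonance profile over ~206-280 Hz so
#: the 208 and 228 Hz task bands are both well populated, and the two
#: longer dendrites contribute sharply tuned distal sites.
MULTIPOLAR_SOMA_SCALE = 0.518880
MULTIPOLAR_BRANCHES = (
    (200.0, 2.5, (MULTIPOLAR_SOMA_SCALE, 0.45)),
    (200.0, 2.0, (MULTIPOLAR_SOMA_SCALE, 0.55)),
    (200.0, 1.5, (MULTIPOLAR_SOMA_SCALE, 0.68)),
    (200.0, 1.2, (MULTIPOLAR_SOMA_SCALE, 0.80)),
    (300.0, 1.0, (MULTIPOLAR_SOMA_SCALE, 0.95)),
    (600.0, 1.0, (MULTIPOLAR_SOMA_SCALE, 1.20)),
)


def build_multipolar(membrane: MembraneSpec | None = None,
                     soma_radius=9.0) -> Morphology:
    ref = membrane or _ref_membrane()
    scaled = lambda s: ref.with_updates(g_h=ref.g_h * s, klt_gbar=ref.klt.gbar * s)
    secs = []
    for length, d, (s0, s1) in MULTIPOLAR_BRANCHES:
        secs.append(Section(length_um=length, diam_um=d, r_a=150.0,
                            membrane=scaled(s0), membrane_distal=scaled(s1),
                            parent=-1))
    return Morphology(sections=secs,
                      soma=Soma(radius_um=soma_radius,
                                membrane=scaled(MULTIPOLAR_SOMA_SCALE)))


_BUILDERS = {
    "cable": build_cable,
    "ballstick": build_ballstick,
    "bipolar": build_bipolar,
    "y": build_y,
    "multipolar": build_multipolar,
}


def build(kind: str, **kwargs) -> Morphology:
    try:
        fn = _BUILDERS[kind]
    except KeyError:
        raise ValueError(f"unknown builder {kind!r}; have {sorted(_BUILDERS)}")
    return fn(**kwargs)
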