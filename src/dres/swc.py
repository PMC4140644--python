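"""Standard 7-column SWC reader/writer for :class:`~dres.tree.Morphology`.

Columns: id, type, x, y, z, radius, parent (1-based ids, parent -1 for
the root).  The soma is a single sphere taken from the first type-1
record; unknown structure types map to dendrite (type 3) with a warning.
Section membranes are not stored in SWC; readers attach a caller-supplied
(or the frozen reference) membrane uniformly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .membrane import MembraneSpec
from .tree import Morphology, Section, Soma, TreeError

SOMA, AXON, DEND, APIC = 1, 2, 3, 4


def read_swc(path, membrane: MembraneSpec | None = None, r_a: float = 150.0) -> Morphology:
    if membrane is None:
        from .workbench import reference_patch
        membrane = reference_patch()
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise TreeError(f"{path}:{ln}: expected 7 SWC columns")
        rows.append((int(parts[0]), int(parts[1]), *map(float, parts[2:6]),
                     int(parts[6])))
    if not rows:
        raise TreeError(f"{path}: empty SWC file")
    byid = {r[0]: r for r in rows}

    soma = None
    soma_ids = {r[0] for r in rows if r[1] == SOMA}
    if soma_ids:
        first = byid[min(soma_ids)]
        soma = Soma(radius_um=first[5], membrane=membrane)

    for r in rows:
        if r[1] not in (SOMA, DEND, APIC):
            warnings.warn(f"SWC type {r[1]} mapped to dendrite", stacklevel=2)

    children = {}
    for r in rows:
        if r[0] in soma_ids:
            continue
        par = r[6]
        key = -1 if (par == -1 or par in soma_ids) else par
        children.setdefault(key, []).append(r[0])

    # walk unbranched chains into sections
    sections, sec_index = [], {}

    def chain_from(start_id, parent_sec):
        pts = []
        prev = byid[start_id][6]
        prev_xyz = (np.array(byid[prev][2:5]) if prev in byid and prev not in soma_ids
                    else None)
        node = start_id
        while True:
            r = byid[node]
            pts.append(r)
            kids = children.get(node, [])
            if len(kids) != 1:
                break
            node = kids[0]
        xyz = np.array([p[2:5] for p in pts])
        if prev_xyz is not None:
            xyz = np.vstack([prev_xyz, xyz])
        seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        length = float(seg.sum())
        if length <= 0:
            length = 1.0
        radii = np.array([p[5] for p in pts])
        d0, d1 = 2.0 * radii[0], 2.0 * radii[-1]
        if d1 > d0:
            d0 = d1 = float(2.0 * radii.mean())
        sec = Section(length_um=length, diam_um=float(d0),
                      diam_distal_um=float(d1), r_a=r_a, membrane=membrane,
                      parent=parent_sec)
        sections.append(sec)
        idx = len(sections) - 1
        sec_index[pts[-1][0]] = idx
        for kid in children.get(pts[-1][0], []):
            chain_from(kid, idx)

    for root in children.get(-1, []):
        chain_from(root, -1)
    if not sections:
        raise TreeError(f"{path}: no dendrite sections")
    return Morphology(sections=sections, soma=soma)


def write_swc(morph: Morphology, path) -> None:
    """Write a morphology as SWC, laying sections out along +x per branch.

    Geometry is synthesized (SWC stores coordinates, the model stores
    path lengths); path lengths, diameters and topology round-trip.
    """
    lines = ["# generated by dres"]
    next_id = 1
    if morph.soma is not None:
        r = morph.soma.radius_um
        lines.append(f"1 {SOMA} 0 0 0 {r:.6g} -1")
        next_id = 2
    roots, ch = morph.children()
    tail = {}
    order = roots + [i for i in range(len(morph.sections))
                     if morph.sections[i].parent != -1]
    # direction per section: spread root branches in the xy plane
    angles = {}
    for n, i in enumerate(roots):
        angles[i] = 2 * np.pi * n / max(len(roots), 1)
    pos = {}
    for i in order:
        s = morph.sections[i]
        if s.parent == -1:
            start = np.zeros(3)
            ang = angles[i]
            par_id = 1 if morph.soma is not None else -1
        else:
            start, ang, par_id = pos[s.parent]
            ang += (0.3 if (ch[s.parent].index(i) % 2) else -0.3)
        npts = max(2, int(round(s.length_um / 20.0)) + 1)
        direction = np.array([np.cos(ang), np.sin(ang), 0.0])
        j0 = 0 if s.parent == -1 else 1   # roots carry their proximal point
        for j in range(j0, npts):
            t = j / (npts - 1)
            xyz = start + direction * s.length_um * t
            rad = s.diam_at(t) / 2.0
            lines.append(f"{next_id} {DEND} {xyz[0]:.9g} {xyz[1]:.9g} "
                         f"{xyz[2]:.9g} {rad:.9g} {par_id}")
            par_id = next_id
            next_id += 1
        pos[i] = (start + direction * s.length_um, ang, par_id)
        tail[i] = par_id
    Path(path).write_text("\n".join(lines) + "\n")
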