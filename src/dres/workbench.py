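"""Shared plumbing: config schema, frozen fixtures, reports, manifests.

Configs are flat TOML with ``[membrane]``, ``[membrane.klt]``, optional
``[membrane_distal]`` (gradient overrides) and ``[cable]`` tables; every
numeric field carries the internal units documented in :mod:`dres.units`.
The frozen reference sets ship inside the package and are loaded through
:func:`reference_patch` and friends.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import sys
import tomllib
from importlib import resources
from pathlib import Path

import numpy as np

from .cable import CableSpec
from .membrane import KLTKinetics, MembraneSpec
from .tree import Morphology, Section


class ConfigError(ValueError):
    pass


_MEMBRANE_FIELDS = {f.name for f in dataclasses.fields(MembraneSpec)} - {"klt"}
_KLT_FIELDS = {f.name for f in dataclasses.fields(KLTKinetics)}


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

def membrane_from_dict(d: dict) -> MembraneSpec:
    klt_d = dict(d.get("klt", {}))
    bad = set(klt_d) - _KLT_FIELDS
    if bad:
        raise ConfigError(f"unknown [membrane.klt] keys: {sorted(bad)}")
    scalars = {k: v for k, v in d.items() if k != "klt"}
    bad = set(scalars) - _MEMBRANE_FIELDS
    if bad:
        raise ConfigError(f"unknown [membrane] keys: {sorted(bad)}")
    ints = {"p", "q"}
    klt = KLTKinetics(**{k: (int(v) if k in ints else float(v))
                         for k, v in klt_d.items()})
    return MembraneSpec(klt=klt, **{k: float(v) for k, v in scalars.items()})


def membrane_to_dict(m: MembraneSpec) -> dict:
    d = {k: getattr(m, k) for k in sorted(_MEMBRANE_FIELDS)}
    d["klt"] = {k: getattr(m.klt, k) for k in sorted(_KLT_FIELDS)}
    return d


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def parse_model(cfg: dict):
    """(CableSpec | Morphology) from a parsed config dict.

    A finite ``[cable]`` (or a ``[membrane_distal]`` gradient) yields a
    single-section :class:`Morphology`; an infinite cable a
    :class:`CableSpec`.
    """
    if "membrane" not in cfg:
        raise ConfigError("config needs a [membrane] table")
    mem = membrane_from_dict(cfg["membrane"])
    cab = dict(cfg.get("cable", {}))
    diam = float(cab.get("diam_um", 2.0))
    r_a = float(cab.get("r_a", 150.0))
    length = float(cab.get("length_um", math.inf))
    distal = None
    if "membrane_distal" in cfg:
        over = dict(cfg["membrane_distal"])
        klt_over = {f"klt_{k}": v for k, v in over.pop("klt", {}).items()}
        distal = mem.with_updates(**over, **klt_over)
    if math.isinf(length):
        if distal is not None:
            raise ConfigError("a semi-infinite cable cannot carry a gradient")
        return CableSpec(diam_um=diam, r_a=r_a, membrane=mem)
    sec = Section(length_um=length, diam_um=diam, r_a=r_a,
                  membrane=mem, membrane_distal=distal)
    return Morphology(sections=[sec])


def _toml_scalar(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return "inf" if math.isinf(v) else repr(float(v))
    raise ConfigError(f"cannot serialize {type(v)} to TOML")


def dump_config(cfg: dict, path) -> None:
    """Write a (nested-dict, scalar-leaf) config as TOML."""
    lines = []

    def table(prefix, d):
        scalars = {k: v for k, v in d.items() if not isinstance(v, dict)}
        subs = {k: v for k, v in d.items() if isinstance(v, dict)}
        if prefix:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_scalar(v)}")
        lines.append("")
        for k, v in subs.items():
            table(f"{prefix}.{k}" if prefix else k, v)

    table("", cfg)
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# frozen fixtures
# ---------------------------------------------------------------------------

def _packaged(name: str) -> dict:
    with resources.files("dres.params").joinpath(name).open("rb") as fh:
        return tomllib.load(fh)


def reference_patch() -> MembraneSpec:
    """The frozen calibrated KLT + leak + static-H membrane patch."""
    return membrane_from_dict(_packaged("reference_patch.toml")["membrane"])


def reference_cable() -> CableSpec:
    """Semi-infinite reference cable (d = 2 um, R_a = 150 Ohm*cm)."""
    model = parse_model(_packaged("reference_patch.toml"))
    assert isinstance(model, CableSpec)
    return model


def optimized_cable() -> Morphology:
    """200 um sealed cable, uniform KLT 15 mS/cm^2, leak 0.32 -> 1 mS/cm^2."""
    model = parse_model(_packaged("optimized_cable.toml"))
    assert isinstance(model, Morphology)
    return model


def multipolar_fixture() -> Morphology:
    """Synthetic multipolar (stellate-like) model for the classification demos.

    Constructed, not reconstructed: five dendrites with frozen conductance
    gradients whose transfer-resonance profile brackets the 208/228 Hz
    task bands.
    """
    from .builders import build_multipolar
    return build_multipolar()


def fixture_generate(kind: str, outdir) -> Path:
    """Write a frozen fixture config (or toy SWC) into ``outdir``."""
    from . import builders, swc
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "patch":
        src = _packaged("reference_patch.toml")
        out = outdir / "patch.toml"
        dump_config(src, out)
    elif kind == "cable":
        src = _packaged("optimized_cable.toml")
        out = outdir / "cable.toml"
        dump_config(src, out)
    elif kind in ("ballstick", "bipolar", "y", "multipolar"):
        morph = builders.build(kind)
        out = outdir / f"{kind}.swc"
        swc.write_swc(morph, out)
    elif kind == "toy_swc":
        out = outdir / "toy.swc"
        swc.write_swc(builders.build_y(), out)
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# reports and manifests
# ---------------------------------------------------------------------------

def profile_report(profile, path=None):
    """Stable-column CSV of a spatial profile (units in headers)."""
    df = profile.to_frame()
    if path is not None:
        df.to_csv(path, index=False)
    return df


def manifest(config: dict, seeds=(), extra=None) -> dict:
    """Reproducibility record: config hash, package/python versions, seeds."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    from . import __version__
    man = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "dres_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seeds": list(seeds),
    }
    if extra:
        man.update(extra)
    return man


def write_manifest(man: dict, outdir) -> Path:
    out = Path(outdir) / "manifest.json"
    out.write_text(json.dumps(man, indent=2, sort_keys=True) + "\n")
    return out
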