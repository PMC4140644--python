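"""Single source of truth for units and conversions.

Internal unit system (chosen so that no hidden factors appear in the
membrane equations):

===================  ==========  =============================
quantity             unit        notes
===================  ==========  =============================
voltage              mV
time                 ms
specific capacitance uF/cm^2     C/g gives ms directly
conductance density  mS/cm^2
current density      uA/cm^2     = (mS/cm^2) * mV
specific impedance   kOhm*cm^2   = 1 / (mS/cm^2)
absolute impedance   MOhm
length (morphology)  um
axial resistivity    Ohm*cm
frequency (user)     Hz
angular frequency    rad/ms      omega = 2*pi*f(Hz)*1e-3
===================  ==========  =============================

Every conversion between the user-facing units (Hz, um, Ohm*cm) and the
internal system goes through the constants and helpers below.
"""

from __future__ import annotations

import numpy as np

#: rad/ms per Hz
OMEGA_PER_HZ = 2.0 * np.pi * 1e-3

#: cm per um
CM_PER_UM = 1e-4

#: kOhm*cm^2 -> Ohm*cm^2
OHM_CM2_PER_KOHM_CM2 = 1e3

#: Ohm -> MOhm
MOHM_PER_OHM = 1e-6


def omega(f_hz):
    """Angular frequency in rad/ms for ``f_hz`` in Hz."""
    return OMEGA_PER_HZ * np.asarray(f_hz, dtype=float)


def f_hz_from_rate(rate_per_ms):
    """Convert a rate in 1/ms (e.g. G/C) to an ordinary frequency in Hz."""
    return rate_per_ms * 1e3 / (2.0 * np.pi)


def specific_impedance_ohm_cm2(admittance_ms_cm2):
    """Specific membrane impedance (Ohm*cm^2) from admittance in mS/cm^2."""
    return 1e3 / admittance_ms_cm2


def um_to_cm(x_um):
    return np.asarray(x_um, dtype=float) * CM_PER_UM


def cylinder_area_cm2(diam_um, length_um):
    """Lateral membrane area of a cylinder in cm^2."""
    return np.pi * um_to_cm(diam_um) * um_to_cm(length_um)


def sphere_area_cm2(radius_um):
    """Surface area of a sphere in cm^2."""
    r = um_to_cm(radius_um)
    return 4.0 * np.pi * r * r
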