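"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's analytic cable/tree code paths:
the frequency-domain oracle discretizes the morphology into quasi-active
compartments and solves the linear system per frequency; the state-space
oracle linearizes the point-membrane ODE by finite differences and reads
the admittance off the resolvent.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from dres import units
from dres.membrane import MembraneSpec, nonlinear_rhs, resting_state
from dres.simulator import CompartmentalSystem


def state_space_admittance(spec: MembraneSpec, f_hz):
    """Admittance (mS/cm^2) from the linearized (V, w, z) system.

    The Jacobian is obtained by central finite differences of the
    nonlinear right-hand side at rest; Y(f) = 1 / [e_V (i w I - J)^-1 B]
    with B the voltage row of the input vector.
    """
    op = resting_state(spec)
    x0 = np.array([op.v_rest, op.w_inf, op.z_inf])
    eps = np.array([1e-6, 1e-9, 1e-9])

    def rhs(x):
        return np.array(nonlinear_rhs(spec, x[0], x[1], x[2], 0.0))

    jac = np.empty((3, 3))
    for j in range(3):
        dx = np.zeros(3)
        dx[j] = eps[j]
        jac[:, j] = (rhs(x0 + dx) - rhs(x0 - dx)) / (2 * eps[j])
    b = np.array([1.0 / spec.c_m, 0.0, 0.0])   # response to unit current density
    out = []
    for f in np.atleast_1d(f_hz):
        w = units.omega(f)
        v = np.linalg.solve(1j * w * np.eye(3) - jac, b)[0]
        out.append(1.0 / v)
    return np.array(out)


def _compartment_operating_points(sys: CompartmentalSystem):
    ops = []
    cache = {}
    for i in range(sys.n):
        key = (sys.g_l[i], sys.e_l[i], sys.g_h[i], sys.e_h[i], sys.gbar[i])
        if key not in cache:
            import dataclasses
            mem = MembraneSpec(c_m=sys.c_m[i], g_l=sys.g_l[i], e_l=sys.e_l[i],
                               g_h=sys.g_h[i], e_h=sys.e_h[i],
                               klt=dataclasses.replace(sys.kinetics,
                                                       gbar=sys.gbar[i]))
            cache[key] = resting_state(mem)
        ops.append(cache[key])
    return ops


def freq_domain_transfer(sys: CompartmentalSystem, f_hz, inject: int,
                         record=None, mode: str = "full"):
    """Transfer impedance (MOhm) of the discretized quasi-active system.

    Assembles the complex conductance matrix per frequency (membrane
    admittance times area on the diagonal plus the axial coupling graph)
    and solves for the voltage response to a unit current at ``inject``.
    ``record=None`` returns the full voltage vector (useful for
    reciprocity checks); an integer returns that compartment's K(f).
    """
    ops = _compartment_operating_points(sys)
    n = sys.n
    rows_p = np.arange(1, n)
    cols_p = sys.parent[1:]
    out = []
    for f in np.atleast_1d(f_hz):
        y_diag = np.array([op.admittance(f, mode=mode) for op in ops]) * sys.area_cm2
        diag = y_diag.astype(complex)
        diag[1:] += sys.g_par[1:]
        np.add.at(diag, cols_p, sys.g_par[1:])
        data = np.concatenate([diag, -sys.g_par[1:], -sys.g_par[1:]])
        rows = np.concatenate([np.arange(n), rows_p, cols_p])
        cols = np.concatenate([np.arange(n), cols_p, rows_p])
        a = csc_matrix((data, (rows, cols)), shape=(n, n))
        rhs = np.zeros(n, complex)
        rhs[inject] = 1.0               # 1 uA
        v = splu(a).solve(rhs)          # mV per uA = kOhm
        out.append(v * 1e-3)            # MOhm
    arr = np.array(out)                 # (n_f, n)
    if record is None:
        return arr
    return arr[:, record]
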