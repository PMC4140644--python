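"""Finite cables with lumped boundaries and tree collapse."""

import numpy as np
import pytest

from dres.cable import CableSpec, characteristic_impedance
from dres.membrane import resonance_of
from dres.simulator import CompartmentalSystem
from dres.tree import (LumpedBoundary, Morphology, Section, Soma, TreeError,
                       collapse_tree, finite_input_impedance, parallel,
                       spatial_profile_tree, transfer_finite)

from oracles import freq_domain_transfer

F = np.geomspace(2.0, 1000.0, 30)


@pytest.fixture(scope="module")
def finite_ref(ref_cable):
    return CableSpec(diam_um=ref_cable.diam_um, r_a=ref_cable.r_a,
                     length_um=200.0, membrane=ref_cable.membrane)


class TestFiniteInputImpedance:
    def test_matched_termination_is_semi_infinite(self, finite_ref, ref_op):
        zc = characteristic_impedance(finite_ref, F, op=ref_op)
        z_in = finite_input_impedance(finite_ref, F, z_term=zc, op=ref_op)
        np.testing.assert_allclose(z_in, zc, rtol=1e-12)

    def test_sealed_long_cable_approaches_semi_infinite(self, ref_cable, ref_op):
        cab = CableSpec(diam_um=ref_cable.diam_um, r_a=ref_cable.r_a,
                        length_um=30000.0, membrane=ref_cable.membrane)
        zc = characteristic_impedance(cab, F, op=ref_op)
        z_in = finite_input_impedance(cab, F, z_term=None, op=ref_op)
        np.testing.assert_allclose(z_in, zc, rtol=1e-9)

    def test_sealed_200um_matches_compartmental_oracle(self, finite_ref, ref_op):
        sys_ = CompartmentalSystem.from_morphology(
            Morphology(sections=[Section(length_um=200.0,
                                         diam_um=finite_ref.diam_um,
                                         r_a=finite_ref.r_a,
                                         membrane=finite_ref.membrane)]),
            dx_um=0.5)
        z_ora = freq_domain_transfer(sys_, F, inject=0, record=0)
        z_ana = finite_input_impedance(finite_ref, F, op=ref_op)
        np.testing.assert_allclose(np.abs(z_ana), np.abs(z_ora), rtol=5e-3)


class TestTransferFinite:
    def test_x_zero_equals_input_impedance(self, finite_ref, ref_op):
        np.testing.assert_allclose(
            transfer_finite(finite_ref, 0.0, F, op=ref_op),
            finite_input_impedance(finite_ref, F, op=ref_op), rtol=1e-12)

    def test_out_of_range_position_raises(self, finite_ref):
        with pytest.raises(TreeError):
            transfer_finite(finite_ref, 250.0, F)

    def test_reciprocity_against_oracle(self, finite_ref, ref_op):
        """K(x -> 0) equals K(0 -> x); the oracle solves both directions."""
        sys_ = CompartmentalSystem.from_morphology(
            Morphology(sections=[Section(length_um=200.0,
                                         diam_um=finite_ref.diam_um,
                                         r_a=finite_ref.r_a,
                                         membrane=finite_ref.membrane)]),
            dx_um=2.0)
        i_x = sys_.locate(0, 120.0)
        x_actual = sys_.positions[i_x][1]
        f = np.geomspace(5, 800, 12)
        k_fwd = freq_domain_transfer(sys_, f, inject=i_x, record=0)
        k_bwd = freq_domain_transfer(sys_, f, inject=0, record=i_x)
        np.testing.assert_allclose(k_fwd, k_bwd, rtol=1e-10)
        k_ana = transfer_finite(finite_ref, x_actual, f, op=ref_op)
        np.testing.assert_allclose(np.abs(k_ana), np.abs(k_fwd), rtol=0.01)


class TestCollapse:
    def test_single_section_tree_equals_transfer_finite(self, finite_ref, ref_op):
        m = Morphology(sections=[Section(length_um=200.0,
                                         diam_um=finite_ref.diam_um,
                                         r_a=finite_ref.r_a,
                                         membrane=finite_ref.membrane)])
        tt = collapse_tree(m, F)
        for x in (0.0, 60.0, 200.0):
            np.testing.assert_allclose(
                tt.transfer(0, x),
                transfer_finite(finite_ref, x, F, op=ref_op), rtol=1e-9)

    def test_symmetric_y_obeys_rall_equivalent_cylinder(self, ref_membrane):
        """Daughters satisfying the 3/2-power rule collapse onto a single
        cylinder whose electrotonic length adds the mapped daughter length."""
        d_p = 2.0
        d_d = (d_p ** 1.5 / 2.0) ** (2.0 / 3.0)
        lp, ld = 120.0, 90.0
        y = Morphology(sections=[
            Section(length_um=lp, diam_um=d_p, membrane=ref_membrane),
            Section(length_um=ld, diam_um=d_d, membrane=ref_membrane, parent=0),
            Section(length_um=ld, diam_um=d_d, membrane=ref_membrane, parent=0)])
        l_equiv = lp + ld * np.sqrt(d_p / d_d)
        eq = Morphology(sections=[
            Section(length_um=l_equiv, diam_um=d_p, membrane=ref_membrane)])
        z_y = collapse_tree(y, F).input_impedance()
        z_eq = collapse_tree(eq, F).input_impedance()
        np.testing.assert_allclose(z_y, z_eq, rtol=1e-6)

    def test_ballstick_matches_compartmental_oracle(self, ref_membrane):
        m = Morphology(
            sections=[Section(length_um=200.0, diam_um=2.0,
                              membrane=ref_membrane)],
            soma=Soma(radius_um=8.0, membrane=ref_membrane))
        sys_ = CompartmentalSystem.from_morphology(m, dx_um=1.0)
        tt = collapse_tree(m, F)
        i_x = sys_.locate(0, 150.0)
        x = sys_.positions[i_x][1]
        k_ora = freq_domain_transfer(sys_, F, inject=i_x, record=0)
        np.testing.assert_allclose(np.abs(tt.transfer(0, x)), np.abs(k_ora),
                                   rtol=0.01)

    def test_collapse_invariant_under_sibling_order(self, ref_membrane):
        def make(order):
            lengths = {0: 150.0, 1: 200.0, 2: 120.0}
            diams = {0: 2.0, 1: 1.5, 2: 1.0}
            secs = [Section(length_um=lengths[i], diam_um=diams[i],
                            membrane=ref_membrane) for i in order]
            return Morphology(sections=secs,
                              soma=Soma(radius_um=8.0, membrane=ref_membrane))
        z1 = collapse_tree(make([0, 1, 2]), F).input_impedance()
        z2 = collapse_tree(make([2, 0, 1]), F).input_impedance()
        np.testing.assert_allclose(z1, z2, rtol=1e-12)

    def test_parallel_combination_commutes(self):
        rng = np.random.default_rng(7)
        z1 = rng.normal(size=8) + 1j * rng.normal(size=8)
        z2 = rng.normal(size=8) + 1j * rng.normal(size=8)
        np.testing.assert_allclose(parallel(z1, z2), parallel(z2, z1))
        np.testing.assert_allclose(parallel(z1, None), z1)

    def test_gradient_refinement_converged_at_default(self, fig3_cable):
        p1 = spatial_profile_tree(fig3_cable, positions=[(0, 0.0), (0, 100.0),
                                                         (0, 200.0)],
                                  seg_len_um=5.0)
        p2 = spatial_profile_tree(fig3_cable, positions=[(0, 0.0), (0, 100.0),
                                                         (0, 200.0)],
                                  seg_len_um=2.5)
        assert np.max(np.abs(p1.f_r_hz - p2.f_r_hz)) < 0.2


# ---------------------------------------------------------------------------
# boundary-condition phenomenology
# ---------------------------------------------------------------------------

def _lump_set(ref_membrane):
    """Constructed resonant lumps spanning roughly 150-420 Hz.

    The area is chosen so the lump impedance is comparable to the
    reference cable's characteristic impedance near its resonance;
    otherwise every lump degenerates to an effectively sealed (or
    shorted) end and its tuning becomes irrelevant.
    """
    area = 4e-5   # cm^2
    lumps = []
    for scale in (0.35, 0.6, 1.0, 1.4, 1.9):
        mem = ref_membrane.with_updates(g_h=ref_membrane.g_h * scale,
                                        klt_gbar=ref_membrane.klt.gbar * scale)
        lumps.append(LumpedBoundary.membrane_patch(mem, area))
    return lumps


class TestBoundaryConditions:
    @pytest.fixture(scope="class")
    def lumps(self, ref_membrane):
        return _lump_set(ref_membrane)

    def test_lump_set_spans_printed_resonance_range(self, lumps):
        frs = [resonance_of(lambda f: lump(f)).f_r for lump in lumps]
        assert min(frs) < 170.0
        assert max(frs) > 400.0

    @pytest.mark.parametrize("length_um,lo,hi", [(75.0, 25.0, np.inf),
                                                 (300.0, 0.0, 15.0)])
    def test_lump_influence_depends_on_segment_length(self, ref_cable, ref_op,
                                                      lumps, length_um, lo, hi):
        """A resonant tip lump re-tunes a short segment end to end (tens of
        Hz at the far, proximal end) while a long segment is shielded by
        cable attenuation (frozen thresholds: > 25 Hz at 75 um, < 15 Hz at
        300 um, measured at x = 0 against the matched-termination control)."""
        cab = CableSpec(diam_um=ref_cable.diam_um, r_a=ref_cable.r_a,
                        length_um=length_um, membrane=ref_cable.membrane)
        control = resonance_of(lambda f: transfer_finite(
            cab, 0.0, f, z_term=characteristic_impedance(cab, f, op=ref_op),
            op=ref_op)).f_r
        max_shift = max(abs(resonance_of(lambda f: transfer_finite(
            cab, 0.0, f, z_term=lump(f), op=ref_op)).f_r - control)
            for lump in lumps)
        assert lo < max_shift < hi

    def test_soma_lump_shifts_entire_profile(self, ref_cable, ref_membrane):
        """A detuned resonant soma re-tunes even the distal end of a long
        segment, unlike a tip lump (frozen threshold: > 10 Hz everywhere)."""
        sec = Section(length_um=300.0, diam_um=ref_cable.diam_um,
                      r_a=ref_cable.r_a, membrane=ref_cable.membrane)
        soma_mem = ref_membrane.with_updates(
            g_h=ref_membrane.g_h * 0.5, klt_gbar=ref_membrane.klt.gbar * 0.5)
        plain = spatial_profile_tree(Morphology(sections=[sec]),
                                     positions=[(0, 150.0), (0, 300.0)])
        with_soma = spatial_profile_tree(
            Morphology(sections=[sec],
                       soma=Soma(radius_um=12.0, membrane=soma_mem)),
            positions=[(0, 150.0), (0, 300.0)])
        assert np.all(np.abs(with_soma.f_r_hz - plain.f_r_hz) > 10.0)

    def test_q_profile_less_sensitive_than_frequency_profile(self, ref_cable,
                                                             ref_op, lumps):
        """Across the boundary set, Q(x) spreads far less than f_R(x)."""
        cab = CableSpec(diam_um=ref_cable.diam_um, r_a=ref_cable.r_a,
                        length_um=150.0, membrane=ref_cable.membrane)
        f_rs, qs = [], []
        for lump in lumps:
            met = resonance_of(lambda f: transfer_finite(cab, 75.0, f,
                                                         z_term=lump(f),
                                                         op=ref_op))
            f_rs.append(met.f_r)
            if met.q is not None:
                qs.append(met.q)
        assert len(qs) >= 3   # the most detuned lump may blunt the peak
        rel_spread = lambda v: (max(v) - min(v)) / np.mean(v)
        assert rel_spread(qs) < rel_spread(f_rs)
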