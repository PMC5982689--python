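"""Serpentine-spring stiffness: closed-form energy method vs the space-frame
finite-element oracle, section properties, and the calibrated default."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gripsim as gs
from gripsim.config import BeamSegment, SuspensionModel
from gripsim.springs import (LoadCase, beam_matrix_oracle, castigliano_stiffness,
                             section_properties, strain_energy, tip_compliance,
                             torsion_constant)

E_POLY, NU_POLY = 160e9, 0.23


def serpentine(n_long=6, L_long=100e-6, L_link=20e-6, b=8.043248e-6, h=2.5e-6):
    segs = []
    for i in range(n_long):
        ax = (1.0, 0.0, 0.0) if i % 2 == 0 else (-1.0, 0.0, 0.0)
        segs.append(BeamSegment(L=L_long, b=b, h=h, axis=ax))
        if i < n_long - 1:
            segs.append(BeamSegment(L=L_link, b=b, h=h, axis=(0.0, 1.0, 0.0)))
    return segs


class TestSectionProperties:
    def test_square_torsion_constant(self):
        """J/h^4 = 0.1406 for a square section (classical value)."""
        h = 3e-6
        sec = section_properties(h, h, series_terms=12)
        assert sec.J / h**4 == pytest.approx(0.1406, abs=1e-4)
        # truncation: 12 terms agree with a very deep series evaluation
        assert sec.J == pytest.approx(torsion_constant(h, h, 400), rel=1e-9)

    def test_thin_strip_limit(self):
        b, h = 1e-3, 1e-6
        sec = section_properties(b, h, 30)
        assert sec.J == pytest.approx(b * h**3 / 3.0, rel=1e-3)

    def test_bending_inertias_exact(self):
        sec = section_properties(2e-6, 1e-6, 12)
        assert sec.I_outplane == pytest.approx(2e-6 * 1e-18 / 12, rel=1e-15)
        assert sec.I_inplane == pytest.approx(1e-6 * 8e-18 / 12, rel=1e-15)
        assert sec.A == pytest.approx(2e-12, rel=1e-15)

    def test_torsion_constant_symmetric_under_swap(self):
        assert torsion_constant(2e-6, 1e-6, 200) == pytest.approx(
            torsion_constant(1e-6, 2e-6, 200), rel=1e-8
        )


class TestStrainEnergy:
    def test_zero_load_zero_energy(self):
        assert strain_energy(serpentine(), LoadCase(), E_POLY, NU_POLY) == 0.0

    def test_cantilever_pure_moment_textbook(self):
        """Single beam under tip moment Mz: U = Mz^2 L / (2EI), θ = Mz L / EI."""
        L, b, h, Mz = 200e-6, 4e-6, 2.5e-6, 1e-9
        beam = [BeamSegment(L=L, b=b, h=h, axis=(1.0, 0.0, 0.0))]
        I = h * b**3 / 12  # in-plane bending
        U = strain_energy(beam, LoadCase(Mz=Mz), E_POLY, NU_POLY)
        assert U == pytest.approx(Mz**2 * L / (2 * E_POLY * I), rel=1e-12)
        C = tip_compliance(beam, E_POLY, NU_POLY)
        assert C[5, 5] == pytest.approx(L / (E_POLY * I), rel=1e-12)

    def test_energy_quadratic_in_load(self):
        load = LoadCase(Fx=1e-6, Fy=2e-6, Mz=1e-9)
        double = LoadCase(Fx=2e-6, Fy=4e-6, Mz=2e-9)
        beams = serpentine()
        assert strain_energy(beams, double, E_POLY, NU_POLY) == pytest.approx(
            4 * strain_energy(beams, load, E_POLY, NU_POLY), rel=1e-12
        )


class TestCastigliano:
    def test_single_beam_textbook_stiffnesses(self):
        """A one-segment 'serpentine' reduces to cantilever formulas:
        lateral 3EI/L^3 and axial torsion GJ/L."""
        L, b, h = 300e-6, 3e-6, 2.5e-6
        susp = SuspensionModel(
            mode="castigliano", E=E_POLY, nu_poly=NU_POLY, n_springs=1,
            beams=(BeamSegment(L=L, b=b, h=h, axis=(1.0, 0.0, 0.0)),),
        )
        sec = section_properties(b, h)
        k = castigliano_stiffness(susp)
        assert k.k_Fy == pytest.approx(3 * E_POLY * sec.I_inplane / L**3, rel=1e-12)
        assert k.k_Fz == pytest.approx(3 * E_POLY * sec.I_outplane / L**3, rel=1e-12)
        assert k.k_Fx == pytest.approx(E_POLY * sec.A / L, rel=1e-12)
        G = E_POLY / (2 * (1 + NU_POLY))
        assert k.k_tx == pytest.approx(G * sec.J / L, rel=1e-12)

    def test_parallel_springs_double(self):
        beams = tuple(serpentine())
        one = castigliano_stiffness(SuspensionModel(
            mode="castigliano", E=E_POLY, nu_poly=NU_POLY, beams=beams, n_springs=1))
        two = castigliano_stiffness(SuspensionModel(
            mode="castigliano", E=E_POLY, nu_poly=NU_POLY, beams=beams, n_springs=2))
        for name in ("k_tz", "k_tx", "k_Fx", "k_Fy", "k_Fz"):
            assert getattr(two, name) == pytest.approx(
                2 * getattr(one, name), rel=1e-12)

    def test_description_invariance_split_segment(self):
        """Splitting one beam into two collinear halves changes nothing."""
        whole = serpentine()
        split = []
        for seg in whole:
            split.append(BeamSegment(L=seg.L / 2, b=seg.b, h=seg.h, axis=seg.axis))
            split.append(BeamSegment(L=seg.L / 2, b=seg.b, h=seg.h, axis=seg.axis))
        k1 = castigliano_stiffness(SuspensionModel(
            mode="castigliano", E=E_POLY, nu_poly=NU_POLY, beams=tuple(whole)))
        k2 = castigliano_stiffness(SuspensionModel(
            mode="castigliano", E=E_POLY, nu_poly=NU_POLY, beams=tuple(split)))
        for name in ("k_tz", "k_tx", "k_Fx", "k_Fy", "k_Fz"):
            assert getattr(k1, name) == pytest.approx(getattr(k2, name), rel=1e-10)

    def test_default_geometry_reproduces_published_k_tz(self, serpentine_scenario):
        k = gs.suspension_stiffness(serpentine_scenario.suspension)
        assert k.k_tz == pytest.approx(4.9557e-8, rel=5e-3)


class TestOracleAgreement:
    @pytest.mark.parametrize("n_long,L_long,L_link,b,h", [
        (4, 120e-6, 25e-6, 4e-6, 2.5e-6),
        (6, 100e-6, 20e-6, 8e-6, 2.5e-6),
        (8, 80e-6, 15e-6, 3e-6, 6e-6),
    ])
    def test_all_five_stiffnesses_match(self, n_long, L_long, L_link, b, h):
        beams = serpentine(n_long, L_long, L_link, b, h)
        susp = SuspensionModel(mode="castigliano", E=E_POLY, nu_poly=NU_POLY,
                               beams=tuple(beams), n_springs=1)
        k = castigliano_stiffness(susp)
        for comp, name in ((0, "k_Fx"), (1, "k_Fy"), (2, "k_Fz"),
                           (3, "k_tx"), (5, "k_tz")):
            load = np.zeros(6)
            load[comp] = 1e-9
            u = beam_matrix_oracle(beams, LoadCase(*load), E_POLY, NU_POLY, n_elem=4)
            assert 1e-9 / u[comp] == pytest.approx(
                getattr(k, name), rel=0.02), name

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n_long=st.integers(3, 7),
        L_long=st.floats(60e-6, 200e-6),
        ratio=st.floats(0.1, 0.3),
        b=st.floats(2e-6, 6e-6),
        h=st.floats(2e-6, 6e-6),
    )
    def test_randomized_slender_serpentines(self, n_long, L_long, ratio, b, h):
        beams = serpentine(n_long, L_long, max(ratio * L_long, 10 * max(b, h)), b, h)
        susp = SuspensionModel(mode="castigliano", E=E_POLY, nu_poly=NU_POLY,
                               beams=tuple(beams), n_springs=1)
        k = castigliano_stiffness(susp)
        for comp, name in ((0, "k_Fx"), (1, "k_Fy"), (2, "k_Fz"),
                           (3, "k_tx"), (5, "k_tz")):
            load = np.zeros(6)
            load[comp] = 1e-9
            u = beam_matrix_oracle(beams, LoadCase(*load), E_POLY, NU_POLY, n_elem=2)
            assert 1e-9 / u[comp] == pytest.approx(getattr(k, name), rel=0.02), name


class TestOracle:
    def test_axial_bar(self):
        L, b, h = 100e-6, 4e-6, 4e-6
        beams = [BeamSegment(L=L, b=b, h=h, axis=(1.0, 0.0, 0.0))]
        u = beam_matrix_oracle(beams, LoadCase(Fx=1e-6), E_POLY, NU_POLY, n_elem=1)
        assert u[0] == pytest.approx(1e-6 * L / (E_POLY * b * h), rel=1e-12)

    def test_reciprocity(self):
        beams = serpentine()
        C = np.zeros((6, 6))
        for i in range(6):
            q = np.zeros(6)
            q[i] = 1e-9
            C[:, i] = beam_matrix_oracle(beams, LoadCase(*q), E_POLY, NU_POLY,
                                         n_elem=2) / 1e-9
        # scale-aware symmetry: compare against the compliance's own scale,
        # sqrt(C_ii C_jj), since exact-zero cross terms carry solver noise
        scale = np.sqrt(np.outer(np.diag(C), np.diag(C)))
        np.testing.assert_array_less(np.abs(C - C.T), 1e-10 * scale)

    def test_mesh_refinement_converged(self):
        beams = serpentine()
        load = LoadCase(Fy=1e-9, Mz=1e-12)
        u32 = beam_matrix_oracle(beams, load, E_POLY, NU_POLY, n_elem=32)
        u64 = beam_matrix_oracle(beams, load, E_POLY, NU_POLY, n_elem=64)
        np.testing.assert_allclose(u64, u32, rtol=1e-3)


class TestReactionTorque:
    def test_zero_rotation(self):
        assert gs.reaction_torque(4.9557e-8, 0.0) == 0.0

    def test_published_stiffness_at_squeeze_angle(self):
        """k_tz = 49,557 uN um/rad at θ_z = 0.0016 rad gives 79.29 uN um."""
        ts = gs.reaction_torque(4.9557e-8, 0.0016)
        assert ts / 1e-12 == pytest.approx(79.2912, rel=1e-12)

    def test_linear(self):
        assert gs.reaction_torque(2.0, 0.3) == pytest.approx(
            3 * gs.reaction_torque(2.0, 0.1), rel=1e-14)
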