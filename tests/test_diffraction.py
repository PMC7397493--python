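"""Reflection generation, electron structure factors, normalization and
the twinning L-test, each checked against an independent oracle."""

import itertools

import numpy as np
import pytest

from microshred.diffraction import (
    ReflectionSet, FormFactorTable, UnknownElementError,
    electron_form_factor, generate_reflections, structure_factors,
    normalize_E, l_test, write_reflections_tsv, read_reflections,
    orthogonalization_matrix,
)
from microshred.symmetry import SpaceGroupInfo, SpaceGroupError
from conftest import random_blob

# Peng neutral-atom 5-Gaussian coefficients for carbon (International
# Tables C, table 4.3.2.2) — independent of the implementation's table
CARBON_A = [0.0893, 0.2563, 0.7570, 1.0487, 0.3575]
CARBON_B = [0.2465, 1.7100, 6.4094, 18.6113, 50.2523]


class TestGenerateReflections:
    def test_p1_cubic_matches_brute_force(self):
        refl = generate_reflections((10, 10, 10, 90, 90, 90), "P1", 5.0)
        oracle = set()
        for h in itertools.product(range(-2, 3), repeat=3):
            if h == (0, 0, 0):
                continue
            if 10.0 / np.linalg.norm(h) >= 5.0:
                oracle.add(max(h, tuple(-x for x in h)))
        assert refl.n == len(oracle)
        assert set(map(tuple, refl.hkl)) == oracle

    def test_p43212_screw_absences(self):
        refl = generate_reflections((20, 20, 30, 90, 90, 90), "P43212", 3.0)
        got = set(map(tuple, refl.hkl))
        # 00l present only for l = 4n (4_3 screw), h00 only for h = 2n
        assert (0, 0, 4) in got and (0, 0, 2) not in got
        assert (2, 0, 0) in got and (0, 0, 1) not in got

    def test_degenerate_range_is_not_an_error(self):
        refl = generate_reflections((10, 10, 10, 90, 90, 90), "P1", 5.0, 5.0)
        assert refl.n >= 0
        if refl.n:
            np.testing.assert_allclose(refl.d(), 5.0)

    def test_unknown_spacegroup_lists_supported(self):
        with pytest.raises(SpaceGroupError, match="P43212"):
            generate_reflections((10, 10, 10, 90, 90, 90), "C2", 3.0)

    def test_resolution_bounds_respected(self):
        refl = generate_reflections((15, 17, 19, 90, 90, 90), "P212121",
                                    2.0, 8.0)
        d = refl.d()
        assert d.min() >= 2.0 - 1e-9 and d.max() <= 8.0 + 1e-9
        assert not refl.sg_info.systematically_absent(refl.hkl).any()


class TestFormFactors:
    def test_carbon_against_published_coefficients(self):
        for s in (0.0, 0.2, 0.5, 1.0):
            expected = sum(a * np.exp(-b * s * s)
                           for a, b in zip(CARBON_A, CARBON_B))
            assert electron_form_factor("C", s) == pytest.approx(
                expected, rel=1e-6)

    def test_strictly_decreasing(self):
        s = np.linspace(0.0, 1.5, 40)
        for el in ("C", "N", "O", "S", "Ca"):
            f = electron_form_factor(el, s)
            assert np.all(np.diff(f) < 0)

    def test_unknown_element_raises(self):
        with pytest.raises(UnknownElementError):
            electron_form_factor("Xq", 0.1)

    def test_custom_table_override(self):
        table = FormFactorTable({"C": ([1.0] * 5, [1.0] * 5)})
        assert electron_form_factor("C", 0.0, table) == pytest.approx(5.0)


class TestStructureFactors:
    def test_single_atom_at_origin_real_positive(self):
        m = random_blob(1, seed=0)
        m.xyz[:] = 0.0
        m.b_factor[:] = 0.0
        m.occ[:] = 1.0
        m.element[:] = "C"
        refl = generate_reflections((10, 10, 10, 90, 90, 90), "P1", 2.0)
        fc = structure_factors(m, refl)
        np.testing.assert_allclose(fc.phase % 360.0, 0.0, atol=1e-6)
        np.testing.assert_allclose(
            fc.F, electron_form_factor("C", fc.stol()), rtol=1e-12)

    def test_inversion_pair_real(self):
        m = random_blob(2, seed=1)
        m.element[:] = "N"
        m.occ[:] = 1.0
        m.b_factor[:] = 4.0
        m.xyz[0] = [2.0, 1.0, 3.0]
        m.xyz[1] = [-2.0, -1.0, -3.0]
        refl = generate_reflections((12, 12, 12, 90, 90, 90), "P1", 2.5)
        fc = structure_factors(m, refl)
        phases = np.deg2rad(fc.phase)
        np.testing.assert_allclose(np.abs(np.sin(phases)), 0.0, atol=1e-10)

    def test_p212121_matches_naive_oracle(self):
        cell = (15.0, 18.0, 22.0, 90, 90, 90)
        m = random_blob(10, seed=1, extent=12.0)
        refl = generate_reflections(cell, "P212121", 2.5)
        refl = refl.subset(np.arange(50))
        fc = structure_factors(m, refl)
        F = _naive_structure_factors(m, refl)
        np.testing.assert_allclose(fc.F, np.abs(F), rtol=1e-6)
        phase_diff = np.abs(np.exp(1j * np.deg2rad(fc.phase))
                            - F / np.abs(F))
        assert phase_diff.max() < 1e-6

    def test_linear_in_occupancy_and_friedel(self):
        cell = (14.0, 14.0, 20.0, 90, 90, 90)
        m = random_blob(6, seed=3, extent=10.0)
        refl = generate_reflections(cell, "P21", 3.0)
        fc1 = structure_factors(m, refl)
        half = m.copy()
        half.occ = m.occ * 0.5
        fc2 = structure_factors(half, refl)
        np.testing.assert_allclose(fc2.F, 0.5 * fc1.F, rtol=1e-10)

    def test_origin_shift_moves_phases_not_amplitudes(self):
        cell = (16.0, 16.0, 24.0, 90, 90, 90)
        m = random_blob(8, seed=4, extent=10.0)
        refl = generate_reflections(cell, "P212121", 3.0)
        fc = structure_factors(m, refl)
        shifted = m.copy()
        M = orthogonalization_matrix(cell)
        shifted.xyz = m.xyz + np.array([0.5, 0.5, 0.0]) @ M.T
        fc2 = structure_factors(shifted, refl)
        np.testing.assert_allclose(fc2.F, fc.F, rtol=1e-8)
        expected = (fc.phase - 360.0 * (refl.hkl @ [0.5, 0.5, 0.0])) % 360.0
        np.testing.assert_allclose(
            np.exp(1j * np.deg2rad(fc2.phase)),
            np.exp(1j * np.deg2rad(expected)), atol=1e-8)


def _naive_structure_factors(model, refl):
    """Direct python-loop sum over all symmetry copies of all atoms."""
    sg = SpaceGroupInfo(refl.spacegroup)
    M = orthogonalization_matrix(refl.cell)
    frac = model.xyz @ np.linalg.inv(M).T
    stol = refl.stol()
    table = FormFactorTable()
    F = np.zeros(refl.n, dtype=complex)
    for i in range(refl.n):
        h = refl.hkl[i]
        for R, t in zip(sg.rotations, sg.translations):
            pos = frac @ R.astype(float).T + t
            for j in range(model.n_atoms):
                f = electron_form_factor(model.element[j], stol[i], table)
                F[i] += (model.occ[j] * f
                         * np.exp(-model.b_factor[j] * stol[i] ** 2)
                         * np.exp(2j * np.pi * np.dot(h, pos[j])))
    return F


class TestNormalizeE:
    def test_constant_intensities_give_unit_E(self):
        refl = generate_reflections((12, 12, 12, 90, 90, 90), "P1", 2.0)
        refl.I = np.full(refl.n, 7.5)
        ne = normalize_E(refl, n_shells=5)
        np.testing.assert_allclose(ne.E, 1.0, atol=1e-12)

    def test_per_shell_second_moment_exact(self, rng):
        refl = generate_reflections((18, 20, 24, 90, 90, 90), "P212121", 2.2)
        refl.I = rng.exponential(50.0, refl.n) * (1.0 + refl.stol())
        ne = normalize_E(refl, n_shells=10)
        from microshred.diffraction import _equal_count_shells
        shell = _equal_count_shells(np.square(ne.stol()), 10)
        for i in range(10):
            assert np.mean(ne.E[shell == i] ** 2) == pytest.approx(
                1.0, abs=1e-12)

    def test_wilson_tail_fraction(self, rng):
        # acentric Wilson statistics: P(|E| > 2) = exp(-4)
        refl = generate_reflections((40, 42, 44, 90, 90, 90), "P1", 2.4)
        refl.I = rng.exponential(1.0, refl.n)
        ne = normalize_E(refl, n_shells=10)
        frac = np.mean(ne.E > 2.0)
        assert frac == pytest.approx(np.exp(-4.0), abs=0.006)


class TestLTest:
    def test_untwinned_moments(self, rng):
        refl = generate_reflections((40, 42, 44, 90, 90, 90), "P1", 2.6)
        refl.I = rng.exponential(1.0, refl.n)
        res = l_test(refl)
        assert res.mean_abs_l == pytest.approx(0.5, abs=0.02)
        assert res.mean_l2 == pytest.approx(1.0 / 3.0, abs=0.02)
        assert not res.twinned

    def test_perfect_twin_moments(self, rng):
        refl = generate_reflections((40, 42, 44, 90, 90, 90), "P1", 2.6)
        refl.I = rng.exponential(0.5, refl.n) + rng.exponential(0.5, refl.n)
        res = l_test(refl)
        assert res.mean_abs_l == pytest.approx(0.375, abs=0.02)
        assert res.twinned

    def test_small_table_matches_direct_arithmetic(self):
        # chain of reflections (0,0,l): every (h,k,l+1) partner exists
        hkl = np.array([[1, 2, l] for l in range(1, 12)])
        I = np.arange(1.0, 12.0)
        refl = ReflectionSet(cell=(30, 30, 30, 90, 90, 90), spacegroup="P1",
                             hkl=hkl, I=I)
        with pytest.warns(UserWarning):
            res = l_test(refl)
        # oracle over the explicit neighbour pairs actually formed
        assert res.n_pairs >= 10
        Ls = []
        lut = {tuple(h): v for h, v in zip(map(tuple, hkl), I)}
        seen = set()
        for d in ((0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 0, 2), (0, 2, 0),
                  (2, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)):
            for h in map(tuple, hkl):
                p = (h[0] + d[0], h[1] + d[1], h[2] + d[2])
                if p in lut and frozenset((h, p)) not in seen:
                    seen.add(frozenset((h, p)))
                    Ls.append((lut[h] - lut[p]) / (lut[h] + lut[p]))
        assert res.mean_abs_l == pytest.approx(np.mean(np.abs(Ls)))
        assert res.mean_l2 == pytest.approx(np.mean(np.square(Ls)))


class TestReflectionIO:
    def test_tsv_round_trip_bit_exact(self, rng, tmp_path):
        refl = generate_reflections((12, 13, 14, 90, 90, 90), "P212121", 3.0)
        refl.I = rng.exponential(100.0, refl.n)
        refl.sigI = rng.uniform(0.5, 2.0, refl.n)
        path = tmp_path / "r.tsv"
        write_reflections_tsv(refl, path)
        back = read_reflections(path)
        assert back.spacegroup == "P212121"
        np.testing.assert_array_equal(back.hkl, refl.hkl)
        np.testing.assert_array_equal(back.I, refl.I)      # bit-exact
        np.testing.assert_array_equal(back.sigI, refl.sigI)

    def test_mtz_read(self, rng, tmp_path):
        import gemmi
        refl = generate_reflections((12, 13, 14, 90, 90, 90), "P212121", 3.0)
        refl.I = rng.exponential(100.0, refl.n)
        refl.sigI = rng.uniform(0.5, 2.0, refl.n)
        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = gemmi.SpaceGroup("P 21 21 21")
        mtz.set_cell_for_all(gemmi.UnitCell(12, 13, 14, 90, 90, 90))
        mtz.add_dataset("x")
        mtz.add_column("IMEAN", "J")
        mtz.add_column("SIGIMEAN", "Q")
        data = np.column_stack([refl.hkl, refl.I, refl.sigI])
        mtz.set_data(data)
        path = tmp_path / "r.mtz"
        mtz.write_to_file(str(path))
        back = read_reflections(path)
        np.testing.assert_allclose(np.sort(back.I), np.sort(refl.I),
                                   rtol=1e-6)
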