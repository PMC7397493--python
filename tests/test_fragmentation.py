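"""Fragment-library generation, the per-residue shred descriptor, model
selection and eLLG-based sizing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from microshred.fragmentation import (
    Fragment, ShredProfile, sequential_fragments, spherical_fragments,
    cluster_rotations, rotation_angle_deg, shred_llg_profile, select_models,
    ellg_model_size,
)
from microshred.model_io import to_polyalanine
from microshred.diffraction import generate_reflections
from conftest import build_chain


class TestSequential:
    def test_thirty_residues_sizes_10_12(self, chain30):
        lib = sequential_fragments(chain30, 10, 12, 4)
        # brute force: s=10 -> 6 starts, s=11 -> 5, s=12 -> 5
        assert len(lib) == 16

    def test_whole_chain_single_fragment(self, chain30):
        lib = sequential_fragments(chain30, 30, 30, 4)
        assert len(lib) == 1
        assert lib[0].size == 30

    def test_parameter_errors(self, chain30):
        with pytest.raises(ValueError):
            sequential_fragments(chain30, 12, 10, 4)
        with pytest.raises(ValueError):
            sequential_fragments(chain30, 10, 12, 0)

    def test_omit_partitions_template(self, chain30):
        all_res = set(to_polyalanine(chain30).residue_keys())
        ext = sequential_fragments(chain30, 10, 10, 4, kind="extract")
        omi = sequential_fragments(chain30, 10, 10, 4, kind="omit")
        for fe, fo in zip(ext, omi):
            re_, ro = set(fe.residue_keys()), set(fo.residue_keys())
            assert re_ | ro == all_res
            assert not (re_ & ro)

    def test_chain_break_restarts_grid(self):
        import numpy as np
        from microshred.model_io import StructureModel
        a = build_chain(12)
        b = build_chain(12, first_res=13, offset=(12 * 3.8 + 30.0, 0, 0))
        both = StructureModel(
            element=np.concatenate([a.element, b.element]),
            name=np.concatenate([a.name, b.name]),
            res_id=np.concatenate([a.res_id, b.res_id]),
            res_name=np.concatenate([a.res_name, b.res_name]),
            chain=np.concatenate([a.chain, b.chain]),
            xyz=np.concatenate([a.xyz, b.xyz]),
            occ=np.concatenate([a.occ, b.occ]),
            b_factor=np.concatenate([a.b_factor, b.b_factor]))
        lib = sequential_fragments(both, 10, 10, 4)
        # each 12-residue run yields one valid 10-residue window at 0
        # and none spanning the 30 A gap
        assert len(lib) == 2
        for frag in lib:
            ids = sorted(r for _, r, _ in frag.residue_keys())
            assert ids[-1] - ids[0] == 9

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(L=st.integers(12, 70), smin=st.integers(5, 12),
           width=st.integers(0, 8), step=st.integers(1, 6))
    def test_count_matches_closed_form(self, L, smin, width, step):
        smax = smin + width
        chain = build_chain(L)
        lib = sequential_fragments(chain, smin, smax, step)
        expected = sum((L - s) // step + 1
                       for s in range(smin, smax + 1) if s <= L)
        assert len(lib) == expected


class TestSpherical:
    def test_straight_chain_single_span(self, chain30):
        lib = spherical_fragments(chain30, 10)
        assert len(lib) > 0
        assert all(len(f.spans) == 1 for f in lib)
        assert all(abs(f.size - 10) <= 10 for f in lib)

    def test_two_chain_bundle_multi_span(self):
        import numpy as np
        from microshred.model_io import StructureModel
        a = build_chain(20)
        b = build_chain(20, first_res=31, offset=(0.0, 5.0, 0.0))
        both = StructureModel(
            element=np.concatenate([a.element, b.element]),
            name=np.concatenate([a.name, b.name]),
            res_id=np.concatenate([a.res_id, b.res_id]),
            res_name=np.concatenate([a.res_name, b.res_name]),
            chain=np.concatenate([a.chain, b.chain]),
            xyz=np.concatenate([a.xyz, b.xyz]),
            occ=np.concatenate([a.occ, b.occ]),
            b_factor=np.concatenate([a.b_factor, b.b_factor]))
        lib = spherical_fragments(both, 12)
        # a centre mid-strand must pull residues from the facing strand
        assert any(len(f.spans) > 1 for f in lib)
        # oracle for one centre: explicit distance sort
        pa = to_polyalanine(both)
        keys = pa.residue_keys()
        camask = pa.ca_mask()
        ca = np.array([pa.xyz[pa.residue_mask([k]) & camask][0]
                       for k in keys])
        center = 9   # residue 10 of run 1
        order = np.argsort(np.linalg.norm(ca - ca[center], axis=1))
        nearest = {keys[i] for i in order[:12]}
        hit = [f for f in lib
               if ("A", 10, "") in set(f.residue_keys())]
        assert any(set(f.residue_keys()) <= nearest | set(f.residue_keys())
                   and len(set(f.residue_keys()) & nearest) >= 8
                   for f in hit)

    def test_whole_chain_limit(self, chain30):
        lib = spherical_fragments(chain30, 30)
        assert len(lib) == 1
        assert lib[0].size == 30

    def test_parameter_error(self, chain30):
        with pytest.raises(ValueError):
            spherical_fragments(chain30, 2, min_contig=3)


class TestClusterRotations:
    def test_close_pair_single_cluster(self):
        R1 = np.eye(3)
        R2 = Rotation.from_euler("zxz", [8, 5, 0], degrees=True).as_matrix()
        cl = cluster_rotations([R1, R2], [2.0, 1.0], 15.0)
        assert len(cl) == 1
        assert len(cl[0].members) == 2

    def test_distant_pair_two_clusters(self):
        R1 = np.eye(3)
        R2 = Rotation.from_euler("zxz", [0, 170, 0], degrees=True).as_matrix()
        cl = cluster_rotations([R1, R2], [1.0, 2.0], 15.0)
        assert len(cl) == 2
        # representative of the first cluster is the higher-scoring one
        assert rotation_angle_deg(cl[0].representative, R2) < 1e-6

    def test_symmetry_aware_metric(self):
        sym = [np.eye(3), Rotation.from_euler("z", 180,
                                              degrees=True).as_matrix()]
        R2 = Rotation.from_euler("z", 175, degrees=True).as_matrix()
        assert rotation_angle_deg(np.eye(3), R2) > 170
        assert rotation_angle_deg(np.eye(3), R2, sym) == pytest.approx(5.0)

    def test_matches_greedy_oracle_on_random_input(self, rng):
        rots = [Rotation.random(random_state=i).as_matrix()
                for i in range(50)]
        scores = list(rng.random(50))
        cl = cluster_rotations(rots, scores, 15.0)
        # independent re-implementation of the same greedy contract
        order = sorted(range(50), key=lambda i: (-scores[i], i))
        reps, assign = [], {}
        for i in order:
            for j, rep in enumerate(reps):
                if rotation_angle_deg(rots[i], rep) <= 15.0:
                    assign.setdefault(j, []).append(i)
                    break
            else:
                reps.append(rots[i])
                assign.setdefault(len(reps) - 1, []).append(i)
        assert len(cl) == len(reps)
        for j, c in enumerate(cl):
            assert len(c.members) == len(assign[j])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cluster_rotations([], [], 15.0)


class TestShredProfile:
    def _lib(self, chain30):
        return sequential_fragments(chain30, 10, 12, 4)

    def test_constant_scores_give_zero_profile(self, chain30):
        lib = self._lib(chain30)
        prof = shred_llg_profile(lib, {f.fragment_id: 3.0 for f in lib})
        np.testing.assert_allclose(prof.values, 0.0)

    def test_hand_computed_single_size_group(self, chain30):
        lib = sequential_fragments(chain30, 10, 10, 5)   # 5 fragments
        scores = {f.fragment_id: float(i)
                  for i, f in enumerate(lib)}
        prof = shred_llg_profile(lib, scores)
        raw = np.arange(5.0)
        z = (raw - raw.mean()) / raw.std()
        # windows start at residues 1, 6, 11, 16, 21 (length 10);
        # residue 1 is covered only by window 0, residue 30 only by 4,
        # residue 12 by windows 1 and 2
        assert prof.per_residue_score[("A", 1, "")] == pytest.approx(z[0])
        assert prof.per_residue_score[("A", 30, "")] == pytest.approx(z[4])
        assert prof.per_residue_score[("A", 12, "")] == pytest.approx(
            z[1:3].mean())

    def test_group_shift_invariance(self, chain30, rng):
        lib = self._lib(chain30)
        scores = {f.fragment_id: float(rng.random()) for f in lib}
        shifted = {fid: (v * 7.0 + 100.0 if
                         next(f for f in lib if f.fragment_id == fid).size
                         == 10 else v)
                   for fid, v in scores.items()}
        p1 = shred_llg_profile(lib, scores)
        p2 = shred_llg_profile(lib, shifted)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)

    def test_unscored_fragment_raises(self, chain30):
        lib = self._lib(chain30)
        with pytest.raises(ValueError):
            shred_llg_profile(lib, {})


class TestSelectModels:
    def test_flat_profile_whole_chain(self, chain30):
        prof = ShredProfile(
            per_residue_score={("A", i, ""): 1.0 for i in range(1, 31)},
            source_scores={})
        lib = select_models(prof, chain30)
        assert len(lib) >= 1
        assert lib[0].size == 30

    def test_triangular_profile_rule3_matches_thresholding(self):
        chain = build_chain(40)
        vals = {("A", i, ""): float(min(i, 41 - i)) for i in range(1, 41)}
        prof = ShredProfile(per_residue_score=vals, source_scores={})
        lib = select_models(prof, chain)
        arr = np.array([vals[("A", i, "")] for i in range(1, 41)])
        thr = arr.min() + 0.75 * (arr.max() - arr.min())
        oracle = {("A", i, "") for i in range(1, 41)
                  if vals[("A", i, "")] >= thr}
        got = [set(f.residue_keys()) for f in lib]
        assert oracle in got

    def test_at_most_max_models_and_min_size(self, chain30, rng):
        vals = {("A", i, ""): float(rng.random()) for i in range(1, 31)}
        prof = ShredProfile(per_residue_score=vals, source_scores={})
        lib = select_models(prof, chain30, max_models=4)
        assert len(lib) <= 4
        assert all(f.n_residues >= 10 for f in lib)


class TestEllgModelSize:
    def test_brute_force_oracle(self):
        ds = generate_reflections((30, 30, 30, 90, 90, 90), "P1", 2.0)
        n = ellg_model_size(ds, rmsd_est=1.0, asu_residues=100,
                            target_ellg=30.0)
        inv_d = 1.0 / ds.d()
        w = np.where(ds.centric, 0.25, 0.5)
        base = np.exp(-2 * np.pi ** 2 * inv_d ** 2 / 3.0) ** 4
        def ellg(k):
            return (k / 100.0) ** 2 * float(np.sum(base * w))
        brute = next(k for k in range(1, 101) if ellg(k) >= 30.0)
        assert n == brute

    def test_monotone_in_target(self):
        ds = generate_reflections((30, 30, 30, 90, 90, 90), "P1", 2.0)
        n30 = ellg_model_size(ds, 1.0, 100, 30.0)
        n60 = ellg_model_size(ds, 1.0, 100, 60.0)
        assert n60 >= n30

    def test_zero_rmsd_limit(self):
        # rmsd -> 0, f = 1: eLLG = N_ac/2 + N_c/4
        ds = generate_reflections((20, 20, 20, 90, 90, 90), "P212121", 3.0)
        cap = (np.sum(~ds.centric) / 2.0 + np.sum(ds.centric) / 4.0)
        n = ellg_model_size(ds, rmsd_est=1e-9, asu_residues=50,
                            target_ellg=cap * 0.99)
        assert n <= 50
        with pytest.warns(UserWarning):
            full = ellg_model_size(ds, rmsd_est=1e-9, asu_residues=50,
                                   target_ellg=cap * 1.01)
        assert full == 50

    def test_invalid_rmsd(self):
        ds = generate_reflections((20, 20, 20, 90, 90, 90), "P1", 3.0)
        with pytest.raises(ValueError):
            ellg_model_size(ds, 0.0, 100)
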