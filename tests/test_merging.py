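"""Scaling, CC1/2, damage-frame omission, merging and merge-set choice."""

import itertools

import numpy as np
import pytest

from microshred.diffraction import generate_reflections, d_spacings
from microshred.merging import (
    Frame, CrystalSeries, scale_series, cc_half, omit_damage_frames,
    merge, select_merge_set, write_series_tsv, read_series_tsv,
)
from microshred.symmetry import SpaceGroupInfo

CELL = (20.0, 22.0, 26.0, 90, 90, 90)
SG = "P212121"


def _theoretical():
    return generate_reflections(CELL, SG, 2.5)


def _series_from(hkl, I, sig, cid="x", n_frames=1):
    frames = []
    chunks = np.array_split(np.arange(len(I)), n_frames)
    for fi, idx in enumerate(chunks):
        frames.append(Frame(index=fi, hkl=hkl[idx], I=I[idx], sigI=sig[idx]))
    return CrystalSeries(crystal_id=cid, frames=frames)


@pytest.fixture
def full_obs(rng):
    """Every theoretical reflection observed twice with mild noise."""
    theo = _theoretical()
    truth = rng.exponential(100.0, theo.n) + 5.0
    hkl = np.concatenate([theo.hkl, theo.hkl])
    I = np.concatenate([truth, truth]) * (1 + rng.normal(0, 0.05,
                                                         2 * theo.n))
    sig = np.full(2 * theo.n, 3.0)
    return theo, truth, hkl, I, sig


class TestScaleSeries:
    def test_identical_series_unit_scale(self, full_obs):
        theo, truth, hkl, I, sig = full_obs
        a = _series_from(hkl, I, sig, "a")
        b = _series_from(hkl, I.copy(), sig, "b")
        out = scale_series([a, b], CELL, SG)
        assert out[1].scale == pytest.approx(1.0, abs=1e-6)
        assert out[1].b_rel == pytest.approx(0.0, abs=1e-3)

    def test_recovers_linear_factor(self, full_obs):
        theo, truth, hkl, I, sig = full_obs
        a = _series_from(hkl, I, sig, "a")
        b = _series_from(hkl, 2.5 * I, sig, "b")
        out = scale_series([a, b], CELL, SG)
        assert out[1].scale == pytest.approx(2.5, rel=1e-3)
        # corrected intensities match the reference
        np.testing.assert_allclose(out[1].frames[0].I,
                                   out[0].frames[0].I, rtol=1e-6)

    def test_recovers_b_decay(self, full_obs):
        theo, truth, hkl, I, sig = full_obs
        s2 = np.square(0.5 / d_spacings(CELL, hkl))
        a = _series_from(hkl, I, sig, "a")
        b = _series_from(hkl, I * np.exp(-2 * 5.0 * s2), sig, "b")
        out = scale_series([a, b], CELL, SG)
        assert out[1].b_rel == pytest.approx(5.0, abs=0.3)

    def test_insufficient_overlap_warns(self, full_obs):
        theo, truth, hkl, I, sig = full_obs
        a = _series_from(hkl, I, sig, "a")
        b = _series_from(hkl[:4], I[:4], sig[:4], "b")
        with pytest.warns(UserWarning):
            out = scale_series([a, b], CELL, SG)
        assert out[1].scale == pytest.approx(1.0)


class TestCCHalf:
    def test_duplicated_noise_free_is_one(self, full_obs):
        theo, truth, hkl, I, sig = full_obs
        exact = np.concatenate([truth, truth])
        assert cc_half(hkl, exact, SG, seed=1) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self, rng):
        theo = _theoretical()
        hkl = np.concatenate([theo.hkl] * 4)
        I = rng.normal(0, 1, len(hkl))
        cc = cc_half(hkl, I, SG, seed=2)
        assert abs(cc) < 2.0 / np.sqrt(theo.n)

    def test_toy_matches_hand_computation(self):
        # 5 reflections x 2 observations in P1; the oracle replays the
        # seeded per-reflection split (groups visited in canonical-key
        # order, one permutation drawn per group)
        hkl = np.array([[i, 0, 0] for i in range(1, 6)] * 2)
        I = np.array([10, 20, 30, 40, 50, 12, 18, 33, 39, 52], float)
        cc = cc_half(hkl, I, "P1", seed=0)
        pairs = {i: (I[i - 1], I[i + 4]) for i in range(1, 6)}
        rng = np.random.default_rng(0)
        m1, m2 = [], []
        for i in sorted(pairs):          # canonical keys ascend with i
            perm = rng.permutation(2)
            vals = np.array(pairs[i])[perm]
            m1.append(vals[0])
            m2.append(vals[1])
        expected = np.corrcoef(m1, m2)[0, 1]
        assert cc == pytest.approx(expected, abs=1e-12)

    def test_too_few_reflections_raise(self):
        with pytest.raises(ValueError):
            cc_half(np.array([[1, 0, 0], [1, 0, 0]]), np.array([1.0, 2.0]),
                    "P1", seed=0)


def _damaged_series(rng, damage=True, n_frames=10, cid="x"):
    """Multi-frame series with s^2-weighted decay on the last 4 frames."""
    theo = _theoretical()
    truth = rng.exponential(100.0, theo.n) + 5.0
    s2 = np.square(1.0 / theo.d())
    frames = []
    for fi in range(n_frames):
        decay = (np.exp(-8.0 * s2 * max(fi - 6 + 1, 0))
                 if damage else np.ones(theo.n))
        I = truth * decay * (1 + rng.normal(0, 0.08, theo.n))
        frames.append(Frame(index=fi, hkl=theo.hkl, I=I,
                            sigI=np.full(theo.n, 3.0)))
    return CrystalSeries(crystal_id=cid, frames=frames)


class TestOmitDamageFrames:
    def test_damaged_series_trims_one_to_six(self, rng):
        s = _damaged_series(rng, damage=True)
        out = omit_damage_frames(s, CELL, SG, seed=4)
        dropped = len(s.frames) - len(out.frames)
        assert 1 <= dropped <= 6

    def test_damage_free_series_untouched(self, rng):
        s = _damaged_series(rng, damage=False)
        out = omit_damage_frames(s, CELL, SG, seed=4)
        assert len(out.frames) == len(s.frames)

    def test_never_more_than_max_omit(self, rng):
        s = _damaged_series(rng, damage=True)
        out = omit_damage_frames(s, CELL, SG, max_omit=2, seed=4)
        assert len(s.frames) - len(out.frames) <= 2

    def test_decision_cc_never_decreases(self, rng):
        s = _damaged_series(rng, damage=True)
        out = omit_damage_frames(s, CELL, SG, seed=4)
        def decision_cc(cs):
            hkl, I, _, _ = cs.observations()
            dmed = np.median(d_spacings(CELL, hkl))
            keep = d_spacings(CELL, hkl) <= dmed if False else \
                d_spacings(CELL, cs.observations()[0]) <= np.median(
                    d_spacings(CELL, s.observations()[0]))
            hkl2, I2 = hkl[keep], I[keep]
            return np.mean([cc_half(hkl2, I2, SG, seed=4 + 1000 * j)
                            for j in range(5)])
        assert decision_cc(out) >= decision_cc(s)


class TestMerge:
    def test_single_complete_crystal(self, rng):
        theo = _theoretical()
        I = rng.exponential(100.0, theo.n)
        s = _series_from(theo.hkl, I, np.full(theo.n, 2.0), "a")
        res = merge([s], CELL, SG, 2.5)
        assert res.completeness == pytest.approx(100.0)
        assert res.multiplicity == pytest.approx(1.0)
        assert res.merged.n == theo.n

    def test_duplicated_crystal_doubles_multiplicity(self, rng):
        theo = _theoretical()
        I = rng.exponential(100.0, theo.n)
        s1 = _series_from(theo.hkl, I, np.full(theo.n, 2.0), "a")
        s2 = _series_from(theo.hkl, I.copy(), np.full(theo.n, 2.0), "b")
        r1 = merge([s1], CELL, SG, 2.5)
        r2 = merge([s1, s2], CELL, SG, 2.5)
        assert r2.multiplicity == pytest.approx(2.0)
        lut = {tuple(h): v for h, v in zip(map(tuple, r1.merged.hkl),
                                           r1.merged.I)}
        for h, v in zip(map(tuple, r2.merged.hkl), r2.merged.I):
            assert v == pytest.approx(lut[h])

    def test_completeness_matches_union_oracle(self, rng):
        theo = _theoretical()
        sg = SpaceGroupInfo(SG)
        series, union = [], set()
        for i in range(4):
            pick = rng.random(theo.n) < 0.4
            hkl = theo.hkl[pick]
            union |= set(map(tuple, sg.reduce_to_asu(hkl)))
            series.append(_series_from(hkl, rng.exponential(50.0,
                                                            pick.sum()),
                                       np.full(pick.sum(), 2.0), f"c{i}"))
        res = merge(series, CELL, SG, 2.5)
        assert res.completeness == pytest.approx(
            100.0 * len(union) / theo.n)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            merge([], CELL, SG, 2.5)

    def test_merged_mean_invariant_to_order(self, rng):
        theo = _theoretical()
        series = []
        for i in range(3):
            I = rng.exponential(100.0, theo.n)
            series.append(_series_from(theo.hkl, I,
                                       np.full(theo.n, 2.0), f"c{i}"))
        r1 = merge(series, CELL, SG, 2.5)
        r2 = merge(series[::-1], CELL, SG, 2.5)
        lut = {tuple(h): v for h, v in zip(map(tuple, r1.merged.hkl),
                                           r1.merged.I)}
        for h, v in zip(map(tuple, r2.merged.hkl), r2.merged.I):
            assert v == pytest.approx(lut[h], rel=1e-12)


class TestSelectMergeSet:
    def test_single_complete_crystal_chosen(self, rng):
        theo = _theoretical()
        full = _series_from(theo.hkl, rng.exponential(100.0, theo.n),
                            np.full(theo.n, 2.0), "full")
        part = _series_from(theo.hkl[: theo.n // 2],
                            rng.exponential(100.0, theo.n // 2),
                            np.full(theo.n // 2, 2.0), "part")
        chosen, res = select_merge_set([part, full], CELL, SG, 2.5)
        assert [c.crystal_id for c in chosen] == ["full"]

    def test_tie_broken_by_i_over_sigma(self, rng):
        theo = _theoretical()
        half1 = rng.random(theo.n) < 0.55
        truth = rng.exponential(100.0, theo.n) + 10.0
        def mk(mask, sig, cid):
            return _series_from(theo.hkl[mask], truth[mask],
                                np.full(mask.sum(), sig), cid)
        A = mk(half1, 2.0, "A")
        B = mk(~half1, 10.0, "B")       # complements A, noisy
        C = mk(~half1, 1.0, "C")        # complements A, precise
        chosen, res = select_merge_set([A, B, C], CELL, SG, 2.5,
                                       threshold=90.0)
        assert sorted(c.crystal_id for c in chosen) == ["A", "C"]
        # exhaustive oracle
        best = None
        for r in range(1, 4):
            combos = [c for c in itertools.combinations([A, B, C], r)
                      if merge(list(c), CELL, SG, 2.5).completeness > 90.0]
            if combos:
                best = max(combos, key=lambda c: merge(
                    list(c), CELL, SG, 2.5).mean_i_over_sig)
                break
        assert sorted(c.crystal_id for c in best) == \
            sorted(c.crystal_id for c in chosen)

    def test_threshold_zero_picks_best_singleton(self, rng):
        theo = _theoretical()
        truth = rng.exponential(100.0, theo.n) + 10.0
        a = _series_from(theo.hkl, truth, np.full(theo.n, 5.0), "a")
        b = _series_from(theo.hkl, truth, np.full(theo.n, 1.0), "b")
        chosen, _ = select_merge_set([a, b], CELL, SG, 2.5, threshold=0.0)
        assert [c.crystal_id for c in chosen] == ["b"]

    def test_nothing_passes_returns_full_set(self, rng):
        theo = _theoretical()
        tiny = _series_from(theo.hkl[:10], rng.exponential(10.0, 10),
                            np.full(10, 2.0), "tiny")
        with pytest.warns(UserWarning):
            chosen, _ = select_merge_set([tiny], CELL, SG, 2.5)
        assert len(chosen) == 1


def test_series_tsv_round_trip(tmp_path, rng):
    theo = _theoretical()
    s = _series_from(theo.hkl, rng.exponential(10.0, theo.n),
                     np.full(theo.n, 2.0), "xtal07", n_frames=3)
    path = tmp_path / "s.tsv"
    write_series_tsv(s, path)
    back = read_series_tsv(path)
    assert back.crystal_id == "xtal07"
    assert len(back.frames) == 3
    h1, i1, g1, f1 = s.observations()
    h2, i2, g2, f2 = back.observations()
    np.testing.assert_array_equal(h1, h2)
    np.testing.assert_array_equal(i1, i2)
    np.testing.assert_array_equal(f1, f2)
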