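"""Placement of polyalanine fragments against intensity data.

The rotation target is a Patterson-correlation-style score: the Pearson
correlation, over unique reflections, between the observed E^2 and the
symmetry-summed squared molecular transform of the rotated fragment
(translation-independent).  The translation target is the correlation of
calculated and observed amplitudes on a brute-force grid over the
Cheshire cell, with the translation Z-score (TFZ) defined against the
grid-score distribution.  Both are documented simplifications of the
maximum-likelihood rotation/translation functions of full molecular
replacement engines; scores are comparable ordinally, not numerically,
with those engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import i0e, i1e
from scipy.spatial.transform import Rotation as _Rot

from .symmetry import SpaceGroupInfo
from .diffraction import (
    ReflectionSet,
    FormFactorTable,
    orthogonalization_matrix,
    atom_scattering_weights,
    structure_factors,
    normalize_E,
    _equal_count_shells,
)
from .fragmentation import Fragment, sigma_a

__all__ = [
    "SearchGrid",
    "Placement",
    "rotation_search",
    "refine_rotation",
    "translation_search",
    "rigid_refine",
    "pack_filter",
    "llg_proxy",
    "so3_grid",
]

_MAX_ROT_STEP = 30.0


@dataclass
class SearchGrid:
    """Sampling parameters for the brute-force searches."""

    rot_step_deg: float = 10.0
    trans_step_frac: float = 1.0 / 24.0
    dmin: float | None = None     # optional high-resolution cutoff
    dmax: float | None = None
    top_rotations: int = 30

    def __post_init__(self):
        if self.rot_step_deg <= 0 or self.trans_step_frac <= 0:
            raise ValueError("grid steps must be positive")


@dataclass
class Placement:
    """A fragment plus rigid placement and its scores."""

    fragment_id: str
    rotation: np.ndarray          # 3x3 Cartesian, det +1
    translation: np.ndarray       # fractional triplet
    rf_score: float = np.nan
    t_score: float = np.nan       # translation-function correlation [0..1]
    tfz: float = np.nan
    cc: float = np.nan            # 100 * Pearson correlation of |F|
    llg_proxy: float = np.nan

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)


# -- rotation grid ----------------------------------------------------------

def so3_grid(step_deg: float) -> np.ndarray:
    """Uniform zxz-Euler grid over SO(3); returns (n, 3, 3) matrices."""
    na = max(1, int(round(360.0 / step_deg)))
    nb = max(1, int(round(180.0 / step_deg)))
    alphas = np.arange(na) * 360.0 / na
    betas = (np.arange(nb) + 0.5) * 180.0 / nb
    mats = []
    for b in betas:
        for a in alphas:
            for g in alphas:
                mats.append(_Rot.from_euler("zxz", [a, b, g],
                                            degrees=True).as_matrix())
    return np.array(mats)


def _reduce_grid_to_asu(grid: np.ndarray, sym_rots: np.ndarray) -> np.ndarray:
    """One representative per orbit of the point group acting on the left.

    Scoring is invariant under R -> M R for point-group rotations M, so
    only one member per orbit needs evaluation.
    """
    kept, seen = [], set()
    for R in grid:
        qs = []
        for M in sym_rots:
            q = _Rot.from_matrix(M @ R).as_quat()
            if q[3] < 0 or (q[3] == 0 and q[0] < 0):
                q = -q
            qs.append(tuple(np.round(q, 5)))
        key = max(qs)
        if key in seen:
            continue
        seen.add(key)
        kept.append(R)
    return np.array(kept)


# -- rotation search --------------------------------------------------------

class _RotationScorer:
    """Precomputed machinery to score rotations of one fragment.

    When the data set exceeds ``max_refl`` reflections, scoring uses the
    reflections with the largest |E^2 - 1| (the terms that carry the
    Patterson-correlation signal) — a standard economy for grid searches.
    Internals run in single precision; the score is a correlation
    coefficient, insensitive at that level.
    """

    def __init__(self, fragment_model, data: ReflectionSet,
                 table: FormFactorTable | None = None, n_shells: int = 10,
                 max_refl: int = 768):
        if data.E is None:
            data = normalize_E(data)
        self.data = data
        sg = data.sg_info
        M = orthogonalization_matrix(data.cell)
        self.sym_cart = sg.cartesian_rotations(M)
        if data.n > max_refl:
            pick = np.argsort(-np.abs(data.E ** 2 - 1.0),
                              kind="stable")[:max_refl]
            pick.sort()
            data = data.subset(pick)
        svec = data.hkl.astype(float) @ np.linalg.inv(M)   # 1/d vectors
        # symmetry-expanded scattering vectors, (n_ops * n_refl, 3)
        self.s_all = np.einsum("mij,rj->mri", self.sym_cart, svec
                               ).reshape(-1, 3).astype(np.float32)
        self.n_ops = len(self.sym_cart)
        self.n_refl = data.n
        xyz = fragment_model.xyz - fragment_model.xyz.mean(axis=0)
        self.xyz = xyz.astype(np.float32)
        stol = data.stol()
        W1 = atom_scattering_weights(fragment_model, stol, table)
        self.W = np.tile(W1, (self.n_ops, 1)).astype(np.float32)
        self.e2 = data.E ** 2
        self.shell = _equal_count_shells(np.square(stol),
                                         max(1, min(n_shells, data.n)))
        self.shell_counts = np.bincount(self.shell)

    def score(self, R: np.ndarray) -> float:
        theta = (2.0 * np.float32(np.pi)) * (
            (self.s_all @ R.astype(np.float32)) @ self.xyz.T)
        re = np.einsum("sa,sa->s", self.W, np.cos(theta))
        im = np.einsum("sa,sa->s", self.W, np.sin(theta))
        inten = (re.astype(float) ** 2 + im.astype(float) ** 2
                 ).reshape(self.n_ops, self.n_refl).sum(axis=0)
        shell_mean = np.bincount(self.shell, weights=inten) / self.shell_counts
        norm = inten / shell_mean[self.shell]
        a, b = self.e2, norm
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _resolution_slice(data: ReflectionSet, grid: SearchGrid) -> ReflectionSet:
    d = data.d()
    mask = np.ones(data.n, dtype=bool)
    if grid.dmin is not None:
        mask &= d >= grid.dmin
    if grid.dmax is not None:
        mask &= d <= grid.dmax
    return data.subset(mask) if not mask.all() else data


def rotation_search(fragment, data: ReflectionSet, grid: SearchGrid,
                    table: FormFactorTable | None = None) -> list:
    """Score a uniform SO(3) grid; returns [(rf_score, rotation), ...] desc.

    ``fragment`` may be a Fragment or a bare StructureModel.
    """
    if grid.rot_step_deg > _MAX_ROT_STEP:
        raise ValueError(
            f"rotation step {grid.rot_step_deg} deg > {_MAX_ROT_STEP} deg "
            "is meaningless sampling")
    model = fragment.model if isinstance(fragment, Fragment) else fragment
    if model.n_atoms == 0:
        raise ValueError("empty fragment")
    data = _resolution_slice(data, grid)
    scorer = _RotationScorer(model, data, table)
    rotations = _reduce_grid_to_asu(so3_grid(grid.rot_step_deg),
                                    scorer.sym_cart)
    scored = [(scorer.score(R), R) for R in rotations]
    scored.sort(key=lambda t: -t[0])
    return scored


def refine_rotation(fragment, data: ReflectionSet, rotation: np.ndarray,
                    grid: SearchGrid | None = None,
                    table: FormFactorTable | None = None,
                    max_iter: int = 60):
    """Local simplex maximisation of the rotation score around a start.

    Returns (refined rotation, score); never worse than the input.
    """
    grid = grid or SearchGrid()
    model = fragment.model if isinstance(fragment, Fragment) else fragment
    data = _resolution_slice(data, grid)
    scorer = _RotationScorer(model, data, table)
    R0 = np.asarray(rotation, dtype=float)
    start_score = scorer.score(R0)

    def neg(euler_deg):
        dR = _Rot.from_euler("zxz", euler_deg, degrees=True).as_matrix()
        return -scorer.score(dR @ R0)

    res = minimize(neg, np.zeros(3), method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 0.05,
                            "fatol": 1e-5,
                            "initial_simplex": np.vstack(
                                [np.zeros(3),
                                 np.eye(3) * grid.rot_step_deg / 2.0])})
    if -res.fun > start_score:
        dR = _Rot.from_euler("zxz", res.x, degrees=True).as_matrix()
        return dR @ R0, float(-res.fun)
    return R0, float(start_score)


# -- translation search -----------------------------------------------------

class _TranslationScorer:
    """F(h; t) via per-operator partial sums: one matrix product per batch.

    The search score is the Pearson correlation of *normalized*
    amplitudes (E-values, epsilon-aware, per-shell rms scaling of each
    candidate's |F_calc|): correlating raw amplitudes is dominated by the
    common Wilson falloff and barely discriminates translations.  The
    raw-|F| correlation is still available for reporting (``cc_raw``).
    """

    def __init__(self, fragment_model, rotation, data: ReflectionSet,
                 table: FormFactorTable | None = None, n_shells: int = 10,
                 max_refl: int | None = None, rmsd_weight: float = 0.0):
        if data.E is None:
            data = normalize_E(data, n_shells)
        if max_refl is not None and data.n > max_refl:
            pick = np.argsort(-np.abs(data.E ** 2 - 1.0),
                              kind="stable")[:max_refl]
            pick.sort()
            data = data.subset(pick)
        self.data = data
        # sigma_A-style resolution weights: an imperfect model carries
        # exponentially less amplitude signal at high resolution, and the
        # weighting also widens the tolerance to residual rotation error
        if rmsd_weight > 0:
            self.w = sigma_a(1.0 / data.d(), 1.0, rmsd_weight) ** 2
        else:
            self.w = np.ones(data.n)
        self.w = self.w / self.w.sum()
        sg = data.sg_info
        M = orthogonalization_matrix(data.cell)
        xyz = fragment_model.xyz - fragment_model.xyz.mean(axis=0)
        frac = (xyz @ np.asarray(rotation).T) @ np.linalg.inv(M).T
        stol = data.stol()
        W = atom_scattering_weights(fragment_model, stol, table)
        h = data.hkl.astype(float)
        self.n_ops = sg.n_ops
        self.hr = np.einsum("rj,mjk->mrk", h, sg.rotations.astype(float))
        A = []
        for m, (R, t) in enumerate(zip(sg.rotations, sg.translations)):
            phase = self.hr[m] @ frac.T + (h @ t)[:, None]
            A.append(np.einsum("ra,ra->r", W, np.exp(2j * np.pi * phase)))
        self.A = np.array(A)                     # (n_ops, n_refl)
        self.fobs = data.amplitudes()
        n_shells = max(1, min(n_shells, data.n))
        shell = _equal_count_shells(np.square(stol), n_shells)
        self.shell_onehot = np.zeros((data.n, n_shells))
        self.shell_onehot[np.arange(data.n), shell] = 1.0
        self.shell_counts = self.shell_onehot.sum(axis=0)
        self.shell = shell
        self.inv_eps = 1.0 / data.epsilon.astype(float)
        # observed E re-derived with the scorer's own shell partition, so
        # that exact agreement of |F_calc| with |F_obs| scores exactly 1
        self.eobs = self._normalized(self.fobs[None, :])[0]
        self.eobs_c = self.eobs - float(self.w @ self.eobs)
        self.eobs_ss = float(self.w @ self.eobs_c ** 2)

    def amplitudes(self, trans: np.ndarray) -> np.ndarray:
        """|F_calc| for a batch of fractional translations, (n_t, n_refl)."""
        trans = np.atleast_2d(trans)
        F = np.zeros((len(trans), self.A.shape[1]), dtype=complex)
        for m in range(self.n_ops):
            F += np.exp(2j * np.pi * trans @ self.hr[m].T) * self.A[m]
        return np.abs(F)

    def _normalized(self, fc: np.ndarray) -> np.ndarray:
        """Per-shell epsilon-aware E-values of a batch of |F_calc| rows."""
        i_eps = np.square(fc) * self.inv_eps
        shell_mean = (i_eps @ self.shell_onehot) / self.shell_counts
        shell_mean = np.where(shell_mean > 0, shell_mean, 1.0)
        return np.sqrt(i_eps / shell_mean[:, self.shell])

    def correlations(self, trans: np.ndarray) -> np.ndarray:
        """Weighted Pearson correlation of normalized amplitudes."""
        ec = self._normalized(self.amplitudes(trans))
        ec_c = ec - (ec @ self.w)[:, None]
        num = ec_c @ (self.w * self.eobs_c)
        den = np.sqrt(((ec_c ** 2) @ self.w) * self.eobs_ss)
        ok = den > 0
        out = np.zeros(len(ec))
        out[ok] = num[ok] / den[ok]
        return out

    def cc_raw(self, trans: np.ndarray) -> np.ndarray:
        """Plain Pearson correlation of |F_calc| vs |F_obs| (percent/100)."""
        fc = self.amplitudes(trans)
        fc_c = fc - fc.mean(axis=1, keepdims=True)
        fo_c = self.fobs - self.fobs.mean()
        den = np.sqrt(np.sum(fc_c ** 2, axis=1) * np.sum(fo_c ** 2))
        ok = den > 0
        out = np.zeros(len(fc))
        out[ok] = (fc_c @ fo_c)[ok] / den[ok]
        return out


def translation_search(fragment, rotation, data: ReflectionSet,
                       grid: SearchGrid,
                       table: FormFactorTable | None = None,
                       top_n: int = 10, chunk: int = 512,
                       coarse_dmin: float = 4.5,
                       n_carry: int = 200,
                       rmsd_weight: float = 0.0,
                       min_separation: float = 2.0) -> list:
    """Two-stage brute-force translation search over the Cheshire cell.

    The full-resolution correlation peak is only ~d_min/4 wide — far
    narrower than any affordable grid — so the search first scans the
    ``grid.trans_step_frac`` grid at lowered resolution (``coarse_dmin``,
    where peaks are broad enough to register), then rescores the best
    ``n_carry`` coarse positions and their sub-grid neighbourhoods at
    full resolution.  TFZ is the Z-score of the best coarse score
    against the coarse-scan distribution; the returned ``t_score``/``cc``
    are full-resolution values.
    """
    model = fragment.model if isinstance(fragment, Fragment) else fragment
    fid = fragment.fragment_id if isinstance(fragment, Fragment) else "model"
    data_s = _resolution_slice(data, grid)
    # stage A: coarse grid, lowered resolution
    d = data_s.d()
    coarse_mask = d >= coarse_dmin
    data_c = data_s.subset(coarse_mask) if coarse_mask.sum() >= 30 else data_s
    scorer_c = _TranslationScorer(model, rotation, data_c, table,
                                  rmsd_weight=rmsd_weight)
    n_div = max(2, int(round(1.0 / grid.trans_step_frac)))
    tgrid = data_s.sg_info.cheshire_translations(n_div)
    scores = np.empty(len(tgrid))
    for lo in range(0, len(tgrid), chunk):
        scores[lo:lo + chunk] = scorer_c.correlations(tgrid[lo:lo + chunk])
    sd = scores.std()
    if sd == 0:
        warnings.warn("degenerate translation-score distribution; TFZ = 0")
        tfz_best = 0.0
    else:
        tfz_best = float((scores.max() - scores.mean()) / sd)
    # stage B: full resolution on the best coarse positions +- sub-steps
    carry = np.argsort(-scores)[:min(n_carry, len(scores))]
    sub = np.array([-0.5, 0.0, 0.5]) * (1.0 / n_div)
    offs = np.stack(np.meshgrid(sub, sub, sub, indexing="ij"),
                    axis=-1).reshape(-1, 3)
    cand = (tgrid[carry][:, None, :] + offs[None, :, :]).reshape(-1, 3)
    scorer_f = _TranslationScorer(model, rotation, data_s, table,
                                  rmsd_weight=rmsd_weight)
    fscores = np.empty(len(cand))
    for lo in range(0, len(cand), chunk):
        fscores[lo:lo + chunk] = scorer_f.correlations(cand[lo:lo + chunk])
    order = np.argsort(-fscores)
    M = orthogonalization_matrix(data_s.cell)
    out = []
    for i in order:
        t = cand[i] % 1.0
        close = False
        for p in out:
            diff = t - p.translation
            diff -= np.round(diff)
            if np.linalg.norm(diff @ M.T) < min_separation:
                close = True
                break
        if close:
            continue
        out.append(Placement(fragment_id=fid, rotation=np.asarray(rotation),
                             translation=t,
                             t_score=float(fscores[i]),
                             tfz=tfz_best if not out else
                             (float((scores[carry[i // len(offs)]]
                                     - scores.mean()) / sd) if sd > 0
                              else 0.0),
                             cc=float(100.0 * scorer_f.cc_raw(
                                 cand[i][None, :])[0])))
        if len(out) >= top_n:
            break
    return out


# -- rigid-body refinement --------------------------------------------------

def rigid_refine(placement: Placement, fragment, data: ReflectionSet,
                 max_iter: int = 100,
                 grid: SearchGrid | None = None,
                 table: FormFactorTable | None = None,
                 rmsd_weight: float = 0.0) -> Placement:
    """Derivative-free local maximisation of the translation-function score
    over the six rigid-body parameters.

    The returned placement never scores below the input (monotonicity by
    construction: if the simplex fails to improve, the input is returned).
    Stops at ``max_iter`` evaluations or when steps fall below 0.05 deg /
    0.002 fractional.
    """
    grid = grid or SearchGrid()
    model = fragment.model if isinstance(fragment, Fragment) else fragment
    data_s = _resolution_slice(data, grid)
    R0 = placement.rotation
    t0 = placement.translation
    TSCALE = 25.0   # 1 parameter unit = 1 deg rotation = 0.04 fractional

    def make_placement(params):
        dR = _Rot.from_euler("zxz", params[:3], degrees=True).as_matrix()
        return dR @ R0, t0 + params[3:] / TSCALE

    # the simplex objective runs on a strongest-E subset for speed; the
    # final decision below is made at full resolution
    def neg(params):
        R, t = make_placement(params)
        sc = _TranslationScorer(model, R, data_s, table, max_refl=1024,
                                rmsd_weight=rmsd_weight)
        return -float(sc.correlations(t[None, :])[0])

    simplex = np.vstack([np.zeros(6), np.eye(6)])
    simplex[1:4, :3] *= 2.0            # 2 deg rotation steps
    simplex[4:7, 3:] *= 0.02 * TSCALE  # 0.02 fractional steps
    res = minimize(neg, np.zeros(6), method="Nelder-Mead",
                   options={"maxfev": max_iter, "xatol": 0.05,
                            "fatol": 1e-6, "initial_simplex": simplex})

    def full_score(R, t):
        sc = _TranslationScorer(model, R, data_s, table,
                                rmsd_weight=rmsd_weight)
        return (float(sc.correlations(t[None, :])[0]),
                float(100.0 * sc.cc_raw(t[None, :])[0]))

    start_full, start_cc = full_score(R0, t0)
    R1, t1 = make_placement(res.x)
    t1 = t1 % 1.0
    new_full, new_cc = full_score(R1, t1)
    if new_full <= start_full:
        R, t, best, cc = R0, t0, start_full, start_cc
    else:
        R, t, best, cc = R1, t1, new_full, new_cc
    return Placement(fragment_id=placement.fragment_id, rotation=R,
                     translation=t, rf_score=placement.rf_score,
                     t_score=best, tfz=placement.tfz, cc=cc,
                     llg_proxy=placement.llg_proxy)


# -- packing filter ---------------------------------------------------------

def placed_ca_fractional(placement: Placement, fragment, cell) -> np.ndarray:
    """Fractional Calpha coordinates of a placed fragment."""
    model = fragment.model if isinstance(fragment, Fragment) else fragment
    M = orthogonalization_matrix(cell)
    xyz = model.xyz[model.ca_mask()]
    xyz = xyz - model.xyz.mean(axis=0)
    frac = (xyz @ placement.rotation.T) @ np.linalg.inv(M).T
    return frac + placement.translation


def _min_image_close_fraction(frac_a, frac_b, M, cutoff):
    """Fraction of atoms in a within cutoff of any atom in b (min image)."""
    diff = frac_a[:, None, :] - frac_b[None, :, :]
    diff -= np.round(diff)
    cart = diff @ M.T
    dist = np.linalg.norm(cart, axis=2)
    return float(np.mean(dist.min(axis=1) < cutoff))


def pack_filter(placement: Placement, placed: list, fragment,
                cell, spacegroup, placed_fragments: list | None = None,
                clash_dist: float = 3.0,
                max_clash_fraction: float = 0.05) -> bool:
    """Accept or reject a placement on steric grounds.

    Rejects when more than ``max_clash_fraction`` of the candidate's
    Calpha atoms approach (a) any of its own non-identity symmetry
    copies, or (b) any prior placement or its symmetry copies, closer
    than ``clash_dist`` Angstrom (minimum-image convention).
    """
    sg = SpaceGroupInfo(spacegroup)
    M = orthogonalization_matrix(cell)
    ca = placed_ca_fractional(placement, fragment, cell)
    n_ca = len(ca)
    if n_ca == 0:
        return True
    clashing = np.zeros(n_ca, dtype=bool)

    def mark(other_frac):
        nonlocal clashing
        diff = ca[:, None, :] - other_frac[None, :, :]
        diff -= np.round(diff)
        dist = np.linalg.norm(diff @ M.T, axis=2)
        clashing |= (dist < clash_dist).any(axis=1)

    # own symmetry copies (skip identity)
    for R, t in list(zip(sg.rotations, sg.translations))[1:]:
        mark(ca @ R.astype(float).T + t)
    # prior placements and all their symmetry copies
    if placed_fragments is None:
        placed_fragments = [fragment] * len(placed)
    for other, ofrag in zip(placed, placed_fragments):
        oca = placed_ca_fractional(other, ofrag, cell)
        for R, t in zip(sg.rotations, sg.translations):
            mark(oca @ R.astype(float).T + t)
    return bool(np.mean(clashing) <= max_clash_fraction)


# -- likelihood-style scoring -----------------------------------------------

def _log_i0(x):
    return np.log(i0e(x)) + np.abs(x)


def llg_proxy(placement: Placement, fragment, data: ReflectionSet,
              rmsd_est: float, completeness_fraction: float,
              table: FormFactorTable | None = None) -> float:
    """Rice-likelihood gain of a placement over the random-atom null.

    Both observed and calculated amplitudes are normalised (E-values);
    sigma_A combines the model completeness fraction and the coordinate-
    error estimate exactly as in eLLG model sizing.  At sigma_A = 0 the
    score is identically zero.  Higher is better.
    """
    if not 0.0 <= completeness_fraction <= 1.0:
        raise ValueError("completeness_fraction must lie in [0, 1]")
    if data.E is None:
        data = normalize_E(data)
    model = fragment.model if isinstance(fragment, Fragment) else fragment
    M = orthogonalization_matrix(data.cell)
    placed = model.copy()
    placed.xyz = ((model.xyz - model.xyz.mean(axis=0)) @ placement.rotation.T
                  + placement.translation @ M.T)
    calc = structure_factors(placed, data, table)
    calc.I = calc.F ** 2
    ecalc = normalize_E(calc).E
    eobs = data.E
    sa = sigma_a(1.0 / data.d(), completeness_fraction, rmsd_est)
    sa = np.clip(sa, 0.0, 0.999)
    centric = data.centric
    one = 1.0 - sa ** 2
    acN = ~centric
    llg = np.zeros(data.n)
    # acentric: Rice vs Wilson
    eo, ec, s, v = eobs[acN], ecalc[acN], sa[acN], one[acN]
    llg_ac = (-np.log(v) - (eo ** 2 + s ** 2 * ec ** 2) / v + eo ** 2
              + _log_i0(2.0 * eo * s * ec / v))
    llg[acN] = llg_ac
    # centric: Woolfson vs centric Wilson
    eo, ec, s, v = eobs[centric], ecalc[centric], sa[centric], one[centric]
    x = eo * s * ec / v
    llg_c = (-0.5 * np.log(v) - (eo ** 2 + s ** 2 * ec ** 2) / (2.0 * v)
             + eo ** 2 / 2.0 + np.logaddexp(x, -x) - np.log(2.0))
    llg[centric] = llg_c
    return float(np.sum(llg))


def figure_of_merit(eobs, ecalc, sa, centric) -> np.ndarray:
    """Sim-style phase figure of merit m per reflection.

    Acentric: m = I1(X)/I0(X); centric: m = tanh(X/2), with
    X = 2 sigma_A Eo Ec / (1 - sigma_A^2).
    """
    sa = np.clip(sa, 0.0, 0.999)
    X = 2.0 * sa * eobs * ecalc / (1.0 - sa ** 2)
    m = np.where(centric, np.tanh(X / 2.0),
                 i1e(X) / np.where(i0e(X) > 0, i0e(X), 1.0))
    return np.clip(m, 0.0, 1.0)
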