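"""Solution-quality metrics: weighted mean phase error, amplitude
correlation, Fourier/difference maps and omit-map peak heights.

Phase comparisons are only meaningful modulo the allowed origin shifts
of the space group (and the enantiomorph ambiguity), so the weighted
mean phase error is minimised over both.  Allowed origin shifts for the
supported groups are hard-coded tables; for groups with a continuously
free origin axis the shift is searched on a fine grid and polished
numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .symmetry import SpaceGroupInfo
from .diffraction import (
    ReflectionSet,
    orthogonalization_matrix,
    structure_factors,
)

__all__ = [
    "PhaseSet",
    "MapGrid",
    "wmpe",
    "amp_cc",
    "fourier_map",
    "difference_map",
    "omit_peak_height",
]


@dataclass
class PhaseSet:
    """Phases (degrees) with figure-of-merit weights on unique indices."""

    cell: tuple
    spacegroup: str
    hkl: np.ndarray
    phase: np.ndarray
    weight: np.ndarray | None = None
    F: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.phase = np.asarray(self.phase, dtype=float) % 360.0
        if self.weight is None:
            self.weight = np.ones(len(self.hkl))
        self.weight = np.clip(np.asarray(self.weight, dtype=float), 0.0, 1.0)
        if self.F is not None:
            self.F = np.asarray(self.F, dtype=float)

    @property
    def n(self) -> int:
        return len(self.hkl)

    @classmethod
    def from_reflections(cls, refl: ReflectionSet,
                         weight=None) -> "PhaseSet":
        if refl.phase is None:
            raise ValueError("reflection set has no phases")
        return cls(cell=refl.cell, spacegroup=refl.spacegroup,
                   hkl=refl.hkl.copy(), phase=refl.phase.copy(),
                   weight=weight, F=None if refl.F is None else refl.F.copy())


def _canonicalize(ps: PhaseSet):
    """Map indices to the canonical asymmetric-unit representative and
    transform phases accordingly (phi(hR) = phi(h) - 360 h.t; Friedel
    negates)."""
    sg = SpaceGroupInfo(ps.spacegroup)
    hkl = ps.hkl
    eq = sg.equivalent_hkl(hkl)                     # (2*n_ops, n, 3)
    big = int(np.abs(eq).max()) + 1 if eq.size else 1
    key = (eq[..., 0] * big + eq[..., 1]) * (2 * big) + eq[..., 2]
    best = np.argmax(key, axis=0)
    n_ops = sg.n_ops
    op_idx = best % n_ops
    friedel = best >= n_ops
    shift = np.einsum("nj,nj->n", hkl.astype(float),
                      sg.translations[op_idx])
    phase = ps.phase - 360.0 * shift
    phase = np.where(friedel, -phase, phase) % 360.0
    new_hkl = eq[best, np.arange(len(hkl))]
    return new_hkl, phase


def _origin_shift_candidates(sg: SpaceGroupInfo, n_cont: int = 24):
    discrete, cont = sg.allowed_origin_shifts()
    axes = []
    for ax in range(3):
        if cont[ax]:
            axes.append(np.arange(n_cont) / float(n_cont))
        else:
            axes.append(np.array([0.0]))
    g = np.meshgrid(*axes, indexing="ij")
    cont_grid = np.stack([a.ravel() for a in g], axis=1)
    return np.concatenate([d[None, :] + cont_grid for d in discrete]), cont


def _circular_abs(delta_deg: np.ndarray) -> np.ndarray:
    return 180.0 - np.abs(180.0 - np.mod(delta_deg, 360.0))


def wmpe(test: PhaseSet, reference: PhaseSet, n_cont: int = 24,
         polish: bool = True) -> float:
    """Weighted mean phase error in degrees.

    wMPE = sum w |dphi|_circ / sum w over the common index set, minimised
    over all allowed origin shifts of the space group and the
    enantiomorph flip (negated phases).  Weights come from the test set's
    figures of merit (equal weights when absent).
    """
    ta_hkl, ta_phi = _canonicalize(test)
    rb_hkl, rb_phi = _canonicalize(reference)
    lut = {tuple(h): i for i, h in enumerate(map(tuple, rb_hkl))}
    pairs = [(i, lut[tuple(h)]) for i, h in enumerate(map(tuple, ta_hkl))
             if tuple(h) in lut]
    if not pairs:
        raise ValueError("no common reflections between phase sets")
    ia, ib = np.array(pairs).T
    hkl = ta_hkl[ia].astype(float)
    w = test.weight[ia]
    if w.sum() <= 0:
        w = np.ones_like(w)
    phi_t, phi_r = ta_phi[ia], rb_phi[ib]
    sg = SpaceGroupInfo(test.spacegroup)
    shifts, cont = _origin_shift_candidates(sg, n_cont)
    wsum = w.sum()

    def mean_err(delta_rows):
        return (_circular_abs(delta_rows) @ w) / wsum

    best = 360.0
    best_arg = None
    for flip in (1.0, -1.0):
        d0 = flip * phi_t - phi_r
        for lo in range(0, len(shifts), 2048):
            sl = shifts[lo:lo + 2048]
            errs = mean_err(d0[None, :] - 360.0 * (sl @ hkl.T))
            i = int(np.argmin(errs))
            if errs[i] < best:
                best = float(errs[i])
                best_arg = (flip, sl[i])
    if polish and any(cont) and best_arg is not None:
        flip, t0 = best_arg
        free = np.where(cont)[0]
        d0 = flip * phi_t - phi_r

        def f(x):
            t = t0.copy()
            t[free] = x
            return mean_err((d0 - 360.0 * (hkl @ t))[None, :])[0]

        res = minimize(f, t0[free], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-4})
        best = min(best, float(res.fun))
    return best


def amp_cc(a: np.ndarray, b: np.ndarray) -> float:
    """100 x Pearson correlation of two amplitude arrays on a common set."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need matched amplitude arrays of length >= 3")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        import warnings
        warnings.warn("zero variance in amplitude correlation")
        return 0.0
    return float(100.0 * np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


# -- Fourier synthesis ------------------------------------------------------

@dataclass
class MapGrid:
    """Real-space map on a cell-covering grid, standardised to sigma units.

    ``values`` has mean 0 and standard deviation 1; ``raw`` keeps the
    unstandardised synthesis (useful for numerical round-trips).
    """

    values: np.ndarray
    cell: tuple
    spacegroup: str
    raw: np.ndarray | None = None

    @property
    def shape(self):
        return self.values.shape

    def value_at_frac(self, frac) -> float:
        """Trilinear interpolation with periodic wrapping."""
        frac = np.asarray(frac, dtype=float) % 1.0
        dims = np.array(self.values.shape)
        x = frac * dims
        i0 = np.floor(x).astype(int) % dims
        f = x - np.floor(x)
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    idx = ((i0[0] + dx) % dims[0], (i0[1] + dy) % dims[1],
                           (i0[2] + dz) % dims[2])
                    wgt = ((f[0] if dx else 1 - f[0])
                           * (f[1] if dy else 1 - f[1])
                           * (f[2] if dz else 1 - f[2]))
                    out += wgt * self.values[idx]
        return float(out)

    def value_at_cart(self, xyz) -> float:
        M = orthogonalization_matrix(self.cell)
        return self.value_at_frac(np.asarray(xyz, float) @ np.linalg.inv(M).T)

    def write_ccp4(self, path) -> None:
        import gemmi
        from .symmetry import SUPPORTED_SPACEGROUPS, normalize_symbol
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(
            self.values, dtype=np.float32))
        m.grid.unit_cell = gemmi.UnitCell(*self.cell)
        m.grid.spacegroup = gemmi.SpaceGroup(
            SUPPORTED_SPACEGROUPS[normalize_symbol(self.spacegroup)])
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))


def _grid_dims(cell, spacegroup, spacing: float):
    sg = SpaceGroupInfo(spacegroup)
    factors = sg.grid_factors()
    M = orthogonalization_matrix(cell)
    lens = np.linalg.norm(M, axis=0)
    dims = []
    for ln, fac in zip(lens, factors):
        n = max(4, int(np.ceil(ln / spacing)))
        step = int(np.lcm(int(fac), 2))
        n = ((n + step - 1) // step) * step
        dims.append(n)
    return tuple(dims)


def fourier_map(cell, spacegroup, hkl, F_complex, spacing: float | None = None,
                dims=None) -> MapGrid:
    """Inverse Fourier synthesis of a unique-reflection list onto a grid.

    The unique list is symmetry-expanded (including Friedel mates) before
    the FFT; default grid spacing is d_min/3.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    F_complex = np.asarray(F_complex, dtype=complex)
    if np.any(~np.isfinite(F_complex)):
        raise ValueError("missing or non-finite coefficients")
    sg = SpaceGroupInfo(spacegroup)
    if dims is None:
        from .diffraction import d_spacings
        dmin = float(d_spacings(cell, hkl).min())
        spacing = spacing if spacing is not None else dmin / 3.0
        dims = _grid_dims(cell, spacegroup, spacing)
    grid = np.zeros(dims, dtype=complex)
    filled = np.zeros(dims, dtype=bool)
    for R, t in zip(sg.rotations, sg.translations):
        h2 = hkl @ R
        ph = np.exp(-2j * np.pi * (hkl.astype(float) @ t))
        for sign in (1, -1):
            hh = sign * h2
            vals = (F_complex * ph) if sign == 1 else np.conj(F_complex * ph)
            idx = tuple((hh % dims).T)
            grid[idx] = vals
            filled[idx] = True
    # crystallographic convention rho(x) ~ sum_h F(h) exp(-2 pi i h.x);
    # numpy's ifftn uses the opposite sign, hence the conjugate
    rho = np.fft.ifftn(np.conj(grid)).real * np.prod(dims)
    mean, sd = rho.mean(), rho.std()
    if sd == 0:
        # identically-zero synthesis (e.g. Fo = Fc exactly): zero-sigma map
        return MapGrid(values=rho - mean, cell=tuple(cell),
                       spacegroup=sg.symbol, raw=rho)
    return MapGrid(values=(rho - mean) / sd, cell=tuple(cell),
                   spacegroup=sg.symbol, raw=rho)


def difference_map(fobs: np.ndarray, fcalc: ReflectionSet,
                   kind: str = "fo-fc", weight=None,
                   spacing: float | None = None) -> MapGrid:
    """Difference Fourier synthesis with model phases.

    ``fcalc`` supplies |Fc| and phases; ``fobs`` the observed amplitudes
    on the same index set.  ``kind='2mfo-fc'`` uses (2 m |Fo| - |Fc|)
    coefficients, ``'fo-fc'`` uses m |Fo| - |Fc|; m defaults to 1.
    """
    if fcalc.phase is None or fcalc.F is None:
        raise ValueError("calculated amplitudes and phases required")
    fobs = np.asarray(fobs, dtype=float)
    if len(fobs) != fcalc.n:
        raise ValueError("observed amplitudes do not match index set")
    m = np.ones(fcalc.n) if weight is None else np.clip(
        np.asarray(weight, float), 0.0, 1.0)
    kind_l = kind.lower().replace("_", "-").replace("2mfo-fc", "2mfofc")
    if kind_l in ("fo-fc", "fofc"):
        amp = m * fobs - fcalc.F
    elif kind_l in ("2mfofc", "2mfo-fc", "2mfofc"):
        amp = 2.0 * m * fobs - fcalc.F
    else:
        raise ValueError(f"unknown map kind {kind!r}")
    coeff = amp * np.exp(1j * np.deg2rad(fcalc.phase))
    return fourier_map(fcalc.cell, fcalc.spacegroup, fcalc.hkl, coeff,
                       spacing=spacing)


def omit_peak_height(model_without_feature, data: ReflectionSet,
                     feature_position, table=None,
                     spacing: float | None = None) -> float:
    """Fo-Fc difference-map value (sigma units) at an omitted feature.

    ``data`` provides observed amplitudes (|F| or sqrt(I)); phases come
    from the omit model.  Positions outside the cell wrap by lattice
    translation.
    """
    fcalc = structure_factors(model_without_feature, data, table)
    dmap = difference_map(data.amplitudes(), fcalc, kind="fo-fc",
                          spacing=spacing)
    return dmap.value_at_cart(np.asarray(feature_position, dtype=float))
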