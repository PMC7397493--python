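"""Reflection handling and electron-scattering structure factors.

Conventions used throughout the package:

* ``s`` denotes sin(theta)/lambda = 1/(2d) in inverse Angstrom; electron
  form factors are 5-Gaussian sums f(s) = sum_i a_i exp(-b_i s^2) (Peng
  parameterisation for neutral atoms) and the Debye-Waller factor is
  exp(-B s^2).
* Structure factors are direct sums over all atoms and all symmetry
  operators — exactness over speed at desk scale; no FFT, no bulk
  solvent, no anisotropy.
* Unique reflections carry a canonical index representative (Friedel
  pairs merged) defined in :mod:`microshred.symmetry`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import gemmi

from .symmetry import SpaceGroupInfo

__all__ = [
    "FormFactorTable",
    "ReflectionSet",
    "LTestResult",
    "UnknownElementError",
    "orthogonalization_matrix",
    "electron_form_factor",
    "generate_reflections",
    "structure_factors",
    "normalize_E",
    "l_test",
    "read_reflections",
    "write_reflections_tsv",
]


class UnknownElementError(KeyError):
    """Element has no electron form-factor entry (no silent X-ray fallback)."""


def orthogonalization_matrix(cell) -> np.ndarray:
    """3x3 matrix whose columns are the cell vectors in Cartesian Angstrom."""
    uc = gemmi.UnitCell(*cell)
    return np.array(uc.orth.mat.tolist(), dtype=float)


def scattering_vectors(cell, hkl: np.ndarray) -> np.ndarray:
    """Cartesian reciprocal vectors (|s*| = 1/d), one row per reflection."""
    M = orthogonalization_matrix(cell)
    return np.atleast_2d(hkl).astype(float) @ np.linalg.inv(M)


def d_spacings(cell, hkl: np.ndarray) -> np.ndarray:
    s = scattering_vectors(cell, hkl)
    return 1.0 / np.linalg.norm(s, axis=1)


# -- electron form factors --------------------------------------------------

class FormFactorTable:
    """Five-Gaussian elastic electron scattering factors, f(s) in Angstrom.

    Coefficients default to the Peng neutral-atom parameterisation shipped
    with gemmi; entries can be overridden or supplied directly.
    """

    def __init__(self, coefficients: dict | None = None):
        self._coef = {}
        if coefficients:
            for el, (a, b) in coefficients.items():
                a, b = np.asarray(a, float), np.asarray(b, float)
                if a.shape != (5,) or b.shape != (5,):
                    raise ValueError("expected 5 Gaussian (a, b) pairs")
                self._coef[el.capitalize()] = (a, b)

    def coefficients(self, element: str):
        el = str(element).capitalize()
        if el not in self._coef:
            gel = gemmi.Element(el)
            if gel.name != el or gel.atomic_number == 0:
                raise UnknownElementError(
                    f"no electron form factor for element {element!r}")
            c = gel.c4322
            a, b = np.asarray(c.a, float), np.asarray(c.b, float)
            if not np.any(a):
                raise UnknownElementError(
                    f"no electron form factor for element {element!r}")
            self._coef[el] = (a, b)
        return self._coef[el]

    def __contains__(self, element) -> bool:
        try:
            self.coefficients(element)
            return True
        except UnknownElementError:
            return False


def electron_form_factor(element: str, s, table: FormFactorTable | None = None):
    """f(s) = sum_i a_i exp(-b_i s^2) with s = sin(theta)/lambda [1/A]."""
    table = table or FormFactorTable()
    a, b = table.coefficients(element)
    s2 = np.square(np.asarray(s, dtype=float))
    return np.einsum("i,i...->...", a, np.exp(-np.multiply.outer(b, s2)))


# -- reflection container ---------------------------------------------------

@dataclass
class ReflectionSet:
    """Unique reflections with cell, symmetry and per-reflection data.

    Optional arrays (``I``, ``sigI``, ``F``, ``phase``, ``E``) are None
    when absent.  ``F`` is an amplitude; ``phase`` is in degrees.
    """

    cell: tuple
    spacegroup: str
    hkl: np.ndarray
    I: np.ndarray | None = None
    sigI: np.ndarray | None = None
    F: np.ndarray | None = None
    phase: np.ndarray | None = None
    E: np.ndarray | None = None
    centric: np.ndarray | None = None
    epsilon: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        sg = self.sg_info
        if self.centric is None:
            self.centric = sg.centric_flags(self.hkl)
        if self.epsilon is None:
            self.epsilon = sg.epsilon_factors(self.hkl)
        for attr in ("I", "sigI", "F", "phase", "E"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))

    @property
    def sg_info(self) -> SpaceGroupInfo:
        return SpaceGroupInfo(self.spacegroup)

    @property
    def n(self) -> int:
        return len(self.hkl)

    def d(self) -> np.ndarray:
        return d_spacings(self.cell, self.hkl)

    def stol(self) -> np.ndarray:
        """sin(theta)/lambda = 1/(2d)."""
        return 0.5 / self.d()

    @property
    def dmin(self) -> float:
        return float(self.d().min())

    @property
    def dmax(self) -> float:
        return float(self.d().max())

    def subset(self, mask) -> "ReflectionSet":
        kw = {}
        for attr in ("I", "sigI", "F", "phase", "E", "centric", "epsilon"):
            v = getattr(self, attr)
            kw[attr] = None if v is None else v[mask]
        return ReflectionSet(cell=self.cell, spacegroup=self.spacegroup,
                             hkl=self.hkl[mask], **kw)

    def complex_F(self) -> np.ndarray:
        if self.F is None or self.phase is None:
            raise ValueError("amplitudes and phases required")
        return self.F * np.exp(1j * np.deg2rad(self.phase))

    def amplitudes(self) -> np.ndarray:
        """|F| from F if present, else sqrt(max(I,0))."""
        if self.F is not None:
            return np.abs(self.F)
        if self.I is not None:
            return np.sqrt(np.clip(self.I, 0.0, None))
        raise ValueError("no amplitudes or intensities present")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.hkl, columns=["h", "k", "l"])
        for attr in ("I", "sigI", "F", "phase", "E"):
            v = getattr(self, attr)
            if v is not None:
                df[attr] = v
        df["centric"] = self.centric
        df["epsilon"] = self.epsilon
        return df


# -- reflection generation --------------------------------------------------

def generate_reflections(cell, spacegroup, dmin: float, dmax: float = 1e6
                         ) -> ReflectionSet:
    """Symmetry-unique reflection indices with dmin <= d <= dmax.

    Friedel pairs are merged, systematic absences excluded, centric and
    epsilon flags set from the space-group operators.
    """
    if dmin <= 0 or dmin > dmax:
        raise ValueError("need 0 < dmin <= dmax")
    sg = SpaceGroupInfo(spacegroup)
    M = orthogonalization_matrix(cell)
    axis_len = np.linalg.norm(M, axis=0)
    hmax = np.floor(axis_len / dmin).astype(int)
    grids = np.meshgrid(*[np.arange(-m, m + 1) for m in hmax], indexing="ij")
    hkl = np.stack([g.ravel() for g in grids], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = d_spacings(cell, hkl)
    hkl = hkl[(d >= dmin) & (d <= dmax)]
    hkl = sg.reduce_to_asu(hkl)
    hkl = np.unique(hkl, axis=0)
    hkl = hkl[~sg.systematically_absent(hkl)]
    # stable ordering: by resolution, then index
    d = d_spacings(cell, hkl)
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0], -d))
    return ReflectionSet(cell=tuple(cell), spacegroup=sg.symbol, hkl=hkl[order])


# -- structure factors ------------------------------------------------------

def atom_scattering_weights(model, stol: np.ndarray,
                            table: FormFactorTable | None = None) -> np.ndarray:
    """(n_refl, n_atoms) weights: occ * f_el(s) * exp(-B s^2)."""
    table = table or FormFactorTable()
    s2 = np.square(stol)
    W = np.empty((len(stol), model.n_atoms))
    for el in np.unique(model.element.astype(str)):
        f = electron_form_factor(el, stol, table)
        idx = np.where(model.element.astype(str) == el)[0]
        W[:, idx] = f[:, None]
    W *= model.occ[None, :]
    W *= np.exp(-np.outer(s2, model.b_factor))
    return W


def structure_factors(model, refl: ReflectionSet,
                      table: FormFactorTable | None = None,
                      chunk: int = 4096) -> ReflectionSet:
    """Direct-summation electron structure factors over all symmetry copies.

    F(h) = sum_ops sum_atoms occ f(s) exp(-B s^2) exp(2 pi i h.(R x + t)).
    Returns a copy of ``refl`` with amplitude ``F`` and ``phase`` set.
    """
    sg = refl.sg_info
    M = orthogonalization_matrix(refl.cell)
    frac = model.xyz @ np.linalg.inv(M).T
    Fc = np.zeros(refl.n, dtype=complex)
    stol = refl.stol()
    for lo in range(0, refl.n, chunk):
        sl = slice(lo, min(lo + chunk, refl.n))
        W = atom_scattering_weights(model, stol[sl], table)
        h = refl.hkl[sl].astype(float)
        acc = np.zeros(h.shape[0], dtype=complex)
        for R, t in zip(sg.rotations, sg.translations):
            hr = h @ R
            phase = hr @ frac.T + (h @ t)[:, None]
            acc += np.einsum("ra,ra->r", W, np.exp(2j * np.pi * phase))
        Fc[sl] = acc
    out = replace(refl)
    out.F = np.abs(Fc)
    out.phase = np.rad2deg(np.angle(Fc)) % 360.0
    return out


# -- normalized structure factors -------------------------------------------

def _equal_count_shells(s2: np.ndarray, n_shells: int) -> np.ndarray:
    order = np.argsort(s2, kind="stable")
    shell = np.empty(len(s2), dtype=int)
    bounds = np.linspace(0, len(s2), n_shells + 1).astype(int)
    for i in range(n_shells):
        shell[order[bounds[i]:bounds[i + 1]]] = i
    return shell


def normalize_E(refl: ReflectionSet, n_shells: int = 20) -> ReflectionSet:
    """Normalized structure factors: E^2 = I / (eps * <I/eps>_shell).

    Shells are equal-count in s^2; within each shell <|E|^2> = 1 exactly.
    Negative measured intensities are clipped to zero before averaging
    (they carry no amplitude information here), which keeps the per-shell
    identity exact for noisy input.  Shells whose mean intensity is
    non-positive are merged with their lower-resolution neighbour.
    """
    if refl.I is not None:
        inten = np.clip(refl.I, 0.0, None)
    elif refl.F is not None:
        inten = refl.F ** 2
    else:
        raise ValueError("intensities or amplitudes required")
    n_shells = max(1, min(n_shells, refl.n))
    s2 = np.square(refl.stol())
    shell = _equal_count_shells(s2, n_shells)
    ratio = inten / refl.epsilon
    # merge non-positive-mean shells downwards until all means positive
    for _ in range(n_shells):
        means = np.array([ratio[shell == i].mean() if np.any(shell == i)
                          else np.nan for i in range(n_shells)])
        bad = [i for i in range(n_shells)
               if np.any(shell == i) and not means[i] > 0]
        if not bad:
            break
        i = bad[0]
        j = i - 1 if i > 0 else i + 1
        shell[shell == i] = j
    shell_mean = np.zeros(refl.n)
    for i in np.unique(shell):
        m = shell == i
        shell_mean[m] = ratio[m].mean()
    e2 = ratio / shell_mean
    out = replace(refl)
    out.E = np.sqrt(np.clip(e2, 0.0, None))
    return out


# -- twinning L-test --------------------------------------------------------

_L_OFFSETS = ((0, 0, 1), (0, 1, 0), (1, 0, 0),
              (0, 0, 2), (0, 2, 0), (2, 0, 0),
              (0, 1, 1), (1, 0, 1), (1, 1, 0))


@dataclass
class LTestResult:
    """Moments of L = (I1 - I2)/(I1 + I2) over unrelated neighbour pairs."""

    mean_abs_l: float
    mean_l2: float
    n_pairs: int
    # analytic references for reporting
    untwinned: tuple = (0.5, 1.0 / 3.0)
    perfect_twin: tuple = (0.375, 0.2)

    @property
    def twinned(self) -> bool:
        """Closer to the perfect-twin expectation than to untwinned."""
        return abs(self.mean_abs_l - 0.375) < abs(self.mean_abs_l - 0.5)


def l_test(refl: ReflectionSet, min_pairs: int = 500) -> LTestResult:
    """Padilla-Yeates style twinning test on intensity ratios.

    Pairs are (h, k, l) vs (h, k, l) + delta for small non-symmetric
    offsets delta, both reduced to the canonical asymmetric unit; pairs
    mapping to the same unique reflection are skipped.
    """
    if refl.I is None:
        raise ValueError("intensities required for the L-test")
    sg = refl.sg_info
    lut = {tuple(h): i for i, h in enumerate(map(tuple, refl.hkl))}
    seen = set()
    i1, i2 = [], []
    for delta in _L_OFFSETS:
        partner = sg.reduce_to_asu(refl.hkl + np.array(delta))
        for a, p in enumerate(map(tuple, partner)):
            b = lut.get(p)
            if b is None or b == a:
                continue
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            i1.append(refl.I[a])
            i2.append(refl.I[b])
    i1, i2 = np.array(i1), np.array(i2)
    denom = i1 + i2
    ok = denom != 0
    L = (i1[ok] - i2[ok]) / denom[ok]
    if len(L) < min_pairs:
        warnings.warn(f"L-test used only {len(L)} pairs (< {min_pairs})")
    if len(L) == 0:
        raise ValueError("no usable L-test pairs")
    return LTestResult(mean_abs_l=float(np.mean(np.abs(L))),
                       mean_l2=float(np.mean(L ** 2)), n_pairs=len(L))


# -- reflection file IO -----------------------------------------------------

_TSV_COLS = ["h", "k", "l", "I", "sigI", "F", "phase"]


def write_reflections_tsv(refl: ReflectionSet, path) -> None:
    """Plain whitespace table: h k l I sigI [F phase]. Bit-exact round trip."""
    cols = ["h", "k", "l"]
    data = {"h": refl.hkl[:, 0], "k": refl.hkl[:, 1], "l": refl.hkl[:, 2]}
    for attr in ("I", "sigI", "F", "phase"):
        v = getattr(refl, attr)
        if v is not None:
            data[attr] = v
            cols.append(attr)
    df = pd.DataFrame(data, columns=cols)
    with open(path, "w") as fh:
        fh.write("# cell " + " ".join(repr(float(x)) for x in refl.cell) + "\n")
        fh.write(f"# spacegroup {refl.spacegroup}\n")
        fh.write("\t".join(cols) + "\n")
        for row in df.itertuples(index=False):
            vals = [str(int(v)) for v in row[:3]]
            vals += [repr(float(v)) for v in row[3:]]
            fh.write("\t".join(vals) + "\n")


def _read_tsv(path, cell, spacegroup):
    header_cell, header_sg = cell, spacegroup
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("# cell"):
            header_cell = tuple(float(x) for x in stripped.split()[2:8])
        elif stripped.startswith("# spacegroup"):
            header_sg = stripped.split()[2]
        elif stripped.startswith("#") or not stripped:
            pass
        else:
            break
        body_start += 1
    has_header = lines[body_start].lstrip()[0].isalpha()
    df = pd.read_csv(path, sep=r"\s+", skiprows=body_start,
                     header=0 if has_header else None,
                     float_precision="round_trip")
    if not has_header or "h" not in df.columns:
        df.columns = _TSV_COLS[:df.shape[1]]
    if header_cell is None or header_sg is None:
        raise ValueError("cell and spacegroup required (no header in file)")
    kw = {c: df[c].to_numpy() for c in ("I", "sigI", "F", "phase")
          if c in df.columns}
    return ReflectionSet(cell=tuple(header_cell), spacegroup=header_sg,
                         hkl=df[["h", "k", "l"]].to_numpy(int), **kw)


def _read_mtz(path):
    mtz = gemmi.read_mtz_file(str(path))
    hkl = np.array([mtz.column_with_label(x).array for x in "HKL"],
                   dtype=int).T
    def first(types, labels=()):
        for lab in labels:
            col = mtz.column_with_label(lab)
            if col is not None:
                return np.array(col.array, dtype=float)
        for col in mtz.columns:
            if col.type in types:
                return np.array(col.array, dtype=float)
        return None
    I = first("J", ("IMEAN", "I"))
    sigI = first("Q", ("SIGIMEAN", "SIGI"))
    F = first("F", ("FP", "F"))
    phase = first("P", ("PHIB", "PHI"))
    c = mtz.cell
    return ReflectionSet(cell=(c.a, c.b, c.c, c.alpha, c.beta, c.gamma),
                         spacegroup=mtz.spacegroup.hm, hkl=hkl,
                         I=I, sigI=sigI, F=F, phase=phase)


def _read_sf_mmcif(path):
    doc = gemmi.cif.read(str(path))
    rblocks = gemmi.as_refln_blocks(doc)
    if not rblocks:
        raise ValueError(f"no reflection data in {path}")
    rb = rblocks[0]
    hkl = np.array(rb.make_miller_array(), dtype=int)
    def col(name):
        v = rb.make_float_array(name)
        v = np.asarray(v, dtype=float)
        return None if np.all(np.isnan(v)) else v
    c = rb.cell
    sym = rb.spacegroup.hm if rb.spacegroup else None
    return ReflectionSet(cell=(c.a, c.b, c.c, c.alpha, c.beta, c.gamma),
                         spacegroup=sym, hkl=hkl,
                         I=col("intensity_meas"), sigI=col("intensity_sigma"),
                         F=col("F_meas_au"), phase=col("phase_calc"))


def read_reflections(path, format: str = "auto", cell=None, spacegroup=None
                     ) -> ReflectionSet:
    """Read reflection data from MTZ, structure-factor mmCIF, or TSV."""
    p = str(path)
    if format == "auto":
        if p.endswith(".mtz"):
            format = "mtz"
        elif p.endswith((".cif", ".ent")):
            format = "mmcif"
        else:
            format = "tsv"
    if format == "mtz":
        return _read_mtz(p)
    if format == "mmcif":
        return _read_sf_mmcif(p)
    if format == "tsv":
        return _read_tsv(p, cell, spacegroup)
    raise ValueError(f"unknown reflection format {format!r}")
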