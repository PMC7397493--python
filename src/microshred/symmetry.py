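"""Space-group bookkeeping for the handful of groups the toolkit supports.

Operator tables, centric/epsilon flags and systematic absences come from
gemmi; this module adds the vectorised helpers the rest of the package
needs (canonical asymmetric-unit reduction of Miller indices, Cartesian
point-group rotations, allowed origin shifts and Cheshire translations).

Only the space groups needed for protein nanocrystal work at desk scale
are supported: P1, P21, P212121, P43212 and its enantiomorph P41212.
Anything else is rejected loudly rather than half-supported.
"""

from __future__ import annotations

import numpy as np
import gemmi

__all__ = [
    "SpaceGroupError",
    "SpaceGroupInfo",
    "normalize_symbol",
    "SUPPORTED_SPACEGROUPS",
]

# short symbol -> Hermann-Mauguin name understood by gemmi
SUPPORTED_SPACEGROUPS = {
    "P1": "P 1",
    "P21": "P 1 21 1",
    "P212121": "P 21 21 21",
    "P43212": "P 43 21 2",
    "P41212": "P 41 21 2",
}

# Allowed origin shifts (fractional), one tuple per discrete shift.  Axes
# along which the origin is continuously free are listed separately; phase
# comparisons must search those numerically.
_ORIGIN_SHIFTS = {
    "P1": ([(0.0, 0.0, 0.0)], (True, True, True)),
    "P21": ([(0.0, 0.0, 0.0), (0.5, 0.0, 0.0), (0.0, 0.0, 0.5), (0.5, 0.0, 0.5)],
            (False, True, False)),
    "P212121": ([(x, y, z) for x in (0.0, 0.5) for y in (0.0, 0.5) for z in (0.0, 0.5)],
                (False, False, False)),
    "P43212": ([(0.0, 0.0, 0.0), (0.5, 0.5, 0.0), (0.0, 0.0, 0.5), (0.5, 0.5, 0.5)],
               (False, False, False)),
    "P41212": ([(0.0, 0.0, 0.0), (0.5, 0.5, 0.0), (0.0, 0.0, 0.5), (0.5, 0.5, 0.5)],
               (False, False, False)),
}

# Cheshire cell: a fundamental domain of the allowed-origin-shift group —
# the box a translation search must cover (all other translations are
# equivalent by an origin shift).  For the tetragonal groups the shift
# group {(0,0,0),(1/2,1/2,0),(0,0,1/2),(1/2,1/2,1/2)} has order 4, so the
# domain is (1, 1/2, 1/2): the x,y-coupled shift identifies (x,y) with
# (x+1/2, y+1/2), which a half-open box in both x and y would not cover.
# None marks a continuously free axis (searching it is pointless:
# amplitudes do not depend on position along it).
_CHESHIRE = {
    "P1": (None, None, None),
    "P21": (0.5, None, 0.5),
    "P212121": (0.5, 0.5, 0.5),
    "P43212": (1.0, 0.5, 0.5),
    "P41212": (1.0, 0.5, 0.5),
}


class SpaceGroupError(ValueError):
    """Unknown or unsupported space-group symbol."""


def normalize_symbol(symbol: str) -> str:
    """Return the canonical short symbol (e.g. ``'P43212'``) or raise."""
    key = str(symbol).replace(" ", "").replace("_", "")
    for short, hm in SUPPORTED_SPACEGROUPS.items():
        if key.upper() == short.upper() or key == hm.replace(" ", ""):
            return short
    raise SpaceGroupError(
        f"unsupported space group {symbol!r}; supported symbols: "
        + ", ".join(SUPPORTED_SPACEGROUPS)
    )


class SpaceGroupInfo:
    """Symmetry operations and reflection bookkeeping for one space group."""

    def __init__(self, symbol: str):
        self.symbol = normalize_symbol(symbol)
        self.gemmi_sg = gemmi.SpaceGroup(SUPPORTED_SPACEGROUPS[self.symbol])
        self._ops = self.gemmi_sg.operations()
        rots, trans = [], []
        for op in self._ops:
            rots.append(np.array(op.rot, dtype=int) // 24)
            trans.append(np.array(op.tran, dtype=float) / 24.0)
        self.rotations = np.array(rots)          # (n_ops, 3, 3) integer
        self.translations = np.array(trans)      # (n_ops, 3) fractional

    # -- basic properties -------------------------------------------------
    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpaceGroupInfo({self.symbol!r}, {self.n_ops} ops)"

    # -- reflection bookkeeping -------------------------------------------
    def equivalent_hkl(self, hkl: np.ndarray) -> np.ndarray:
        """All symmetry equivalents incl. Friedel mates, shape (2*n_ops, n, 3).

        Reciprocal-space equivalence: h' = h R for each operator rotation R.
        """
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        eq = np.einsum("nj,mjk->mnk", hkl, self.rotations)
        return np.concatenate([eq, -eq], axis=0)

    def reduce_to_asu(self, hkl: np.ndarray) -> np.ndarray:
        """Canonical representative per reflection (Friedel pairs merged).

        The representative is the lexicographically largest equivalent
        index triple — a convention, consistent across the package.
        """
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        eq = self.equivalent_hkl(hkl)                     # (m, n, 3)
        big = int(np.abs(eq).max()) + 1 if eq.size else 1
        key = (eq[..., 0] * big + eq[..., 1]) * (2 * big) + eq[..., 2]
        best = np.argmax(key, axis=0)
        return eq[best, np.arange(hkl.shape[0])]

    def centric_flags(self, hkl: np.ndarray) -> np.ndarray:
        arr = np.ascontiguousarray(np.atleast_2d(hkl), dtype=np.int32)
        return np.asarray(self._ops.centric_flag_array(arr), dtype=bool)

    def epsilon_factors(self, hkl: np.ndarray) -> np.ndarray:
        arr = np.ascontiguousarray(np.atleast_2d(hkl), dtype=np.int32)
        return np.asarray(self._ops.epsilon_factor_without_centering_array(arr),
                          dtype=int)

    def systematically_absent(self, hkl: np.ndarray) -> np.ndarray:
        arr = np.ascontiguousarray(np.atleast_2d(hkl), dtype=np.int32)
        return np.asarray(self._ops.systematic_absences(arr), dtype=bool)

    def grid_factors(self) -> tuple:
        """Required divisibility of real-space grid dimensions."""
        return tuple(self._ops.find_grid_factors())

    # -- real-space symmetry ----------------------------------------------
    def cartesian_rotations(self, orth: np.ndarray) -> np.ndarray:
        """Point-group rotations as Cartesian 3x3 matrices.

        ``orth`` is the orthogonalisation matrix (columns = cell vectors).
        For the orthogonal/tetragonal cells supported here the result is
        orthonormal.
        """
        orth = np.asarray(orth, dtype=float)
        inv = np.linalg.inv(orth)
        return np.einsum("ij,mjk,kl->mil", orth, self.rotations.astype(float), inv)

    # -- origin ambiguity --------------------------------------------------
    def allowed_origin_shifts(self):
        """(list of discrete fractional shifts, tuple of continuous-axis flags)."""
        shifts, cont = _ORIGIN_SHIFTS[self.symbol]
        return [np.array(s) for s in shifts], cont

    def cheshire_translations(self, n: int = 24) -> np.ndarray:
        """Fractional translation grid covering the Cheshire cell.

        ``n`` is the number of grid divisions per full cell edge; free axes
        (where |F| is position-independent) contribute a single zero sample.
        """
        axes = []
        for extent in _CHESHIRE[self.symbol]:
            if extent is None:
                axes.append(np.array([0.0]))
            else:
                k = max(1, int(round(n * extent)))
                axes.append(np.arange(k) / float(n))
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)
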