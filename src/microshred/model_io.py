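"""Coordinate-model handling: reading/writing, polyalanine conversion,
and least-squares superposition with core-Calpha trimming.

The in-memory container, :class:`StructureModel`, is deliberately flat —
parallel numpy arrays over atoms — because everything downstream
(structure factors, rotation search) consumes coordinate arrays, not an
object hierarchy.  gemmi does the file-format work.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import gemmi

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "Superposition",
    "FormatError",
    "EmptyModelError",
    "InsufficientPairsError",
    "read_structure",
    "write_structure",
    "to_polyalanine",
    "superpose",
]

AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "MSE", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL",
}

_CB_BOND = 1.532          # Calpha-Cbeta bond length, Angstrom
_CB_HALF_ANGLE = np.deg2rad(54.75)   # half the ideal tetrahedral angle


class FormatError(ValueError):
    """Coordinate file could not be parsed."""


class EmptyModelError(ValueError):
    """File parsed but contained no atoms."""


class InsufficientPairsError(ValueError):
    """Fewer than three paired Calpha atoms for superposition."""


@dataclass
class StructureModel:
    """Flat atom-table model: templates, fragments and ground truths alike.

    Arrays are parallel over atoms.  ``cell`` is (a, b, c, alpha, beta,
    gamma) in Angstrom/degrees when known; coordinates are Cartesian
    Angstrom always (fractionalisation lives in the diffraction module).
    """

    element: np.ndarray
    name: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain: np.ndarray
    xyz: np.ndarray
    occ: np.ndarray
    b_factor: np.ndarray
    icode: np.ndarray = None
    cell: tuple | None = None
    spacegroup: str | None = None

    def __post_init__(self):
        n = len(self.xyz)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(n, 3)
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.occ = np.asarray(self.occ, dtype=float)
        self.b_factor = np.asarray(self.b_factor, dtype=float)
        for attr in ("element", "name", "res_name", "chain"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        if self.icode is None:
            self.icode = np.full(n, "", dtype=object)
        else:
            self.icode = np.asarray(self.icode, dtype=object)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        if np.any((self.occ < 0) | (self.occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.b_factor < 0):
            raise ValueError("negative B factor")

    # -- basics -----------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    def copy(self) -> "StructureModel":
        return StructureModel(
            element=self.element.copy(), name=self.name.copy(),
            res_id=self.res_id.copy(), res_name=self.res_name.copy(),
            chain=self.chain.copy(), xyz=self.xyz.copy(),
            occ=self.occ.copy(), b_factor=self.b_factor.copy(),
            icode=self.icode.copy(), cell=self.cell, spacegroup=self.spacegroup,
        )

    def select(self, mask: np.ndarray) -> "StructureModel":
        mask = np.asarray(mask)
        return StructureModel(
            element=self.element[mask], name=self.name[mask],
            res_id=self.res_id[mask], res_name=self.res_name[mask],
            chain=self.chain[mask], xyz=self.xyz[mask],
            occ=self.occ[mask], b_factor=self.b_factor[mask],
            icode=self.icode[mask], cell=self.cell, spacegroup=self.spacegroup,
        )

    def ca_mask(self) -> np.ndarray:
        return np.array([n == "CA" for n in self.name], dtype=bool)

    def residue_keys(self) -> list:
        """Ordered unique (chain, res_id, icode) keys."""
        seen, out = set(), []
        for c, r, i in zip(self.chain, self.res_id, self.icode):
            k = (c, int(r), i)
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_mask(self, keys) -> np.ndarray:
        keyset = set(keys)
        return np.array(
            [(c, int(r), i) in keyset
             for c, r, i in zip(self.chain, self.res_id, self.icode)],
            dtype=bool)

    # -- gemmi conversion --------------------------------------------------
    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = "model"
        if self.cell is not None:
            st.cell = gemmi.UnitCell(*self.cell)
        if self.spacegroup is not None:
            from .symmetry import SUPPORTED_SPACEGROUPS, normalize_symbol
            st.spacegroup_hm = SUPPORTED_SPACEGROUPS[normalize_symbol(self.spacegroup)]
        model = gemmi.Model("1")
        chain_obj = {}
        res_obj = {}
        for j in range(self.n_atoms):
            cid = str(self.chain[j])
            if cid not in chain_obj:
                chain_obj[cid] = gemmi.Chain(cid)
                model.add_chain(chain_obj[cid])
                chain_obj[cid] = model[-1]
            ch = chain_obj[cid]
            rkey = (cid, int(self.res_id[j]), self.icode[j])
            if rkey not in res_obj:
                res = gemmi.Residue()
                res.name = str(self.res_name[j])
                res.seqid = gemmi.SeqId(int(self.res_id[j]),
                                        self.icode[j] if self.icode[j] else " ")
                ch.add_residue(res)
                res_obj[rkey] = ch[-1]
            res = res_obj[rkey]
            at = gemmi.Atom()
            at.name = str(self.name[j])
            at.element = gemmi.Element(str(self.element[j]))
            at.pos = gemmi.Position(*self.xyz[j])
            at.occ = float(self.occ[j])
            at.b_iso = float(self.b_factor[j])
            res.add_atom(at)
        st.add_model(model)
        st.setup_entities()
        return st

    @classmethod
    def from_gemmi(cls, st: gemmi.Structure) -> "StructureModel":
        rows = {k: [] for k in
                ("element", "name", "res_id", "res_name", "chain",
                 "xyz", "occ", "b", "icode")}
        if len(st) == 0:
            raise EmptyModelError("structure contains no model")
        model = st[0]
        for ch in model:
            for res in ch:
                # resolve alternate locations to the highest-occupancy copy
                best = {}
                for at in res:
                    key = at.name
                    if key not in best or at.occ > best[key].occ:
                        best[key] = at
                for at in best.values():
                    rows["element"].append(at.element.name)
                    rows["name"].append(at.name)
                    rows["res_id"].append(res.seqid.num)
                    rows["res_name"].append(res.name)
                    rows["chain"].append(ch.name)
                    rows["xyz"].append([at.pos.x, at.pos.y, at.pos.z])
                    rows["occ"].append(min(max(at.occ, 0.0), 1.0))
                    rows["b"].append(max(at.b_iso, 0.0))
                    icode = res.seqid.icode
                    rows["icode"].append(icode.strip() if icode else "")
        if not rows["xyz"]:
            raise EmptyModelError("structure contains no atoms")
        cell = None
        if st.cell and st.cell.a > 1.0:
            c = st.cell
            cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        return cls(element=rows["element"], name=rows["name"],
                   res_id=rows["res_id"], res_name=rows["res_name"],
                   chain=rows["chain"], xyz=np.array(rows["xyz"]),
                   occ=rows["occ"], b_factor=rows["b"], icode=rows["icode"],
                   cell=cell,
                   spacegroup=st.spacegroup_hm if st.spacegroup_hm else None)


@dataclass
class Superposition:
    """Rigid transform mapping mobile onto target: x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_aligned: int

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


# -- file IO ---------------------------------------------------------------

def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF coordinate file.

    Alternate locations are resolved to the highest-occupancy conformer;
    insertion codes are preserved.
    """
    path = str(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r} (pdb, mmcif, auto)")
    try:
        st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return StructureModel.from_gemmi(st)


def write_structure(model: StructureModel, path) -> None:
    """Write PDB (by .pdb extension) or mmCIF (.cif) with gemmi."""
    st = model.to_gemmi()
    path = str(path)
    if path.endswith(".cif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


# -- polyalanine conversion -------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O", "CB")


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cbeta at ideal tetrahedral geometry from backbone N, CA, C."""
    u_n = n - ca
    u_n /= np.linalg.norm(u_n)
    u_c = c - ca
    u_c /= np.linalg.norm(u_c)
    bis = u_n + u_c
    bis /= np.linalg.norm(bis)
    perp = np.cross(u_c, u_n)
    perp /= np.linalg.norm(perp)
    direction = -bis * np.cos(_CB_HALF_ANGLE) - perp * np.sin(_CB_HALF_ANGLE)
    return ca + _CB_BOND * direction


def to_polyalanine(model: StructureModel) -> StructureModel:
    """Strip a model to an all-alanine backbone (N, CA, C, O, CB).

    Waters, ligands and ions are removed.  Residues missing any of N, CA,
    C are dropped with a warning.  Glycine gets an ideal Cbeta; a missing
    carbonyl O is rebuilt in the N-CA-C plane.  Idempotent.
    """
    rows = {k: [] for k in ("element", "name", "res_id", "res_name", "chain",
                            "xyz", "occ", "b", "icode")}
    n_dropped = 0
    for key in model.residue_keys():
        mask = model.residue_mask([key])
        resname = model.res_name[mask][0]
        if resname not in AA3:
            continue
        atoms = {model.name[i]: i for i in np.where(mask)[0]}
        if not {"N", "CA", "C"} <= atoms.keys():
            n_dropped += 1
            logger.warning("dropping residue %s: incomplete backbone", key)
            continue
        coords = {nm: model.xyz[atoms[nm]] for nm in atoms}
        if "CB" not in coords:
            coords["CB"] = _ideal_cb(coords["N"], coords["CA"], coords["C"])
        if "O" not in coords:
            # place O along the bisector opposite N in the peptide plane
            u = coords["C"] - coords["CA"]
            u /= np.linalg.norm(u)
            v = coords["C"] - coords["N"]
            v /= np.linalg.norm(v)
            d = u + v
            d /= np.linalg.norm(d)
            coords["O"] = coords["C"] + 1.231 * d
        for nm in _BACKBONE:
            idx = atoms.get(nm)
            rows["element"].append(nm[0])
            rows["name"].append(nm)
            rows["res_id"].append(key[1])
            rows["res_name"].append("ALA")
            rows["chain"].append(key[0])
            rows["xyz"].append(coords[nm])
            rows["occ"].append(model.occ[idx] if idx is not None else 1.0)
            rows["b"].append(model.b_factor[idx] if idx is not None
                             else float(model.b_factor[atoms["CA"]]))
            rows["icode"].append(key[2])
    if not rows["xyz"]:
        raise EmptyModelError("no complete amino-acid residues to convert")
    if n_dropped:
        warnings.warn(f"to_polyalanine dropped {n_dropped} incomplete residue(s)")
    return StructureModel(element=rows["element"], name=rows["name"],
                          res_id=rows["res_id"], res_name=rows["res_name"],
                          chain=rows["chain"], xyz=np.array(rows["xyz"]),
                          occ=rows["occ"], b_factor=rows["b"],
                          icode=rows["icode"], cell=model.cell,
                          spacegroup=model.spacegroup)


# -- superposition ----------------------------------------------------------

def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rotation/translation (proper, det +1) and rmsd."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - cm, target - ct
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def _pair_ca(mobile: StructureModel, target: StructureModel, pairing: str):
    mob_ca = {(c, int(r), i): x for c, r, i, x, nm in zip(
        mobile.chain, mobile.res_id, mobile.icode, mobile.xyz, mobile.name)
        if nm == "CA"}
    tgt_ca = {(c, int(r), i): x for c, r, i, x, nm in zip(
        target.chain, target.res_id, target.icode, target.xyz, target.name)
        if nm == "CA"}
    if pairing == "by_residue_number":
        keys = [k for k in mob_ca if k in tgt_ca]
        A = np.array([mob_ca[k] for k in keys]).reshape(-1, 3)
        B = np.array([tgt_ca[k] for k in keys]).reshape(-1, 3)
    elif pairing == "sequence_alignment":
        # order-based pairing of Calpha traces (global, gap-free); adequate
        # for the polyalanine fragments this package produces
        mk, tk = list(mob_ca), list(tgt_ca)
        n = min(len(mk), len(tk))
        A = np.array([mob_ca[k] for k in mk[:n]]).reshape(-1, 3)
        B = np.array([tgt_ca[k] for k in tk[:n]]).reshape(-1, 3)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return A, B


def superpose(mobile: StructureModel, target: StructureModel,
              pairing: str = "by_residue_number",
              core_trim: bool = True, trim_cutoff: float = 3.0,
              max_trim_rounds: int = 10) -> Superposition:
    """Kabsch superposition of paired Calpha atoms.

    With ``core_trim`` (default), pairs further than ``trim_cutoff``
    Angstrom after fitting are discarded and the fit repeated until
    stable — a declared stand-in for the "core Calpha" trimming of
    secondary-structure-matching tools.
    """
    A, B = _pair_ca(mobile, target, pairing)
    if len(A) < 3:
        raise InsufficientPairsError(
            f"only {len(A)} paired Calpha atoms; need at least 3")
    keep = np.ones(len(A), dtype=bool)
    R, t, rmsd = _kabsch(A, B)
    if core_trim:
        for _ in range(max_trim_rounds):
            moved = A[keep] @ R.T + t
            dist = np.linalg.norm(moved - B[keep], axis=1)
            bad = dist > trim_cutoff
            if not bad.any() or (keep.sum() - bad.sum()) < 3:
                break
            idx = np.where(keep)[0][bad]
            keep[idx] = False
            R, t, rmsd = _kabsch(A[keep], B[keep])
        # re-admit pairs that fit the converged transform (the first
        # rounds can over-trim while outliers still skew the fit)
        dist_all = np.linalg.norm(A @ R.T + t - B, axis=1)
        readmit = dist_all <= trim_cutoff
        if readmit.sum() >= 3 and not np.array_equal(readmit, keep):
            keep = readmit
            R, t, rmsd = _kabsch(A[keep], B[keep])
    return Superposition(rotation=R, translation=t, rmsd=rmsd,
                         n_aligned=int(keep.sum()))
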