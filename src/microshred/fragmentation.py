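"""Fragment-library generation from a distant homologue template.

Two generation modes mirror common fragment-based molecular-replacement
practice:

* **sequential** — slide a window of 10-20 residues along the chain in
  steps of 4, extracting the window (or omitting it from the template).
  Scoring all windows and aggregating per residue yields the per-residue
  "shred" descriptor used to cut the template into search models.
* **spherical** — for every residue, collect the spatially nearest
  ``n_target`` residues (compact, overlapping sub-domains), keeping only
  contiguous runs of at least ``min_contig`` residues.

Model size for the spherical mode can be chosen from the expected
log-likelihood gain (eLLG) of a hypothetical model of given size and
coordinate error against the actual data resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_io import StructureModel, to_polyalanine

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "ShredProfile",
    "RotationCluster",
    "sequential_fragments",
    "spherical_fragments",
    "cluster_rotations",
    "shred_llg_profile",
    "select_models",
    "ellg_model_size",
    "sigma_a",
]

CHAIN_BREAK_CA_DIST = 4.5   # Angstrom; larger Calpha-Calpha gap = break


@dataclass
class Fragment:
    """A polyalanine sub-model of a template, with provenance."""

    fragment_id: str
    parent_id: str
    spans: tuple            # ((chain, first, last), ...) inclusive
    model: StructureModel
    mode: str               # sequential_extract | sequential_omit | spherical

    def __post_init__(self):
        if not self.spans:
            raise ValueError("fragment must cover at least one span")
        for c, a, b in self.spans:
            if a > b:
                raise ValueError(f"span {c}:{a}-{b} has first > last")

    @property
    def n_residues(self) -> int:
        return self.model.n_residues

    @property
    def size(self) -> int:
        return sum(b - a + 1 for _, a, b in self.spans)

    def residue_keys(self):
        return self.model.residue_keys()


@dataclass
class FragmentLibrary:
    parent_id: str
    fragments: list

    def __len__(self):
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __getitem__(self, i):
        return self.fragments[i]


@dataclass
class RotationCluster:
    members: list           # list of 3x3 rotation matrices
    scores: list
    representative: np.ndarray
    tolerance_deg: float

    @property
    def best_score(self):
        return max(self.scores)


# -- chain-run decomposition ------------------------------------------------

def _contiguous_runs(template: StructureModel):
    """Split the template into break-free runs of residues.

    A run ends at a chain change, a residue-number gap, or a
    Calpha-Calpha distance above 4.5 Angstrom.
    """
    keys = template.residue_keys()
    ca = {}
    for k in keys:
        m = template.residue_mask([k]) & template.ca_mask()
        if m.any():
            ca[k] = template.xyz[m][0]
    runs, current = [], []
    for k in keys:
        if k not in ca:
            if current:
                runs.append(current)
            current = []
            continue
        if current:
            prev = current[-1]
            gap = (k[0] != prev[0] or k[1] != prev[1] + 1
                   or np.linalg.norm(ca[k] - ca[prev]) > CHAIN_BREAK_CA_DIST)
            if gap:
                runs.append(current)
                current = []
        current.append(k)
    if current:
        runs.append(current)
    return runs


def _fragment_from_keys(template_pa: StructureModel, keys, parent_id,
                        frag_id, mode) -> Fragment:
    spans = []
    for k in keys:
        if spans and k[0] == spans[-1][0] and k[1] == spans[-1][2] + 1:
            spans[-1] = (spans[-1][0], spans[-1][1], k[1])
        else:
            spans.append((k[0], k[1], k[1]))
    model = template_pa.select(template_pa.residue_mask(keys))
    return Fragment(fragment_id=frag_id, parent_id=parent_id,
                    spans=tuple(spans), model=model, mode=mode)


# -- sequential mode --------------------------------------------------------

def sequential_fragments(template: StructureModel, size_min: int = 10,
                         size_max: int = 20, step: int = 4,
                         kind: str = "extract",
                         parent_id: str = "template") -> FragmentLibrary:
    """Sliding-window polyalanine fragments (or their complements).

    For each window size s in [size_min, size_max] the start position runs
    over the grid 0, step, 2*step, ... anchored at the first residue of
    each break-free run; windows extending past the run end are skipped.
    ``kind='omit'`` emits the template minus the window instead.
    """
    if size_min > size_max:
        raise ValueError("size_min > size_max")
    if step < 1:
        raise ValueError("step must be >= 1")
    if kind not in ("extract", "omit"):
        raise ValueError(f"unknown kind {kind!r}")
    pa = to_polyalanine(template)
    runs = _contiguous_runs(pa)
    if not runs or max(len(r) for r in runs) < size_min:
        raise ValueError(f"no chain run of at least {size_min} residues")
    all_keys = pa.residue_keys()
    frags = []
    mode = f"sequential_{kind}"
    for run in runs:
        L = len(run)
        for s in range(size_min, size_max + 1):
            if s > L:
                continue
            for start in range(0, L - s + 1, step):
                window = run[start:start + s]
                if kind == "extract":
                    keys = window
                else:
                    wset = set(window)
                    keys = [k for k in all_keys if k not in wset]
                    if not keys:
                        continue
                fid = (f"{parent_id}_{kind}_{window[0][0]}"
                       f"{window[0][1]}-{window[-1][1]}_s{s}")
                frags.append(_fragment_from_keys(pa, keys, parent_id, fid, mode))
    return FragmentLibrary(parent_id=parent_id, fragments=frags)


# -- spherical mode ---------------------------------------------------------

def spherical_fragments(template: StructureModel, n_target: int,
                        min_contig: int = 3,
                        parent_id: str = "template") -> FragmentLibrary:
    """Compact overlapping fragments centred on every residue.

    For each residue's Calpha the ``n_target`` nearest residues (by
    Calpha distance) are collected; contiguous runs shorter than
    ``min_contig`` are discarded.  If trimming leaves the model more than
    10 residues short of ``n_target``, the candidate neighbourhood is
    grown and re-trimmed.  Duplicate residue sets are emitted once.
    """
    if n_target < min_contig:
        raise ValueError("n_target smaller than min_contig")
    pa = to_polyalanine(template)
    keys = pa.residue_keys()
    if n_target > len(keys):
        raise ValueError("n_target exceeds template size")
    camask = pa.ca_mask()
    ca = np.array([pa.xyz[pa.residue_mask([k]) & camask][0] for k in keys])
    key_index = {k: i for i, k in enumerate(keys)}
    runs = _contiguous_runs(pa)

    def trim(selected_idx):
        sel = set(selected_idx)
        kept = []
        for run in runs:
            current = []
            for k in run:
                if key_index[k] in sel:
                    current.append(k)
                else:
                    if len(current) >= min_contig:
                        kept.extend(current)
                    current = []
            if len(current) >= min_contig:
                kept.extend(current)
        return kept

    frags, seen = [], set()
    dist = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    for ic, center in enumerate(keys):
        order = np.argsort(dist[ic], kind="stable")
        k = n_target
        kept = trim(order[:k])
        while len(kept) < n_target - 10 and k < len(keys):
            k += 1
            kept = trim(order[:k])
        if not kept:
            continue
        sig = frozenset(kept)
        if sig in seen:
            continue
        seen.add(sig)
        kept = [k2 for k2 in keys if k2 in sig]      # restore chain order
        fid = f"{parent_id}_sph_{center[0]}{center[1]}_n{len(kept)}"
        frags.append(_fragment_from_keys(pa, kept, parent_id, fid, "spherical"))
    return FragmentLibrary(parent_id=parent_id, fragments=frags)


# -- rotation clustering ----------------------------------------------------

def rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray,
                       sym_rotations=None) -> float:
    """Angle of Ra Rb^T, minimised over point-group rotations if given."""
    cands = [np.eye(3)] if sym_rotations is None else list(sym_rotations)
    best = 180.0
    for M in cands:
        R = Ra @ (M @ Rb).T
        c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        best = min(best, float(np.rad2deg(np.arccos(c))))
    return best


def cluster_rotations(rotations, scores=None, tolerance_deg: float = 15.0,
                      sym_rotations=None) -> list:
    """Greedy score-ordered clustering of rotation-search peaks.

    Rotations are visited by descending score; each joins the first
    existing cluster whose representative lies within ``tolerance_deg``
    under the min-over-symmetry rotation-angle metric, otherwise it
    founds a new cluster.  Ties in score are broken by input order.
    """
    rotations = [np.asarray(R, dtype=float) for R in rotations]
    if not rotations:
        raise ValueError("no rotations to cluster")
    if scores is None:
        scores = [0.0] * len(rotations)
    order = sorted(range(len(rotations)),
                   key=lambda i: (-float(scores[i]), i))
    clusters = []
    for i in order:
        R = rotations[i]
        for cl in clusters:
            if rotation_angle_deg(R, cl.representative,
                                  sym_rotations) <= tolerance_deg:
                cl.members.append(R)
                cl.scores.append(float(scores[i]))
                break
        else:
            clusters.append(RotationCluster(members=[R],
                                            scores=[float(scores[i])],
                                            representative=R,
                                            tolerance_deg=tolerance_deg))
    return clusters


# -- shred profile and model selection --------------------------------------

@dataclass
class ShredProfile:
    """Per-residue descriptor of local template accuracy.

    Built by z-scoring fragment scores within each size group and
    averaging, for every residue, the z-scores of all fragments that
    contain it.
    """

    per_residue_score: dict        # (chain, res_id, icode) -> float
    source_scores: dict            # fragment_id -> raw score
    normalization: str = "per-size z-score, mean over covering fragments"

    def ordered_items(self):
        return sorted(self.per_residue_score.items(),
                      key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))

    @property
    def values(self):
        return np.array([v for _, v in self.ordered_items()])


def shred_llg_profile(library: FragmentLibrary, scores: dict) -> ShredProfile:
    """Aggregate per-fragment scores into the per-residue shred descriptor.

    ``scores`` maps fragment_id to a score.  Scores are z-scored within
    each fragment-size group (so groups of different window size are
    comparable), then each residue receives the mean z-score over all
    fragments containing it.  Residues covered by no scored fragment are
    absent from the profile.
    """
    missing = [f.fragment_id for f in library if f.fragment_id not in scores]
    if missing:
        raise ValueError(f"unscored fragments: {missing[:3]}...")
    by_size = {}
    for f in library:
        by_size.setdefault(f.size, []).append(f)
    z = {}
    for size, frags in by_size.items():
        raw = np.array([float(scores[f.fragment_id]) for f in frags])
        sd = raw.std()
        zz = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
        for f, v in zip(frags, zz):
            z[f.fragment_id] = v
    per_res_acc = {}
    for f in library:
        for k in f.residue_keys():
            per_res_acc.setdefault(k, []).append(z[f.fragment_id])
    per_res = {k: float(np.mean(v)) for k, v in per_res_acc.items()}
    return ShredProfile(per_residue_score=per_res,
                        source_scores={fid: float(scores[fid]) for fid in
                                       (f.fragment_id for f in library)})


def _local_maxima(keys, vals):
    """Indices of local maxima along the residue-ordered profile."""
    idx = []
    n = len(vals)
    for i in range(n):
        left = vals[i - 1] if i > 0 and keys[i - 1][0] == keys[i][0] else -np.inf
        right = vals[i + 1] if i < n - 1 and keys[i + 1][0] == keys[i][0] else -np.inf
        if vals[i] >= left and vals[i] >= right:
            idx.append(i)
    return idx


def select_models(profile: ShredProfile, template: StructureModel,
                  max_models: int = 4, min_residues: int = 10,
                  peak_width_frac: float = 0.10,
                  plateau_len: int = 6,
                  parent_id: str = "template") -> FragmentLibrary:
    """Cut up to ``max_models`` polyalanine models out of the template.

    Four selection rules are applied in order, each producing a residue
    set: (1) regions around local maxima (within ``peak_width_frac`` of
    the peak value); (2) plateaus — runs of >= ``plateau_len`` residues
    all within 10% of their run maximum; (3) residues above 75% of the
    profile maximum; (4) residues above the smallest local-maximum value.
    Duplicate sets are dropped, as are models below ``min_residues``.
    """
    items = profile.ordered_items()
    if not items:
        raise ValueError("empty profile")
    keys = [k for k, _ in items]
    vals = np.array([v for _, v in items])
    vmax, vmin = vals.max(), vals.min()
    span = vmax - vmin if vmax > vmin else 1.0
    peaks = _local_maxima(keys, vals)

    def region_around(i):
        thr = vals[i] - peak_width_frac * span
        lo = i
        while lo > 0 and keys[lo - 1][0] == keys[i][0] and vals[lo - 1] >= thr:
            lo -= 1
        hi = i
        while (hi < len(vals) - 1 and keys[hi + 1][0] == keys[i][0]
               and vals[hi + 1] >= thr):
            hi += 1
        return set(range(lo, hi + 1))

    rule_sets = []
    # rule 1: peak regions
    s1 = set()
    for i in peaks:
        s1 |= region_around(i)
    rule_sets.append(s1)
    # rule 2: plateaus
    s2 = set()
    i = 0
    while i < len(vals):
        j = i
        while (j + 1 < len(vals) and keys[j + 1][0] == keys[j][0]
               and keys[j + 1][1] == keys[j][1] + 1):
            run_max = vals[i:j + 2].max()
            if run_max - vals[i:j + 2].min() <= peak_width_frac * span:
                j += 1
            else:
                break
        if j - i + 1 >= plateau_len:
            s2 |= set(range(i, j + 1))
            i = j + 1
        else:
            i += 1
    rule_sets.append(s2)
    # rule 3: above 75% of the maximum (on the min-shifted scale)
    thr3 = vmin + 0.75 * span
    rule_sets.append({i for i, v in enumerate(vals) if v >= thr3})
    # rule 4: above the smallest local-maximum value
    if peaks:
        thr4 = min(vals[i] for i in peaks)
        rule_sets.append({i for i, v in enumerate(vals) if v >= thr4})

    pa = to_polyalanine(template)
    models, seen = [], set()
    for rule_no, sel in enumerate(rule_sets, start=1):
        if len(models) >= max_models:
            break
        kset = [keys[i] for i in sorted(sel)]
        kset = [k for k in kset if k in set(pa.residue_keys())]
        if len(kset) < min_residues:
            continue
        sig = frozenset(kset)
        if sig in seen:
            continue
        seen.add(sig)
        fid = f"{parent_id}_shredmodel_r{rule_no}_n{len(kset)}"
        models.append(_fragment_from_keys(pa, kset, parent_id, fid,
                                          "sequential_extract"))
    if not models:
        warnings.warn("shred-profile selection produced no model")
    return FragmentLibrary(parent_id=parent_id, fragments=models)


# -- eLLG-based model sizing ------------------------------------------------

def sigma_a(inv_d: np.ndarray, fraction: float, rmsd: float) -> np.ndarray:
    """sigma_A(s) = sqrt(f) exp(-2 pi^2 rmsd^2 s^2 / 3), s = 1/d."""
    return np.sqrt(fraction) * np.exp(
        -2.0 * np.pi ** 2 * rmsd ** 2 * np.square(inv_d) / 3.0)


def ellg_model_size(dataset, rmsd_est: float, asu_residues: int,
                    target_ellg: float = 30.0) -> int:
    """Smallest model size (residues) whose expected LLG meets the target.

    eLLG(n) = sum_acentric sigma_A^4 / 2 + sum_centric sigma_A^4 / 4 with
    the model completeness fraction f = n / asu_residues entering
    sigma_A.  Monotonically non-decreasing in n; if even the whole
    structure cannot reach the target the full size is returned with a
    warning.
    """
    if rmsd_est <= 0:
        raise ValueError("rmsd_est must be positive")
    if asu_residues < 1:
        raise ValueError("asu_residues must be positive")
    inv_d = 1.0 / dataset.d()
    centric = dataset.centric
    base = np.exp(-2.0 * np.pi ** 2 * rmsd_est ** 2 * inv_d ** 2 / 3.0) ** 4
    weight = np.where(centric, 0.25, 0.5)
    per_f1 = float(np.sum(base * weight))   # eLLG at f = 1
    for n in range(1, asu_residues + 1):
        f = n / asu_residues
        if f * f * per_f1 >= target_ellg:
            return n
    warnings.warn(f"target eLLG {target_ellg} unreachable; "
                  f"best (whole structure) = {per_f1:.2f}")
    return asu_residues
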