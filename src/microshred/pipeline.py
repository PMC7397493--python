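"""End-to-end fragment-phasing workflow on intensity data.

The canonical flow mirrors fragment-based molecular replacement from a
distant homologue:

1. rotation search of the whole homologue template against normalized
   intensities, peak clustering (15 degree tolerance) and local
   refinement of the top cluster orientations;
2. sequential shredding of the template, scoring every window fragment
   at the refined orientations, and aggregation into the per-residue
   shred descriptor;
3. cutting up to four search models from the descriptor, then placing
   each (translation search + rigid-body refinement) and scoring the
   placements (TFZ, amplitude CC, likelihood gain);
4. reporting phase quality (weighted mean phase error against a
   reference phase set, when one is available) and the Calpha distance
   of the placed model to a known ground truth (symmetry- and
   origin-aware), for synthetic benchmarks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .model_io import StructureModel, to_polyalanine, superpose
from .symmetry import SpaceGroupInfo
from .diffraction import (
    ReflectionSet, structure_factors, normalize_E, orthogonalization_matrix,
)
from .fragmentation import (
    sequential_fragments, cluster_rotations, shred_llg_profile, select_models,
    sigma_a, rotation_angle_deg,
)
from .search import (
    SearchGrid, Placement, rotation_search, refine_rotation,
    translation_search, rigid_refine, pack_filter, llg_proxy,
    _RotationScorer, _TranslationScorer, _resolution_slice, figure_of_merit,
)
from .phasing_metrics import PhaseSet, wmpe, amp_cc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_phasing",
           "placement_phase_set", "placement_vs_truth_rmsd", "placed_model"]


@dataclass
class PipelineConfig:
    """Tunables of the shred-and-search workflow."""

    size_min: int = 15
    size_max: int = 25
    step: int = 4
    rmsd_est: float = 1.0            # assumed model error, Angstrom
    rot_step_deg: float = 15.0
    # rotation-stage resolution window: high-resolution terms carry
    # little signal for a ~1 A-error model (sigma_A falloff) and mislead
    # the search, so rotation work uses 3.5-15 A by default
    rot_dmin: float = 3.5
    rot_dmax: float = 15.0
    trans_step_frac: float = 1.0 / 24.0
    # rotation clusters carried into the translation stage: the rotation
    # target alone ranks helical decoys close to the true orientation, so
    # several clusters are kept and the refined translation score decides
    n_clusters: int = 8
    n_refine_candidates: int = 3     # placements rigid-refined per model
    max_models: int = 4
    asu_residues: int | None = None  # total ordered residues; None = template


@dataclass
class PipelineResult:
    placements: list
    best: Placement | None
    profile: object
    clusters: list
    report: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)


def placed_model(placement: Placement, fragment, cell) -> StructureModel:
    """Fragment model transformed into the crystal frame of a placement."""
    model = fragment.model if hasattr(fragment, "model") else fragment
    M = orthogonalization_matrix(cell)
    out = model.copy()
    out.xyz = ((model.xyz - model.xyz.mean(axis=0)) @ placement.rotation.T
               + placement.translation @ M.T)
    out.cell = tuple(cell)
    return out


def placement_phase_set(placement: Placement, fragment, data: ReflectionSet,
                        rmsd_est: float, completeness_fraction: float
                        ) -> PhaseSet:
    """Model phases of a placement with Sim-style figure-of-merit weights."""
    model = placed_model(placement, fragment, data.cell)
    calc = structure_factors(model, data)
    if data.E is None:
        data = normalize_E(data)
    calc_i = calc.subset(np.ones(calc.n, dtype=bool))
    calc_i.I = calc.F ** 2
    ecalc = normalize_E(calc_i).E
    sa = sigma_a(1.0 / data.d(), completeness_fraction, rmsd_est)
    fom = figure_of_merit(data.E, ecalc, sa, data.centric)
    return PhaseSet(cell=data.cell, spacegroup=data.spacegroup,
                    hkl=data.hkl.copy(), phase=calc.phase.copy(),
                    weight=fom, F=calc.F.copy())


def placement_vs_truth_rmsd(placement: Placement, fragment,
                            truth: StructureModel, cell, spacegroup) -> float:
    """Calpha rmsd of a placed fragment to the ground truth.

    Minimised over point-group operations combined with allowed origin
    shifts and lattice translations (the placement is only defined up to
    those), matching residues by number.
    """
    sg = SpaceGroupInfo(spacegroup)
    M = orthogonalization_matrix(cell)
    inv = np.linalg.inv(M)
    model = placed_model(placement, fragment, cell)
    keys = [k for k in model.residue_keys()]
    tset = set(truth.residue_keys())
    keys = [k for k in keys if k in tset]
    if not keys:
        return np.inf
    mask_m = model.residue_mask(keys) & model.ca_mask()
    mask_t = truth.residue_mask(keys) & truth.ca_mask()
    frac_m = model.xyz[mask_m] @ inv.T
    frac_t = truth.xyz[mask_t] @ inv.T
    shifts, cont = sg.allowed_origin_shifts()
    if any(cont):
        grid = [np.linspace(0, 1, 9)[:-1] if c else np.array([0.0])
                for c in cont]
        g = np.meshgrid(*grid, indexing="ij")
        extra = np.stack([a.ravel() for a in g], axis=1)
        shifts = [s + e for s in shifts for e in extra]
    best = np.inf
    for R, t in zip(sg.rotations, sg.translations):
        moved = frac_m @ R.astype(float).T + t
        for shift in shifts:
            diff = moved + shift - frac_t
            diff -= np.round(diff)
            rmsd = float(np.sqrt(np.mean(np.sum((diff @ M.T) ** 2, axis=1))))
            best = min(best, rmsd)
    return best


def _scan_and_place(model_pa, data, clusters, full_grid, config,
                    scan_step_deg: float = 4.0, n_carry: int = 150,
                    coarse_dmin: float = 4.5, n_refine: int = 6) -> Placement:
    """Joint rotation-perturbation / translation scan for one model.

    For each cluster orientation: a coarse (low-resolution, sigma_A-
    weighted) Cheshire-cell scan selects candidate positions; those are
    rescored at full resolution for every small rotation perturbation of
    the cluster orientation.  The globally best few (rotation,
    translation) pairs are rigid-body refined and the winner is chosen
    by the refined, unweighted E-correlation among placements that pass
    the crystal-packing filter (clashing decoys are common; packing is a
    hard physical constraint).
    """
    from scipy.spatial.transform import Rotation as _Rot
    deltas = []
    s = scan_step_deg
    for a in (-s, 0.0, s):
        for b in (-s, 0.0, s):
            for g in (-s, 0.0, s):
                deltas.append(_Rot.from_rotvec(
                    np.deg2rad([a, b, g])).as_matrix())
    d = data.d()
    cmask = d >= coarse_dmin
    data_c = data.subset(cmask) if cmask.sum() >= 30 else data
    n_div = max(2, int(round(1.0 / full_grid.trans_step_frac)))
    tgrid = data.sg_info.cheshire_translations(n_div)
    sub = np.array([-0.5, 0.0, 0.5]) / n_div
    offs = np.stack(np.meshgrid(sub, sub, sub, indexing="ij"),
                    axis=-1).reshape(-1, 3)
    pool = []          # (scan score, Placement)
    for rf, R0 in clusters:
        # coarse position carry, shared across rotation perturbations
        # (the low-resolution landscape barely moves under a few degrees)
        sc_c = _TranslationScorer(model_pa, R0, data_c)
        scores = np.concatenate([sc_c.correlations(tgrid[i:i + 512])
                                 for i in range(0, len(tgrid), 512)])
        sd = scores.std()
        tfz = float((scores.max() - scores.mean()) / sd) if sd > 0 else 0.0
        carry = np.argsort(-scores)[:n_carry]
        cands = (tgrid[carry][:, None, :] + offs[None, :, :]).reshape(-1, 3)
        for dR in deltas:
            R = dR @ R0
            sf = _TranslationScorer(model_pa, R, data, max_refl=600)
            fs = np.concatenate([sf.correlations(cands[i:i + 2048])
                                 for i in range(0, len(cands), 2048)])
            for j in np.argsort(-fs)[:2]:
                pool.append((float(fs[j]), Placement(
                    fragment_id="anchor", rotation=R,
                    translation=cands[j] % 1.0, rf_score=rf, tfz=tfz)))
    pool.sort(key=lambda t: -t[0])
    # drop near-duplicates before the expensive refinement
    M = orthogonalization_matrix(data.cell)
    picked = []
    for sc, plc in pool:
        dup = False
        for _, q in picked:
            dt = plc.translation - q.translation
            dt -= np.round(dt)
            if (np.linalg.norm(dt @ M.T) < 2.0
                    and rotation_angle_deg(plc.rotation, q.rotation) < 6.0):
                dup = True
                break
        if not dup:
            picked.append((sc, plc))
        if len(picked) >= n_refine:
            break
    best, best_packed = None, None
    for _, plc in picked:
        ref = rigid_refine(plc, model_pa, data, max_iter=150, grid=full_grid)
        sc_u = _TranslationScorer(model_pa, ref.rotation, data)
        escore = float(sc_u.correlations(ref.translation[None, :])[0])
        ref.t_score = escore
        ref.cc = float(100.0 * sc_u.cc_raw(ref.translation[None, :])[0])
        ref.rf_score = plc.rf_score
        ref.tfz = plc.tfz
        if best is None or escore > best.t_score:
            best = ref
        if pack_filter(ref, [], model_pa, data.cell, data.spacegroup):
            if best_packed is None or escore > best_packed.t_score:
                best_packed = ref
    return best_packed if best_packed is not None else best


def run_phasing(template: StructureModel, data: ReflectionSet,
                config: PipelineConfig | None = None,
                truth_phases: PhaseSet | None = None,
                truth_model: StructureModel | None = None,
                seed: int = 0) -> PipelineResult:
    """Shred a homologue template and phase the data set with its fragments.

    Returns every scored placement (one per selected shred model) plus a
    JSON-ready report; when a reference phase set and/or ground-truth
    model are supplied (synthetic benchmarks), phase errors and Calpha
    rmsds are reported as well.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    pa = to_polyalanine(template)
    if data.E is None:
        data = normalize_E(data)
    asu_res = config.asu_residues or pa.n_residues
    grid = SearchGrid(rot_step_deg=config.rot_step_deg, dmin=config.rot_dmin,
                      dmax=config.rot_dmax,
                      trans_step_frac=config.trans_step_frac)
    full_grid = SearchGrid(rot_step_deg=config.rot_step_deg,
                           trans_step_frac=config.trans_step_frac)

    # 1. template rotation search + clustering + local refinement
    ranked = rotation_search(pa, data, grid)
    sym_cart = SpaceGroupInfo(data.spacegroup).cartesian_rotations(
        orthogonalization_matrix(data.cell))
    top = ranked[:max(60, 5 * config.n_clusters)]
    clusters = cluster_rotations([R for _, R in top],
                                 [s for s, _ in top],
                                 tolerance_deg=15.0, sym_rotations=sym_cart)
    clusters = clusters[:config.n_clusters]
    refined_rots = []
    for cl in clusters:
        R, score = refine_rotation(pa, data, cl.representative, grid)
        refined_rots.append((score, R))
    refined_rots.sort(key=lambda t: -t[0])
    logger.info("template rotation clusters: %d (best score %.3f)",
                len(refined_rots), refined_rots[0][0])

    # 2. anchor: six-dimensional placement of the whole template.  The
    # rotation function's optimum for an imperfect model sits several
    # degrees off the true orientation (and ranks decoy orientations
    # close to it), while the full-resolution translation score only
    # tolerates ~2 degrees — so each distinct cluster orientation is
    # scanned over small rotation perturbations jointly with the
    # translation candidates, and the refined (unweighted) E-correlation
    # arbitrates.
    distinct = []
    for rf, R0 in refined_rots:
        if not any(rotation_angle_deg(R0, R1, sym_cart) < 3.0
                   for _, R1 in distinct):
            distinct.append((rf, R0))
    anchor = _scan_and_place(pa, data, distinct[:5], full_grid, config)
    logger.info("template anchor: E-corr %.3f (tfz %.1f)",
                anchor.t_score, anchor.tfz)

    # 3. shred the template, score windows at the anchor orientation
    library = sequential_fragments(template, config.size_min, config.size_max,
                                   config.step, kind="extract")
    data_rot = _resolution_slice(data, grid)
    frag_scores = {}
    for frag in library:
        fs = _RotationScorer(frag.model, data_rot)
        frag_scores[frag.fragment_id] = fs.score(anchor.rotation)
    profile = shred_llg_profile(library, frag_scores)
    models = select_models(profile, template, max_models=config.max_models)
    if len(models) == 0:
        raise RuntimeError("shred stage produced no search model")

    # 4. place every selected model (fresh translation search from the
    # anchor orientation, locally re-refined per model)
    placements = []
    accepted = []
    accepted_frags = []
    for frag in models:
        Rr, rf = refine_rotation(frag, data, anchor.rotation, grid)
        cand = translation_search(frag, Rr, data, full_grid,
                                  top_n=config.n_refine_candidates)
        refined_cand = [rigid_refine(c, frag, data, max_iter=150,
                                     grid=full_grid) for c in cand]
        ordered = sorted(zip(refined_cand, cand),
                         key=lambda t: -t[0].t_score)
        best_c = ordered[0][0]
        best_c.rf_score = rf
        best_c.tfz = ordered[0][1].tfz   # Z-score of the seeding search
        f_n = min(1.0, frag.n_residues / asu_res)
        best_c.llg_proxy = llg_proxy(best_c, frag, data, config.rmsd_est, f_n)
        if pack_filter(best_c, accepted, frag, data.cell, data.spacegroup,
                       placed_fragments=accepted_frags):
            accepted.append(best_c)
            accepted_frags.append(frag)
        placements.append((best_c, frag))

    # 5. report
    report = {"n_fragments": len(library),
              "n_models": len(models),
              "n_accepted": len(accepted),
              "clusters": [{"score": float(s)} for s, _ in refined_rots],
              "anchor": {"t_score": float(anchor.t_score),
                         "tfz": float(anchor.tfz),
                         "rf_score": float(anchor.rf_score)},
              "placements": []}
    best_entry, best_p = None, None
    for plc, frag in placements:
        f_n = min(1.0, frag.n_residues / asu_res)
        entry = {"fragment_id": plc.fragment_id,
                 "n_residues": frag.n_residues,
                 "rf_score": float(plc.rf_score),
                 "tfz": float(plc.tfz),
                 "cc": float(plc.cc),
                 "llg_proxy": float(plc.llg_proxy)}
        if truth_phases is not None:
            ps = placement_phase_set(plc, frag, data, config.rmsd_est, f_n)
            entry["wmpe_deg"] = wmpe(ps, truth_phases)
            rand = PhaseSet(cell=data.cell, spacegroup=data.spacegroup,
                            hkl=data.hkl,
                            phase=rng.uniform(0, 360, data.n),
                            weight=ps.weight)
            entry["wmpe_random_deg"] = wmpe(rand, truth_phases)
        if truth_model is not None:
            entry["ca_rmsd_vs_truth"] = placement_vs_truth_rmsd(
                plc, frag, truth_model, data.cell, data.spacegroup)
        report["placements"].append(entry)
        if best_entry is None or entry["llg_proxy"] > best_entry["llg_proxy"]:
            best_entry, best_p = entry, plc
    report["best"] = best_entry
    return PipelineResult(placements=[p for p, _ in placements],
                          best=best_p, profile=profile,
                          clusters=refined_rots, report=report)
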