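"""Multi-crystal data-reduction heuristics for wedge-limited nanocrystal
data: per-crystal linear+B scaling, CC1/2, greedy omission of damaged
trailing frames, inverse-variance merging with standard statistics, and
exhaustive minimal-crystal merge-set selection.

All observations are mapped to canonical asymmetric-unit indices before
any statistic is computed.  CC1/2 uses seeded random half-splits of each
reflection's observations (simple and reproducible; no sigma-tau
refinement).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .symmetry import SpaceGroupInfo
from .diffraction import ReflectionSet, generate_reflections, d_spacings

__all__ = [
    "Frame",
    "CrystalSeries",
    "MergeResult",
    "scale_series",
    "cc_half",
    "omit_damage_frames",
    "merge",
    "select_merge_set",
    "read_series_tsv",
    "write_series_tsv",
]


@dataclass
class Frame:
    """Integrated observations from one rotation frame."""

    index: int
    hkl: np.ndarray
    I: np.ndarray
    sigI: np.ndarray

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.I = np.asarray(self.I, dtype=float)
        self.sigI = np.asarray(self.sigI, dtype=float)
        if np.any(self.sigI <= 0):
            raise ValueError("sigI must be positive")


@dataclass
class CrystalSeries:
    """Per-frame observation lists from one crystal, pre-merge."""

    crystal_id: str
    frames: list
    scale: float = 1.0
    b_rel: float = 0.0

    def __post_init__(self):
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be increasing")

    @property
    def n_obs(self) -> int:
        return sum(len(f.I) for f in self.frames)

    def observations(self):
        """(hkl, I, sigI, frame_index) concatenated over frames."""
        if not self.frames:
            z = np.zeros(0)
            return np.zeros((0, 3), dtype=int), z, z, np.zeros(0, dtype=int)
        hkl = np.concatenate([f.hkl for f in self.frames])
        I = np.concatenate([f.I for f in self.frames])
        sig = np.concatenate([f.sigI for f in self.frames])
        fr = np.concatenate([np.full(len(f.I), f.index) for f in self.frames])
        return hkl, I, sig, fr

    def drop_last_frame(self) -> "CrystalSeries":
        return CrystalSeries(crystal_id=self.crystal_id,
                             frames=self.frames[:-1],
                             scale=self.scale, b_rel=self.b_rel)


@dataclass
class MergeResult:
    merged: ReflectionSet
    cc_half: float
    mean_i_over_sig: float
    completeness: float          # percent
    multiplicity: float
    n_crystals: int
    n_obs: int
    outer_shell: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "n_crystals": self.n_crystals,
            "n_obs": self.n_obs,
            "n_unique": self.merged.n,
            "cc_half": self.cc_half,
            "mean_i_over_sig": self.mean_i_over_sig,
            "completeness_pct": self.completeness,
            "multiplicity": self.multiplicity,
        }
        out.update({f"outer_{k}": v for k, v in self.outer_shell.items()})
        return out


# -- grouping helper --------------------------------------------------------

def _group_by_unique(hkl, sg: SpaceGroupInfo):
    """Sort observations by canonical unique index.

    Returns (order, group_starts, unique_hkl): observations reordered by
    ``order`` fall into contiguous groups delimited by ``group_starts``.
    """
    asu = sg.reduce_to_asu(hkl)
    big = int(np.abs(asu).max()) + 1 if len(asu) else 1
    key = (asu[:, 0] * big + asu[:, 1]) * (2 * big) + asu[:, 2]
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    starts = np.concatenate([[0], np.where(np.diff(sorted_key) != 0)[0] + 1,
                             [len(key)]])
    uniq = asu[order[starts[:-1]]]
    return order, starts, uniq


# -- scaling ----------------------------------------------------------------

def scale_series(series: list, cell, spacegroup, reference: int = 0,
                 min_common: int = 10) -> list:
    """Linear + isotropic-B scaling of each crystal onto a reference.

    Fits I_obs ~ k exp(-2 B s^2) I_ref per crystal over reflections in
    common with the reference (s = sin(theta)/lambda), then divides the
    fitted factor out of I and sigI.  The recovered (k, B) are stored on
    the returned series as ``scale`` and ``b_rel``.  Crystals with fewer
    than ``min_common`` common reflections are left unscaled with a
    warning.
    """
    sg = SpaceGroupInfo(spacegroup)

    def mean_by_unique(cs: CrystalSeries):
        hkl, I, _, _ = cs.observations()
        if len(I) == 0:
            return {}
        order, starts, uniq = _group_by_unique(hkl, sg)
        Is = I[order]
        return {tuple(h): Is[a:b].mean()
                for h, a, b in zip(map(tuple, uniq), starts[:-1], starts[1:])}

    ref_means = mean_by_unique(series[reference])
    out = []
    for i, cs in enumerate(series):
        if i == reference:
            out.append(replace(cs, scale=1.0, b_rel=0.0))
            continue
        own = mean_by_unique(cs)
        common = [h for h in own if h in ref_means]
        if len(common) < min_common:
            warnings.warn(f"crystal {cs.crystal_id}: only {len(common)} "
                          "reflections in common with reference; left unscaled")
            out.append(replace(cs))
            continue
        harr = np.array(common)
        s2 = np.square(0.5 / d_spacings(cell, harr))
        i_own = np.array([own[h] for h in common])
        i_ref = np.array([ref_means[h] for h in common])

        def k_for(B):
            g = np.exp(-2.0 * B * s2) * i_ref
            denom = float(np.sum(g * g))
            return float(np.sum(i_own * g) / denom) if denom > 0 else 1.0

        def cost(B):
            k = k_for(B)
            return float(np.sum((i_own - k * np.exp(-2.0 * B * s2) * i_ref) ** 2))

        res = minimize_scalar(cost, bounds=(-100.0, 100.0), method="bounded",
                              options={"xatol": 1e-4})
        B = float(res.x)
        k = k_for(B)
        frames = []
        for f in cs.frames:
            s2f = np.square(0.5 / d_spacings(cell, f.hkl))
            corr = np.exp(2.0 * B * s2f) / k
            frames.append(Frame(index=f.index, hkl=f.hkl.copy(),
                                I=f.I * corr, sigI=f.sigI * corr))
        out.append(CrystalSeries(crystal_id=cs.crystal_id, frames=frames,
                                 scale=k, b_rel=B))
    return out


# -- CC1/2 ------------------------------------------------------------------

def cc_half(hkl, I, spacegroup, seed: int = 0) -> float:
    """Half-dataset correlation from a seeded random split per reflection.

    Each unique reflection's observations are randomly divided into two
    halves; CC1/2 is the Pearson correlation of the half-set means over
    reflections with at least one observation in each half.
    """
    sg = SpaceGroupInfo(spacegroup)
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    I = np.asarray(I, dtype=float)
    if len(I) < 6:
        raise ValueError("too few observations for a half-set split")
    order, starts, _ = _group_by_unique(hkl, sg)
    Is = I[order]
    rng = np.random.default_rng(seed)
    m1, m2 = [], []
    for a, b in zip(starts[:-1], starts[1:]):
        n = b - a
        if n < 2:
            continue
        perm = rng.permutation(n)
        half = n // 2
        vals = Is[a:b][perm]
        m1.append(vals[:half].mean())
        m2.append(vals[half:].mean())
    if len(m1) < 3:
        raise ValueError(f"only {len(m1)} multiply-observed reflections; "
                         "CC1/2 undefined")
    m1, m2 = np.array(m1), np.array(m2)
    s1, s2_ = m1.std(), m2.std()
    if s1 == 0 or s2_ == 0:
        return 0.0
    return float(np.mean((m1 - m1.mean()) * (m2 - m2.mean())) / (s1 * s2_))


# -- damage-frame omission --------------------------------------------------

def omit_damage_frames(series: CrystalSeries, cell, spacegroup,
                       max_omit: int = 6, seed: int = 0,
                       shell: str = "outer", n_splits: int = 5,
                       min_gain: float = 0.005) -> CrystalSeries:
    """Drop trailing high-damage frames while CC1/2 improves.

    Candidate trims of 0 to ``max_omit`` trailing frames are evaluated
    and the smallest trim achieving the best CC1/2 is kept, provided it
    beats the untrimmed CC1/2 by at least ``min_gain`` (damage-free
    series are left intact).  By default the decision CC1/2 is evaluated
    on the outer-resolution half of the series' observations, where
    resolution-dependent damage registers (overall CC1/2 is dominated by
    strong low-resolution terms and barely responds); ``shell='overall'``
    uses all observations.  The decision statistic is averaged over
    ``n_splits`` seeded half-splits to suppress split-sampling noise.
    Deterministic for a given seed.  The result never has lower decision
    CC1/2 than the input, by construction.
    """
    if len(series.frames) < 2:
        return series
    if shell not in ("outer", "overall"):
        raise ValueError(f"unknown shell choice {shell!r}")
    d_split = None
    if shell == "outer":
        hkl_all, _, _, _ = series.observations()
        if len(hkl_all):
            d_split = float(np.median(d_spacings(cell, hkl_all)))

    def cc_of(cs: CrystalSeries):
        hkl, I, _, _ = cs.observations()
        if d_split is not None:
            keep = d_spacings(cell, hkl) <= d_split
            hkl, I = hkl[keep], I[keep]
        try:
            return float(np.mean([cc_half(hkl, I, spacegroup,
                                          seed=seed + 1000 * j)
                                  for j in range(max(1, n_splits))]))
        except ValueError:
            return -np.inf

    candidates = [series]
    while (len(candidates) <= max_omit
           and len(candidates[-1].frames) > 1):
        candidates.append(candidates[-1].drop_last_frame())
    ccs = [cc_of(c) for c in candidates]
    best = int(np.argmax(ccs))     # argmax takes the smallest tied trim
    if best == 0 or ccs[best] <= ccs[0] + min_gain:
        return series
    return candidates[best]


# -- merging ----------------------------------------------------------------

def merge(series: list, cell, spacegroup, dmin: float, dmax: float = 1e6,
          seed: int = 0, n_shells: int = 20) -> MergeResult:
    """Inverse-variance merge of all observations to unique reflections.

    Statistics: completeness against the theoretical unique count in the
    resolution range, multiplicity, <I/sigma(I)> of merged values, CC1/2
    of the unmerged observations, and the same numbers for the outer
    resolution shell (highest-resolution of ``n_shells`` equal-count
    shells of the theoretical list).
    """
    if not series:
        raise ValueError("no crystals to merge")
    sg = SpaceGroupInfo(spacegroup)
    obs_h, obs_i, obs_s = [], [], []
    for cs in series:
        hkl, I, sig, _ = cs.observations()
        if len(I):
            obs_h.append(hkl)
            obs_i.append(I)
            obs_s.append(sig)
    if not obs_h:
        raise ValueError("no observations in input series")
    hkl = np.concatenate(obs_h)
    I = np.concatenate(obs_i)
    sig = np.concatenate(obs_s)
    d = d_spacings(cell, hkl)
    keep = (d >= dmin) & (d <= dmax)
    hkl, I, sig = hkl[keep], I[keep], sig[keep]
    order, starts, uniq = _group_by_unique(hkl, sg)
    Is, sigs = I[order], sig[order]
    n_uniq = len(uniq)
    mI = np.empty(n_uniq)
    msig = np.empty(n_uniq)
    mult = np.empty(n_uniq)
    for j, (a, b) in enumerate(zip(starts[:-1], starts[1:])):
        w = 1.0 / np.square(sigs[a:b])
        mI[j] = np.sum(w * Is[a:b]) / np.sum(w)
        msig[j] = 1.0 / np.sqrt(np.sum(w))
        mult[j] = b - a
    theo = generate_reflections(cell, spacegroup, dmin, dmax)
    merged = ReflectionSet(cell=tuple(cell), spacegroup=sg.symbol,
                           hkl=uniq, I=mI, sigI=msig)
    try:
        cc = cc_half(hkl, I, spacegroup, seed=seed)
    except ValueError:
        cc = np.nan
    completeness = 100.0 * n_uniq / theo.n
    result = MergeResult(
        merged=merged, cc_half=cc,
        mean_i_over_sig=float(np.mean(mI / msig)),
        completeness=float(completeness),
        multiplicity=float(mult.mean()) if n_uniq else np.nan,
        n_crystals=len(series), n_obs=int(len(I)),
    )
    # outer shell: top resolution bin of equal-count shells of the
    # theoretical list
    if theo.n >= n_shells:
        d_theo = np.sort(theo.d())
        edge = d_theo[theo.n // n_shells]
        shell_theo = int(np.sum(d_theo <= edge))
        in_shell_u = merged.d() <= edge
        in_shell_o = d_spacings(cell, hkl) <= edge
        shell = {}
        shell["completeness_pct"] = 100.0 * int(in_shell_u.sum()) / shell_theo
        if in_shell_u.any():
            shell["mean_i_over_sig"] = float(
                np.mean(mI[in_shell_u] / msig[in_shell_u]))
            shell["multiplicity"] = float(mult[in_shell_u].mean())
        try:
            shell["cc_half"] = cc_half(hkl[in_shell_o], I[in_shell_o],
                                       spacegroup, seed=seed)
        except ValueError:
            shell["cc_half"] = np.nan
        result.outer_shell = shell
    return result


def select_merge_set(crystals: list, cell, spacegroup, dmin: float,
                     dmax: float = 1e6, threshold: float = 90.0,
                     seed: int = 0):
    """Choose the merge subset: completeness above threshold with the
    fewest crystals, ties broken by the highest <I/sigma(I)>.

    All non-empty subsets are enumerated (capped at 16 crystals).  If no
    subset passes the completeness threshold the full set is returned
    with a warning.  Returns (chosen crystal list, MergeResult).
    """
    n = len(crystals)
    if n == 0:
        raise ValueError("no crystals")
    if n > 16:
        raise ValueError("exhaustive enumeration capped at 16 crystals")
    sg = SpaceGroupInfo(spacegroup)
    theo = generate_reflections(cell, spacegroup, dmin, dmax)
    # per-crystal unique index sets for the cheap completeness pass
    uniq_sets = []
    for cs in crystals:
        hkl, _, _, _ = cs.observations()
        if len(hkl) == 0:
            uniq_sets.append(frozenset())
            continue
        d = d_spacings(cell, hkl)
        keep = (d >= dmin) & (d <= dmax)
        asu = sg.reduce_to_asu(hkl[keep])
        uniq_sets.append(frozenset(map(tuple, asu)))
    best_subset = None
    for size in range(1, n + 1):
        passing = []
        for combo in itertools.combinations(range(n), size):
            u = frozenset().union(*(uniq_sets[i] for i in combo))
            if 100.0 * len(u) / theo.n > threshold:
                passing.append(combo)
        if passing:
            results = [(combo, merge([crystals[i] for i in combo], cell,
                                     spacegroup, dmin, dmax, seed=seed))
                       for combo in passing]
            best_subset = max(results, key=lambda t: t[1].mean_i_over_sig)
            break
    if best_subset is None:
        warnings.warn(f"no subset reaches {threshold}% completeness; "
                      "returning the full set")
        return list(crystals), merge(list(crystals), cell, spacegroup,
                                     dmin, dmax, seed=seed)
    combo, result = best_subset
    return [crystals[i] for i in combo], result


# -- per-crystal TSV IO -----------------------------------------------------

def write_series_tsv(series: CrystalSeries, path) -> None:
    """Plain table ``frame h k l I sigI`` with a crystal-id header line."""
    hkl, I, sig, fr = series.observations()
    with open(path, "w") as fh:
        fh.write(f"# crystal {series.crystal_id}\n")
        fh.write("frame\th\tk\tl\tI\tsigI\n")
        for j in range(len(I)):
            fh.write(f"{fr[j]}\t{hkl[j,0]}\t{hkl[j,1]}\t{hkl[j,2]}"
                     f"\t{float(I[j])!r}\t{float(sig[j])!r}\n")


def read_series_tsv(path, crystal_id: str | None = None) -> CrystalSeries:
    with open(path) as fh:
        first = fh.readline().strip()
    if crystal_id is None:
        crystal_id = (first.split()[2] if first.startswith("# crystal")
                      else str(path))
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     float_precision="round_trip")
    frames = []
    for fi in sorted(df["frame"].unique()):
        sub = df[df["frame"] == fi]
        frames.append(Frame(index=int(fi),
                            hkl=sub[["h", "k", "l"]].to_numpy(int),
                            I=sub["I"].to_numpy(float),
                            sigI=sub["sigI"].to_numpy(float)))
    return CrystalSeries(crystal_id=crystal_id, frames=frames)
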