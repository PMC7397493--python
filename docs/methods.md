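# Methods

`microshred` implements the desk-scale machinery of fragment-based
molecular replacement for protein microcrystal electron diffraction
(MicroED): reducing multi-crystal, wedge-limited intensity data;
generating polyalanine fragment libraries from a distant homologue;
placing fragments against the data with correlation-based rotation and
translation targets; and quantifying solution quality with
likelihood-style scores and phase-error metrics.  This note records the
models, conventions, numerical choices and limitations.

## Scattering model and conventions

* Electron structure factors are direct sums over all atoms and all
  space-group operators:
  `F(h) = sum_m sum_j occ_j f_j(s) exp(-B_j s^2) exp(2 pi i h.(R_m x_j + t_m))`
  with `s = sin(theta)/lambda = 1/(2d)`.  No FFT, no bulk solvent, no
  anisotropy: exactness over speed at the problem sizes used here.
* Elastic electron form factors are the Peng neutral-atom 5-Gaussian
  parameterisation (`f(s) = sum_i a_i exp(-b_i s^2)`), taken from
  gemmi's coefficient table; unknown elements raise rather than fall
  back to X-ray factors.  Ionic/charged scattering is out of scope.
* Supported space groups are P1, P21, P212121, P43212 and its
  enantiomorph P41212 — enough for the simulator and the protein work
  this package targets.  Other symbols are rejected loudly.  Operator
  tables, centric/epsilon flags and systematic absences come from gemmi.
* Unique reflections use a canonical representative: the
  lexicographically largest index among all symmetry equivalents and
  Friedel mates.  Normalized amplitudes use `E^2 = I/(eps <I/eps>)` in
  equal-count `s^2` shells (20 by default), so `<|E|^2> = 1` holds
  exactly per shell; negative measured intensities are clipped before
  averaging, which preserves the identity on noisy data.

## Data-reduction heuristics

* **Scaling.** Each crystal is brought onto a reference crystal by
  `I ~ k exp(-2 B s^2) I_ref` with the linear factor solved in closed
  form inside a bounded 1-D search over B.  No partiality model, no
  error-model refinement.
* **CC1/2** is the Pearson correlation of half-set means under a seeded
  random split of each unique reflection's observations — simple and
  exactly reproducible; no sigma-tau refinement.
* **Damage-frame omission.** Radiation damage in the simulator (and in
  continuous-rotation experiments) suppresses high-resolution intensity
  on late frames.  Candidate trims of 0–6 trailing frames are scored by
  CC1/2 evaluated on the outer-resolution half of the observations and
  averaged over five seeded splits; the smallest trim achieving the best
  CC1/2 wins, provided it improves the untrimmed value by at least
  0.005.  Two measured facts drive this design: overall CC1/2 is
  dominated by strong low-resolution terms and barely responds to
  resolution-dependent damage, and single-split CC1/2 estimates carry
  0.01–0.07 of sampling noise, enough to stall a strict
  one-frame-at-a-time greedy loop.  An `overall` shell mode is
  available.
* **Merge-set selection.** All non-empty crystal subsets (capped at 16
  crystals) are screened for completeness above the threshold using
  cheap unique-index set unions; among the passing subsets of minimal
  cardinality the highest merged <I/sigma(I)> wins.

## Fragment generation

* **Sequential ("shred") mode** slides windows of 10–20 residues in
  steps of 4 along each break-free chain run (runs end at chain changes,
  residue-number gaps, or Calpha–Calpha distances above 4.5 A).  Windows
  are emitted as polyalanine extracts or as their complements (omit
  models).  Polyalanine retains N, CA, C, O and CB, with CB built at
  ideal tetrahedral geometry for glycine.
* **Shred descriptor.** Fragment scores are z-scored within each window
  size group and each residue receives the mean z-score of all fragments
  containing it.  The aggregation (mean of within-size z-scores) is this
  package's own reconstruction of a per-residue accuracy descriptor; it
  is invariant to affine rescaling of any single size group's scores.
* **Model selection** cuts up to four models per profile using four
  rules: peak regions (within 10% of a local maximum), plateaus (>= 6
  consecutive residues within 10% of their run maximum), residues above
  75% of the profile maximum (on the min-shifted scale), and residues
  above the smallest local-maximum value.  Models under 10 residues are
  dropped, duplicates deduplicated.  The plateau definition is a
  concrete stand-in chosen here; nothing downstream depends on its
  details.
* **Spherical mode** collects, for every residue, the `n` spatially
  nearest residues by Calpha distance, keeps contiguous runs of >= 3
  residues, and grows the neighbourhood if trimming leaves the model
  more than 10 residues short.  The model size can be derived from the
  expected LLG: `eLLG(n) = sum_acentric sigma_A^4/2 + sum_centric
  sigma_A^4/4` with `sigma_A = sqrt(n/N) exp(-2 pi^2 rmsd^2 s^2 / 3)`
  (`s = 1/d`), solved for the smallest `n` reaching the target (30 by
  default).

## Placement targets

* **Rotation function.** Patterson-correlation style: the Pearson
  correlation between observed `E^2` and the symmetry-summed squared
  molecular transform of the rotated fragment (shell-normalised),
  evaluated on a uniform zxz-Euler grid reduced to one representative
  per point-group orbit.  When the data exceed 768 reflections the
  strongest `|E^2 - 1|` subset is used — the terms that carry the
  Patterson signal — and the kernel runs in single precision; both are
  pure economies for a correlation score.  Rotation work defaults to the
  3.5–15 A window: for a ~1 A-rmsd model the sigma_A-degraded
  high-resolution terms actively mislead the search (measured on the
  synthetic benchmark: refinement started at the true orientation walks
  16–19 degrees away at full resolution but stays within 5 degrees in
  the windowed range).
* **Translation function.** The correlation of epsilon-aware normalized
  amplitudes (E-values); raw `|F|` correlation is dominated by the
  common Wilson falloff and accepts wrong placements with r ~ 0.7.  The
  full-resolution peak is only ~d_min/4 (~0.6 A) wide, far narrower
  than an affordable grid, so the search is two-stage: a 1/24-cell
  coarse grid at 4.5 A resolution over the Cheshire cell, then
  full-resolution rescoring of the best 200 coarse positions and their
  half-step neighbourhoods.  TFZ is the Z-score of the best coarse score
  against the coarse-scan distribution.  The plain `|F|` Pearson
  correlation is still reported (`cc`).  The Cheshire cell of
  P43212/P41212 is (1, 1/2, 1/2): the allowed-origin-shift group has
  order four and couples x with y, so a (1/2)^3 box would miss half of
  translation space.
* **Rigid-body refinement** is a Nelder-Mead maximisation of the
  translation score over six parameters (initial steps 2 degrees / 0.02
  fractional, tolerance 0.05 degrees / 0.002 fractional), with the
  objective on a strongest-E subset and the accept/reject decision made
  at full resolution; the returned placement never scores below the
  input.
* **Likelihood-gain score.** A Rice (acentric) / Woolfson (centric)
  log-likelihood of the observed E-values given `sigma_A E_calc`,
  relative to the Wilson null, with sigma_A as in eLLG sizing; it is
  identically zero at `sigma_A = 0` and is used to rank alternative
  placements, not to reproduce any external program's LLG values.
* **Packing filter.** A placement is rejected when more than 5% of its
  Calpha atoms approach a symmetry copy (its own or a prior placement's)
  closer than 3 A under the minimum-image convention.

## The end-to-end pipeline

The workflow anchors on the whole template before shredding: rotation
search (15-degree grid), greedy 15-degree clustering, local refinement
of each cluster, then a joint scan of each distinct cluster orientation
over small rotation-vector perturbations (+-4 degrees per axis) times
the translation-candidate set, with the winner chosen by refined,
unweighted E-correlation among placements that pass the packing filter.
Two measured facts make the joint scan necessary: the rotation-function
optimum for a 1 A-error model sits ~5 degrees off the true orientation
(beyond what the translation target tolerates), and helical decoy
orientations outscore the truth on the rotation target alone.  The
perturbations must be rotation-vector steps: small zxz-Euler triplets
span only two independent axes.  Shred windows are then scored at the
anchor orientation, the descriptor is built, up to four models are cut,
and each is independently translated, rigid-body refined and scored;
model phases carry Sim-style figures of merit
(`m = I1(X)/I0(X)`, `X = 2 sigma_A Eo Ec / (1 - sigma_A^2)`).

## Phase-error metric and maps

The weighted mean phase error is `sum w |dphi|_circ / sum w` over the
common index set, minimised over the space group's allowed origin
shifts (hard-coded tables; continuous axes are grid-searched at 1/24
and polished by simplex) and the enantiomorph flip (negated phases).
Weights default to the test set's figures of merit.  Fourier syntheses
use the crystallographic sign convention `rho(x) ~ sum F(h)
exp(-2 pi i h.x)` on symmetry-expanded grids whose dimensions respect
the space group's grid factors (default spacing d_min/3), standardised
to sigma units.  Difference maps use `m|Fo| - |Fc|` (or `2m|Fo| - |Fc|`)
coefficients with model phases; omit-map peak heights are read by
trilinear interpolation with lattice wrapping.

## Synthetic data: what it emulates and what it does not

`make_ground_truth` builds ideal-geometry polyalanine folds — an
antiparallel helix bundle (30-residue helices, 10.5 A apart, alternating
+-10 degree tilts giving a realistic ~20 degree crossing angle; exactly
parallel identical rods are a degenerate fold that creates artificial
translation decoys) or an antiparallel strand sheet — placed clash-free
in the cell by maximising the closest symmetry contact over a candidate
grid.  The default cell, 52 x 52 x 64 A in P43212, accommodates the
60-residue bundle with about 67% solvent.

`simulate_crystals` emulates the pathologies of multi-crystal
wedge-limited electron diffraction from already-integrated per-frame
intensities: each crystal observes the reflections whose scattering
vectors fall in a 60-degree azimuth band about a random rotation axis
(ten frames per wedge); a 20-degree tilt-limit cone about the crystal
c* axis — common to all crystals, as for plates lying flat on a support,
and stable under the tetragonal symmetry — is never sampled; per-crystal
scale (0.5–2.0) and relative B (0–4 A^2) differences, 10% relative
Gaussian noise, and s^2-weighted exponential damage
(`exp(-8 A^2 * frames-past-onset / d^2)`) on the trailing four frames.
All randomness flows from one seeded generator.  With the defaults, six
wedges merge to ~91–93% completeness at 2.5 A with CC1/2 ~ 0.99 and
merged <I/sigma(I)> in the tens — somewhat cleaner than typical real
data.  The simulator does not model images, spot shapes, dynamical
(multi-beam) scattering, absorption or absolute dose, so passing tests
demonstrate the correctness and internal consistency of the reduction
and phasing machinery, not robustness to those effects.

## Benchmark problem sizes

The end-to-end recovery experiment (also re-run by
`scripts/acceptance.py`) uses a 60-residue bundle, a homologue
perturbed to 1.0 A Calpha rmsd by smooth low-frequency modes (scaled by
bisection on the post-superposition rmsd), six-crystal simulation at
d_min 2.5 A (~3000 unique reflections), a 15-degree rotation grid,
shred windows of 15–25 residues in steps of 4, and up to four selected
models — about six minutes on one CPU.  These are the package's
chosen desk-scale conditions; larger templates and finer grids scale
accordingly.

## Known limitations

* Correlation-based targets, not full maximum-likelihood molecular
  replacement: scores are comparable ordinally with likelihood engines,
  never numerically.
* No density modification, autotracing, or atomic refinement; the
  pipeline ends at scored placements and their phase sets.
* Five space groups; no twinned-data handling beyond the L-test
  diagnostic; neutral-atom scattering only.
* The sequence_alignment pairing mode in `superpose` pairs Calpha atoms
  in chain order (adequate for the polyalanine fragments produced here),
  not by true sequence alignment.
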