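# Methods

`pharmqsar` implements a ligand-based modelling workflow for congeneric
inhibitor series — here tuned to 2-aminophenylbenzamide (benzamide-class)
HDAC1 inhibitors: a common-feature pharmacophore is elucidated from the most
potent ligands, used as the rigid alignment rule for an atom-based
occupancy-grid 3D-QSAR model fitted by partial least squares (PLS), and the
resulting model is validated by cross-validation, held-out prediction and
decoy-library screening.

## Molecule preparation

Structures arrive as SMILES or SDF with activities (IC50 in nM, or pIC50) in
a CSV.  pIC50 is on the **micromolar** scale throughout:
`pIC50 = -log10(IC50[nM] / 1000)`, so 1 uM maps to 0.0 and 10 nM to 2.0.
Potency classes: active `IC50 <= 10 nM`, moderate `10 nM < IC50 < 5 uM`,
inactive `5 uM <= IC50 <= 50 uM`; both stated boundaries are read as
inclusive and anything above 50 uM is flagged outside the modelled domain.

Ionization at pH 7.4 is rule-based, not a pKa predictor: carboxylic and
sulfonic acids are deprotonated; aliphatic amines, amidines and guanidines
are protonated; anilines, amides and azine nitrogens stay neutral.  The rule
table covers the chemistry of this compound class; exactly one ionization
state is emitted per ligand.  Tautomer and stereoisomer enumeration are out
of scope.

Conformers come from ETKDG distance-geometry embedding followed by MMFF94
minimization (at most 2000 iterations, force tolerance 1e-3).  MMFF94 is the
general-purpose force field this stack ships; no solvation correction is
applied.  Ensembles honor a 21 kJ/mol energy window above the minimum and a
0.5 Angstrom redundancy cutoff: conformers are admitted lowest-energy first
and rejected if their best-fit heavy-atom RMSD to any kept conformer falls
below the cutoff.  Everything is deterministic for a fixed seed.  On
n-hexane the stochastic search reproduces exactly the minima of an
exhaustive 120-degree torsion scan after identical pruning (a test oracle).

Train/test splitting is stratified: records are binned by pIC50 quantiles
(default 5 bins) and each bin is split at the training fraction with
largest-remainder rounding, so the response range is covered in both subsets
and 370 records at 70% give exactly 259/111.

## Feature perception and hypothesis search

Six feature kinds are perceived per conformer: hydrogen-bond acceptor (A),
donor (D), hydrophobic (H), negative (N), positive (P), aromatic ring (R).
Definitions live in an editable table (`chemdata.py`): SMARTS for A/D,
formal charges for N/P, aromatic rings (centroid + least-squares normal,
sign made covariant by pointing away from the molecular centroid; ring
normals are treated as axial, only |cos| is scored) and connected aliphatic
carbon clusters for H.  A and D carry unit direction vectors (lone-pair axis
approximated by the heavy-neighbor bisector; mean N-H/O-H axis).

Common k-point hypotheses (k = 5 by default) are enumerated by hashing every
k-subset of every active conformer's features on (kind multiset, sorted
inter-feature distances binned at 1.0 Angstrom).  The hash is computed on
two staggered grids (offsets 0 and half a bin) so a shared geometry cannot
be lost to a bin edge; this hashing is the toolkit's reproducible,
order-independent realization of tree-based partitioning of site distances.
A key attained by at least `min_matched` actives (default: all of them)
becomes a candidate, with geometry taken from the lowest-energy contributing
conformer.

Scoring aligns each active onto the candidate (all kind-respecting feature
assignments, least-squares rigid superposition, exhaustive for k <= 6) and
combines: `site` = 1 - mean RMSD / tolerance (clamped to [0,1]); `vector` =
mean cosine of matched direction vectors; `volume` = mean pairwise
common-volume ratio of the aligned actives, where the intersection of two
molecules is approximated per atom by its best-overlapping partner sphere
(symmetrized) — exact for single-atom molecules and 1 for identical poses;
`selectivity` = -log10 of the (add-half smoothed) match rate in a background
library when one is supplied, else 0; the matched fraction; the reference
ligand's pIC50 as the activity term; and the mean relative conformational
energy of the matched conformers as a penalty scaled by 1/(k x 2.5 kJ/mol),
a thermal energy per site.  All weights default to 1 and are configurable;
since the component magnitudes of the original commercial implementation are
not public, only the ranking behaviour is contractual.  The same site /
vector / volume / match terms evaluated on the inactive set (partial matches
allowed) give the inactive score, and the ranking criterion is the adjusted
survival score `survival - inactive_score`, with ties broken by lower
conformational energy, then lexicographic variant label.

## Alignment

`superpose` is the standard Kabsch SVD solution restricted to proper
rotations; it refuses fewer than three pairs or collinear point sets.
Matching a molecule to a hypothesis searches all conformers and all
kind-respecting feature assignments (batched closed-form RMSDs) and returns
the lowest-RMSD pose within the tolerance (default 2.0 Angstrom, a config
knob — the original study does not state one).  Partial matching (k-1 of k
features) is off during hypothesis generation and on for QSAR training,
prediction and screening, so compounds missing one feature are still placed
in the common frame while complete non-binders fall through to the floor
prediction.  Direction vectors never enter the positional least squares.

## Occupancy-grid QSAR

Aligned heavy atoms are classified into six descriptor classes (donor-H
carrier, hydrophobic carbon, negative, positive, electron-withdrawing /
acceptor, other); hydrogens are folded into their heavy atoms.  Van der
Waals radii (Bondi) are frozen in `chemdata.py` for bit-stable descriptors.
The grid (default spacing 0.5 Angstrom) covers all training poses plus a
2 Angstrom margin; the bit for (cube, class) is set iff the cube center lies
inside the atom's vdW sphere — the cheapest exactly testable occupancy rule,
verified against brute-force enumeration.  Columns are laid out as
active-cubes x classes, where active cubes are those occupied by at least
one training pose.

PLS models with 1..7 latent factors are fitted on the centered binary matrix
(scikit-learn's NIPALS `PLSRegression` under the package's own statistics
layer).  Reported statistics: training R^2; regression SD with
n - factors - 1 denominator; F and its p-value on (factors,
n - factors - 1) degrees of freedom; cross-validated Q^2 from seeded,
response-stratified 10-fold CV (the leave-n-out realization, n about 10%) as
1 - PRESS/SS_tot over concatenated held-out predictions; and Q^2_F3, which
normalizes mean squared test error by the biased training variance — equal
to 1 only for perfect predictions and about 0 for the mean predictor.
Factor selection stops at the smallest count whose SD reaches the assumed
experimental error (default: the generator's noise sigma, 0.3 pIC50 units),
falling back to the maximum-Q^2 model.  Molecules that fail to match the
hypothesis predict at the floor (minimum training pIC50), ranking them last;
this convention is what lets non-matching decoys enter a ROC ranking.  The
coefficient field is exported (CSV / pseudo-atom PDB, B-factor =
coefficient) above a 1.5e-2 magnitude threshold by default.

## Screening validation

A screen ranks the library by predicted pIC50 (ties broken by id) and cuts a
hit list: an explicit hit count overrides the fraction rule
`max(1, round(D x fraction))`.  The reference study used an explicit top-30
cutoff on its 5870-compound database (which it describes loosely as "about
1%"); both routes are exposed.  Metrics: EF = (Ha/Ht)/(A/D);
GH = [Ha(3A+Ht)/(4HtA)][1-(Ht-Ha)/(D-A)], which is confined to [0,1]
exactly on the physically realizable lattice (Ha <= min(Ht,A),
Ht - Ha <= D - A, enforced as preconditions); %YA = 100 Ha/Ht;
%RA = 100 Ha/A.  On the published screen counts (Ha=26, Ht=30, A=106,
D=5870) GH evaluates to 0.71; note EF on those same counts evaluates to
47.99 — the formula, not any printed rounding, is the contract here.  ROC
curves sweep all thresholds with ties as diagonal segments, so the trapezoid
AUC equals the normalized Mann-Whitney statistic (tested to 1e-12 against
the rank-sum).  External validation reports the squared Pearson correlation
of predicted vs experimental pIC50, refusing id overlap with training and
degenerate constant predictions.

## Synthetic libraries (what they emulate, and what they do not)

The generator (`synthlib`) emulates a benzamide HDAC1 SAR campaign without
any external data: N-(2-aminophenyl)arylamide scaffolds enumerated
combinatorially over a curated substituent table, with activity spanning
6 nM - 50 uM.  The planted pharmacophore is the ADDRR motif every scaffold
with an intact zinc-binding group and aromatic cap carries: amide carbonyl
acceptor, amide NH and aniline NH2 donors, two aromatic rings.  The
noiseless activity model is

    pIC50 = -1.45 + 3.3 x [motif intact] + z_eff + p_eff - m_penalty

with z_eff in 0..0.35 for small substituents para to the amide on the
aminophenyl ring (weakly beneficial), p_eff in 0..0.10 on the cap para
position (near-neutral), and m_penalty 0.9-1.6 for bulky cap-meta
substituents (steric penalty); Gaussian noise (sigma = 0.3 pIC50 units,
about a 2x IC50 assay error) is added and the result clipped to the assay
window.  Motif-breaking variants (N-methylated amide, des-amino or
2-methyl anilide, cyclohexyl cap) populate the inactive class.  Requested
class counts are sampled from the noiseless-class pools, so under zero noise
the realized classes match the request exactly.

Ground truth records the planted geometry (from the unsubstituted reference
scaffold at a fixed internal embedding seed, hence identical across library
seeds), per-compound noiseless activities, and effect regions in the planted
frame: `beneficial` — the zinc-binding/amide zone around the planted A/D
features, the dominant positive occupancy term (it is what inactives lack);
`substituent_beneficial` — the weak z-position term; `bulk` — the penalized
cap-meta zone.  Ground truth is never read by the pipeline under test.

Decoys are sampled from a combinatorial pool of non-amide scaffolds (diaryl
ethers/ketones/sulfones/sulfides, benzoates, stilbenes, bibenzyls and pyridyl
analogues) filtered per paired active to molecular weight within +/-25,
Crippen logP within +/-1, identical net charge, Lipinski drug-likeness, and
2D path-fingerprint Tanimoto < 0.4 to every active; each pool molecule is
emitted once.  With 20 actives at 50 decoys each the pool yields ~980 of
1000 (a warning reports any shortfall).

What the generator does **not** emulate: real assay heteroscedasticity and
inter-laboratory offsets, activity cliffs outside the planted terms,
tautomers/stereochemistry, scaffold diversity beyond one amide core, and
decoys drawn from a realistic purchasable-chemistry distribution.  Passing
the recovery tests therefore demonstrates that the pipeline recovers a
pharmacophore and structure-activity signal it is in principle able to
represent — not that it would achieve the same statistics on heterogeneous
literature data.

## Problem sizes and numerical choices

The validation study runs at 300 library compounds (40/140/120
active/moderate/inactive requested) with 1000 decoys, 10 conformers per
library molecule and 2 per decoy — benzamides are semi-rigid (a handful of
amide/biaryl rotamers), and a decoy's screen outcome is decided by its
feature complement rather than by deep conformational sampling.  Ten
conformers per active are enough that the common-key search (which by
default demands all 20 actives share a key) is robust; six was observed to
miss single-molecule rotamers occasionally.  Cross-validated Q^2 is computed
for the selected factor count.  Degenerate inputs fail loudly: constant
response, factor counts above the descriptor rank, collinear superposition
points, single-class ROC input, zero training variance in Q^2_F3.

## Known limitations

- The survival-score component magnitudes are this package's own
  normalization; only rankings are comparable across implementations.
- The rule-based ionizer is a pH-7.4 table, not a titration model.
- Occupancy bits are hard (center-in-sphere); no fractional-volume or
  Gaussian-field descriptors.
- Rigid alignment only; no torsional refinement against the hypothesis.
- The assignment search in matching is exhaustive and intended for k <= 6
  and at most ~8 features per kind.
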