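"""Chemical feature perception and common-feature pharmacophore elucidation.

A pharmacophore hypothesis is a k-point arrangement (default k = 5) of
feature kinds drawn from {A, D, H, N, P, R} that is shared by a set of
active ligands.  Candidate hypotheses are enumerated by hashing every
k-subset of every active conformer's features on (feature-kind multiset,
binned sorted inter-feature distances); a key attained by enough actives is
a common pharmacophore.  Candidates are then scored by aligning the actives
(and inactives) onto the candidate geometry and combining site, vector,
volume, selectivity, match-count, energy and activity terms into a survival
score; subtracting the score the inactive set achieves gives the adjusted
survival score used for final ranking.

The distance-key hashing plays the role of a tree-based partition of
inter-site distances: it is reproducible and independent of input order.
Keys are emitted on two staggered grids (offset 0 and bin_width/2) so that a
common geometry is not lost merely because a distance falls on a bin edge.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from . import chemdata
from .alignment import match_and_align, superpose

__all__ = [
    "FeaturePoint",
    "Hypothesis",
    "ScoringWeights",
    "perceive_features",
    "enumerate_hypotheses",
    "score_hypothesis",
    "select_best",
]

FEATURE_KINDS = ("A", "D", "H", "N", "P", "R")


@dataclass(frozen=True)
class FeaturePoint:
    """One perceived chemical feature on a conformer.

    ``direction`` is a unit vector for A/D (idealized interaction axis) and
    R (ring normal, axial: only |cos| is meaningful); ``None`` for H/N/P.
    """

    kind: str
    position: tuple[float, float, float]
    direction: tuple[float, float, float] | None = None
    atom_indices: tuple[int, ...] = ()

    @property
    def pos(self) -> np.ndarray:
        return np.array(self.position, dtype=float)


@dataclass
class Hypothesis:
    """A k-point pharmacophore with its geometry and scores."""

    features: list[FeaturePoint]
    tolerance: float = 2.0
    variant_label: str = ""
    ref_molecule_id: str = ""
    ref_pic50: float | None = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.variant_label:
            self.variant_label = "".join(sorted(f.kind for f in self.features))

    @property
    def k(self) -> int:
        return len(self.features)

    @property
    def distance_matrix(self) -> np.ndarray:
        pos = np.array([f.position for f in self.features])
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    @property
    def sorted_distances(self) -> np.ndarray:
        dm = self.distance_matrix
        iu = np.triu_indices(self.k, k=1)
        return np.sort(dm[iu])

    def to_dict(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "variant_label": self.variant_label,
            "ref_molecule_id": self.ref_molecule_id,
            "ref_pic50": self.ref_pic50,
            "scores": self.scores,
            "features": [
                {
                    "kind": f.kind,
                    "position": list(f.position),
                    "direction": list(f.direction) if f.direction else None,
                    "atom_indices": list(f.atom_indices),
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hypothesis":
        feats = [
            FeaturePoint(
                kind=fd["kind"],
                position=tuple(fd["position"]),
                direction=tuple(fd["direction"]) if fd["direction"] else None,
                atom_indices=tuple(fd["atom_indices"]),
            )
            for fd in d["features"]
        ]
        return cls(
            features=feats,
            tolerance=d["tolerance"],
            variant_label=d["variant_label"],
            ref_molecule_id=d["ref_molecule_id"],
            ref_pic50=d["ref_pic50"],
            scores=dict(d["scores"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Hypothesis":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# feature perception


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = np.linalg.norm(v)
    return v / n if n > 1e-8 else None


def _ring_normal(coords: np.ndarray, centroid: np.ndarray, mol_centroid: np.ndarray):
    """Least-squares plane normal; sign chosen covariantly with the geometry."""
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    outward = centroid - mol_centroid
    if abs(float(normal @ outward)) > 1e-6 and float(normal @ outward) < 0:
        normal = -normal
    return normal


def perceive_features(mol: Chem.Mol, coords: np.ndarray) -> list[FeaturePoint]:
    """Perceive pharmacophore features on one conformer.

    ``mol`` must carry explicit hydrogens consistent with ``coords`` (one row
    per atom).  Detection is substructure-driven (tables in
    :mod:`pharmqsar.chemdata`) plus geometric construction for ring centroids
    / normals and hydrophobic cluster centroids.  Output order is canonical:
    sorted by kind, then source atom indices.
    """
    if not any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()) and any(
        a.GetTotalNumHs() > 0 for a in mol.GetAtoms()
    ):
        raise ValueError(
            "molecule lacks explicit hydrogens; run conformer preparation first"
        )
    coords = np.asarray(coords, dtype=float)
    heavy_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    mol_centroid = coords[heavy_idx].mean(axis=0)
    feats: list[FeaturePoint] = []

    def heavy_neighbors(atom):
        return [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]

    # acceptors
    seen_a: set[int] = set()
    for smarts in chemdata.ACCEPTOR_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            ai = match[0]
            if ai in seen_a:
                continue
            seen_a.add(ai)
            atom = mol.GetAtomWithIdx(ai)
            nbrs = heavy_neighbors(atom)
            direction = None
            if nbrs:
                nbr_centroid = coords[[n.GetIdx() for n in nbrs]].mean(axis=0)
                direction = _unit(coords[ai] - nbr_centroid)
            feats.append(
                FeaturePoint(
                    kind="A",
                    position=tuple(coords[ai]),
                    direction=tuple(direction) if direction is not None else None,
                    atom_indices=(ai,),
                )
            )

    # donors: one feature per proton-bearing heavy atom
    seen_d: set[int] = set()
    for smarts in chemdata.DONOR_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            ai = match[0]
            if ai in seen_d:
                continue
            seen_d.add(ai)
            atom = mol.GetAtomWithIdx(ai)
            h_idx = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
            direction = None
            if h_idx:
                direction = _unit(coords[h_idx].mean(axis=0) - coords[ai])
            feats.append(
                FeaturePoint(
                    kind="D",
                    position=tuple(coords[ai]),
                    direction=tuple(direction) if direction is not None else None,
                    atom_indices=(ai,),
                )
            )

    # charged groups
    for atom in mol.GetAtoms():
        chg = atom.GetFormalCharge()
        if chg == 0 or atom.GetAtomicNum() == 1:
            continue
        feats.append(
            FeaturePoint(
                kind="N" if chg < 0 else "P",
                position=tuple(coords[atom.GetIdx()]),
                atom_indices=(atom.GetIdx(),),
            )
        )

    # aromatic rings
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        rc = coords[list(ring)]
        centroid = rc.mean(axis=0)
        normal = _ring_normal(rc, centroid, mol_centroid)
        feats.append(
            FeaturePoint(
                kind="R",
                position=tuple(centroid),
                direction=tuple(normal),
                atom_indices=tuple(sorted(ring)),
            )
        )

    # hydrophobic clusters: connected aliphatic carbons with only C/H contacts
    hydro = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors()):
            hydro.add(atom.GetIdx())
    visited: set[int] = set()
    for start in sorted(hydro):
        if start in visited:
            continue
        stack, cluster = [start], []
        while stack:
            a = stack.pop()
            if a in visited:
                continue
            visited.add(a)
            cluster.append(a)
            for n in mol.GetAtomWithIdx(a).GetNeighbors():
                if n.GetIdx() in hydro and n.GetIdx() not in visited:
                    stack.append(n.GetIdx())
        cluster.sort()
        feats.append(
            FeaturePoint(
                kind="H",
                position=tuple(coords[cluster].mean(axis=0)),
                atom_indices=tuple(cluster),
            )
        )

    feats.sort(key=lambda f: (f.kind, f.atom_indices))
    return feats


def ensemble_features(ensemble) -> list[list[FeaturePoint]]:
    """Perceive features for every conformer of an ensemble."""
    return [perceive_features(ensemble.mol, coords) for coords, _ in ensemble.conformers]


# ---------------------------------------------------------------------------
# hypothesis enumeration


def _distance_keys(dists: np.ndarray, bin_width: float):
    """Keys on two staggered grids so bin-edge jitter cannot split a motif."""
    k0 = tuple(np.floor(dists / bin_width).astype(int).tolist())
    k1 = tuple(np.floor(dists / bin_width + 0.5).astype(int).tolist())
    return (0, k0), (1, k1)


def enumerate_hypotheses(
    actives: list,
    k: int = 5,
    bin_width: float = 1.0,
    min_matched: int | None = None,
    tolerance: float = 2.0,
    features_per_active: list[list[list[FeaturePoint]]] | None = None,
) -> list[Hypothesis]:
    """Enumerate common k-point pharmacophore candidates across actives.

    Every k-subset of every active conformer's features is keyed by its
    feature-kind multiset and its 10 (for k = 5) sorted inter-feature
    distances discretized at ``bin_width``.  Keys shared by at least
    ``min_matched`` actives (default: all of them) become candidates; the
    candidate geometry is taken from the lowest-energy contributing
    conformer.  Output is deterministic and independent of active ordering.
    """
    if len(actives) < 2:
        raise ValueError("need at least 2 actives to search for common features")
    if min_matched is None:
        min_matched = len(actives)
    if features_per_active is None:
        features_per_active = [ensemble_features(e) for e in actives]

    # key -> active_index -> best contribution (rel_energy, mol_id, ci, feat idx)
    table: dict[tuple, dict[int, tuple]] = {}
    for ai, (ens, conf_feats) in enumerate(zip(actives, features_per_active)):
        for ci, (coords, rel_e) in enumerate(ens.conformers):
            feats = conf_feats[ci]
            n = len(feats)
            if n < k:
                continue
            pos = np.array([f.position for f in feats])
            diff = pos[:, None, :] - pos[None, :, :]
            dm = np.sqrt((diff**2).sum(axis=-1))
            for subset in itertools.combinations(range(n), k):
                kinds = "".join(sorted(feats[i].kind for i in subset))
                idx = np.array(subset)
                dists = np.sort(dm[np.ix_(idx, idx)][np.triu_indices(k, 1)])
                for gkey in _distance_keys(dists, bin_width):
                    key = (kinds, gkey)
                    entry = table.setdefault(key, {})
                    cand = (rel_e, ens.molecule_id, ci, subset)
                    if ai not in entry or cand < entry[ai]:
                        entry[ai] = cand

    out: list[Hypothesis] = []
    emitted: set[tuple] = set()
    for key in sorted(table, key=lambda kk: (kk[0], kk[1])):
        entry = table[key]
        if len(entry) < min_matched:
            continue
        rel_e, mol_id, ci, subset = min(entry.values())
        ident = (mol_id, ci, subset)
        if ident in emitted:  # same geometry found via the staggered grid
            continue
        emitted.add(ident)
        ai = next(a for a, v in entry.items() if v == (rel_e, mol_id, ci, subset))
        ens = actives[ai]
        feats = [features_per_active[ai][ci][i] for i in subset]
        centroid = np.array([f.position for f in feats]).mean(axis=0)
        centered = [
            FeaturePoint(
                kind=f.kind,
                position=tuple(np.array(f.position) - centroid),
                direction=f.direction,
                atom_indices=f.atom_indices,
            )
            for f in feats
        ]
        h = Hypothesis(
            features=centered,
            tolerance=tolerance,
            ref_molecule_id=mol_id,
            ref_pic50=ens.pic50,
            scores={"matches": len(entry), "energy": rel_e},
        )
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScoringWeights:
    """Survival-score weights; energy enters as a subtractive penalty scaled
    by 1/(k * 2.5 kJ/mol), a thermal-energy-per-site normalization."""

    site: float = 1.0
    vector: float = 1.0
    volume: float = 1.0
    selectivity: float = 1.0
    matches: float = 1.0
    activity: float = 1.0
    energy: float = 1.0


def _sphere_overlap_volume(r1: float, r2: float, d: float) -> float:
    """Exact intersection volume of two spheres (lens formula)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r**3
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def _heavy_spheres(ensemble, pose):
    mol = ensemble.mol
    coords, _ = ensemble.conformers[pose.conformer_index]
    idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    radii = np.array(
        [chemdata.vdw_radius(mol.GetAtomWithIdx(i).GetSymbol()) for i in idx]
    )
    return pose.transform(coords[idx]), radii


def pairwise_volume_ratio(c1, r1, c2, r2) -> float:
    """Common-volume ratio of two aligned molecules, in [0, 1].

    The intersection is approximated per atom by its best-overlapping partner
    sphere on the other molecule (symmetrized over both directions); summing
    all cross pairs instead would over-count shared volume badly for
    well-aligned molecules.  The ratio is intersection / union with each
    molecule's volume taken as the sum of its atomic sphere volumes.  For two
    single-atom molecules this reduces to the exact two-sphere overlap ratio;
    identical superposed molecules give 1.
    """
    if len(r1) == 0 or len(r2) == 0:
        return 0.0
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
    lens = np.zeros_like(d)
    for i in range(len(r1)):
        for j in range(len(r2)):
            if d[i, j] < r1[i] + r2[j]:
                lens[i, j] = _sphere_overlap_volume(r1[i], r2[j], d[i, j])
    inter = 0.5 * (lens.max(axis=1).sum() + lens.max(axis=0).sum())
    v1 = float((4.0 / 3.0 * np.pi * r1**3).sum())
    v2 = float((4.0 / 3.0 * np.pi * r2**3).sum())
    union = v1 + v2 - inter
    return inter / union if union > 0 else 0.0


def _alignment_components(h, ensembles, features, require_all, max_volume_pairs=200):
    matched: list[tuple[int, object]] = []
    for ei, (ens, feats) in enumerate(zip(ensembles, features)):
        pose = match_and_align(ens, feats, h, tol=h.tolerance, require_all=require_all)
        if pose is not None:
            matched.append((ei, pose))
    if not matched:
        return None
    poses = [p for _, p in matched]
    matched_ens = [ensembles[ei] for ei, _ in matched]
    site = max(0.0, min(1.0, 1.0 - float(np.mean([p.rmsd for p in poses])) / h.tolerance))
    cosines = []
    for (ei, pose), ens in zip(matched, matched_ens):
        conf_feats = features[ei][pose.conformer_index]
        for hi, li in pose.mapping:
            hd = h.features[hi].direction
            ld = conf_feats[li].direction
            if hd is None or ld is None:
                continue
            rotated = pose.rotation @ np.array(ld)
            c = float(np.dot(rotated, np.array(hd)))
            if h.features[hi].kind == "R":  # ring normals are axial
                c = abs(c)
            cosines.append(c)
    vector = float(np.mean(cosines)) if cosines else 1.0
    spheres = [_heavy_spheres(ens, pose) for ens, pose in zip(matched_ens, poses)]
    ratios = []
    pair_count = 0
    for i in range(len(spheres)):
        for j in range(i + 1, len(spheres)):
            ratios.append(
                pairwise_volume_ratio(spheres[i][0], spheres[i][1], spheres[j][0], spheres[j][1])
            )
            pair_count += 1
            if pair_count >= max_volume_pairs:
                break
        if pair_count >= max_volume_pairs:
            break
    volume = float(np.mean(ratios)) if ratios else 1.0
    energy = float(np.mean([ens.conformers[p.conformer_index][1] for ens, p in zip(matched_ens, poses)]))
    return {
        "poses": poses,
        "site": site,
        "vector": vector,
        "volume": volume,
        "energy": energy,
        "matched": len(poses),
    }


def score_hypothesis(
    h: Hypothesis,
    actives: list,
    inactives: list | None = None,
    weights: ScoringWeights | None = None,
    background: list | None = None,
    features_actives=None,
    features_inactives=None,
    features_background=None,
) -> Hypothesis:
    """Score a candidate hypothesis against actives (and optionally inactives).

    Components: ``site`` (1 - mean alignment RMSD / tolerance, clamped),
    ``vector`` (mean cosine of matched feature directions), ``volume`` (mean
    pairwise common-volume ratio of the aligned actives), ``selectivity``
    (-log10 of the match rate in a background library, add-half smoothed),
    ``matches`` (count of actives matched), ``energy`` (mean relative
    conformational energy of matched conformers, a penalty) and ``activity``
    (pIC50 of the reference ligand).  ``survival`` is their weighted sum;
    ``inactive_score`` applies the same alignment components to the inactive
    set (partial matches allowed) and ``adjusted_survival = survival -
    inactive_score`` exactly.
    """
    w = weights or ScoringWeights()
    if features_actives is None:
        features_actives = [ensemble_features(e) for e in actives]
    comp = _alignment_components(h, actives, features_actives, require_all=True)
    if comp is None:
        raise ValueError("hypothesis matches none of the actives it came from")

    selectivity = 0.0
    if background:
        if features_background is None:
            features_background = [ensemble_features(e) for e in background]
        n_hit = sum(
            1
            for ens, feats in zip(background, features_background)
            if match_and_align(ens, feats, h, tol=h.tolerance, require_all=True)
            is not None
        )
        selectivity = -math.log10((n_hit + 0.5) / (len(background) + 1.0))

    activity = h.ref_pic50 if h.ref_pic50 is not None else 0.0
    k = h.k
    survival = (
        w.site * comp["site"]
        + w.vector * comp["vector"]
        + w.volume * comp["volume"]
        + w.selectivity * selectivity
        + w.matches * comp["matched"] / len(actives)
        + w.activity * activity
        - w.energy * comp["energy"] / (k * 2.5)
    )

    inactive_score = 0.0
    if inactives:
        if features_inactives is None:
            features_inactives = [ensemble_features(e) for e in inactives]
        icomp = _alignment_components(
            h, inactives, features_inactives, require_all=False
        )
        if icomp is not None:
            inactive_score = (
                w.site * icomp["site"]
                + w.vector * icomp["vector"]
                + w.volume * icomp["volume"]
                + w.matches * icomp["matched"] / len(inactives)
            )
    else:
        warnings.warn("no inactives supplied; inactive score set to 0")

    scores = dict(h.scores)
    scores.update(
        site=comp["site"],
        vector=comp["vector"],
        volume=comp["volume"],
        selectivity=selectivity,
        matches=comp["matched"],
        energy=comp["energy"],
        activity=activity,
        survival=survival,
        inactive_score=inactive_score,
        adjusted_survival=survival - inactive_score,
    )
    return replace(h, scores=scores)


def select_best(candidates: list[Hypothesis]) -> Hypothesis:
    """Top-ranked hypothesis: maximum adjusted survival score, ties broken by
    lower conformational energy, then lexicographic variant label."""
    if not candidates:
        raise ValueError("no candidate hypotheses to select from")
    return min(
        candidates,
        key=lambda h: (
            -h.scores.get("adjusted_survival", float("-inf")),
            h.scores.get("energy", float("inf")),
            h.variant_label,
        ),
    )
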