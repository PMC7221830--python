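"""Seed-controlled synthetic benzamide-like libraries with a planted pharmacophore.

The generator emulates the data regime of a benzamide HDAC1-inhibitor SAR
campaign: a few hundred N-(2-aminophenyl)arylamides whose potency spans five
orders of magnitude (IC50 from 6 nM to 50 uM), governed by a planted
five-feature pharmacophore (one H-bond acceptor on the amide carbonyl, two
donors on the amide NH and the 2-amino group, two aromatic rings) plus
substituent effects and Gaussian noise, together with property-matched
topologically dissimilar decoys.

Scaffold enumeration is combinatorial over a curated substituent table:
every compound is a (zinc-binding-group variant) x (aroyl cap) x
(substituent) combination.  Motif-breaking variants (N-methylated amide,
des-amino anilide, cyclohexyl cap) provide the inactives; bulky meta
substituents on the cap ring provide a steric penalty region, and small
substituents para to the amide on the aminophenyl ring a beneficial region
(the two regions sit on opposite ends of the scaffold).  The noiseless
activity model is

    pIC50 = -1.45 + 3.3 * [full motif] + z_eff + p_eff - m_penalty + N(0, sigma)

clipped to the 6 nM .. 50 uM window (pIC50 on the micromolar scale).
Ground truth (planted geometry, region labels, noiseless activities) is
recorded separately and is never consumed by the modelling pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, DataStructs, Descriptors

from .molprep import (
    ActivityClass,
    MoleculeRecord,
    Role,
    classify_activity,
    from_pic50,
    generate_conformers,
)
from .pharmacophore import perceive_features

__all__ = [
    "SyntheticLibrarySpec",
    "SyntheticLibrary",
    "generate_library",
    "generate_decoys",
    "planted_ground_truth",
]

PIC50_MAX = 2.2218487496163564  # 6 nM
PIC50_MIN = -1.6989700043360187  # 50 uM
_GEOMETRY_SEED = 20  # reference geometry is seed-independent by design


def _b(sub: str) -> str:
    return f"({sub})" if sub else ""


# substituent -> (smiles fragment, activity effect)
# z: beneficial position (para on the aminophenyl ring, far from the cap so
# the beneficial and steric regions are spatially disjoint)
Z_SUBS = {
    "H": ("", 0.0),
    "F": ("F", 0.20),
    "Me": ("C", 0.25),
    "Et": ("CC", 0.27),
    "OMe": ("OC", 0.30),
    "CF3": ("C(F)(F)F", 0.32),
    "Cl": ("Cl", 0.35),
}
# p: near-neutral decoration on the cap para position
P_SUBS = {
    "H": ("", 0.0),
    "F": ("F", 0.05),
    "Cl": ("Cl", 0.08),
    "Me": ("C", 0.10),
}
M_SUBS = {  # steric bulk at the cap meta position: activity penalty
    "H": ("", 0.0),
    "iPr": ("C(C)C", 0.9),
    "tBu": ("C(C)(C)C", 1.3),
    "Ph": ("c2ccccc2", 1.6),
}
ZBGS = ("full", "phenyl", "tolyl", "nmethyl")  # only "full" completes the motif
CAPS = ("phenyl", "pyridyl", "cyclohexyl")  # cyclohexyl removes one ring

BASE_PIC50 = -1.45
MOTIF_EFFECT = 3.3


def _cap_smiles(cap: str, p: str, m: str) -> str:
    pf, mf = P_SUBS[p][0], M_SUBS[m][0]
    if cap == "phenyl":
        return f"c1cc{_b(mf)}c{_b(pf)}cc1"
    if cap == "pyridyl":
        return f"c1nc{_b(mf)}c{_b(pf)}cc1"
    if cap == "cyclohexyl":
        return "C1CCCCC1"
    raise ValueError(cap)


def _variant_smiles(zbg: str, cap: str, p: str, z: str, m: str) -> str:
    zf = Z_SUBS[z][0]
    cap_s = _cap_smiles(cap, p, m)
    if zbg == "full":
        return f"O=C({cap_s})Nc1ccc{_b(zf)}cc1N"
    if zbg == "phenyl":
        return f"O=C({cap_s})Nc1ccc{_b(zf)}cc1"
    if zbg == "tolyl":
        return f"O=C({cap_s})Nc1ccc{_b(zf)}cc1C"
    if zbg == "nmethyl":
        return f"O=C({cap_s})N(C)c1ccc{_b(zf)}cc1N"
    raise ValueError(zbg)


@dataclass(frozen=True)
class Variant:
    zbg: str
    cap: str
    p: str
    z: str
    m: str

    @property
    def has_motif(self) -> bool:
        return self.zbg == "full" and self.cap in ("phenyl", "pyridyl")

    @property
    def smiles(self) -> str:
        return _variant_smiles(self.zbg, self.cap, self.p, self.z, self.m)

    @property
    def pic50_true(self) -> float:
        raw = (
            BASE_PIC50
            + (MOTIF_EFFECT if self.has_motif else 0.0)
            + P_SUBS[self.p][1]
            + Z_SUBS[self.z][1]
            - M_SUBS[self.m][1]
        )
        return float(np.clip(raw, PIC50_MIN, PIC50_MAX))


def enumerate_variants() -> list[Variant]:
    """All chemically distinct scaffold/substituent combinations, in a fixed
    deterministic order."""
    out = []
    for zbg in ZBGS:
        for cap in CAPS:
            p_opts = tuple(P_SUBS) if cap != "cyclohexyl" else ("H",)
            m_opts = tuple(M_SUBS) if cap != "cyclohexyl" else ("H",)
            for p in p_opts:
                for z in Z_SUBS:
                    for m in m_opts:
                        out.append(Variant(zbg, cap, p, z, m))
    return out


@dataclass
class SyntheticLibrarySpec:
    """Study conditions for one synthetic library."""

    n_actives: int = 40
    n_moderate: int = 140
    n_inactive: int = 120
    n_decoys_per_active: int = 50
    noise_sigma: float = 0.3
    seed: int = 0
    planted_motif: str = "ADDRR"

    def __post_init__(self):
        if min(self.n_actives, self.n_moderate, self.n_inactive) < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticLibrary:
    spec: SyntheticLibrarySpec
    records: list[MoleculeRecord]
    ground_truth: dict

    def write(self, out_dir) -> None:
        """SMILES + activity CSV (ingest dialect) + ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "library.smi", "w") as fh:
            for r in self.records:
                fh.write(f"{Chem.MolToSmiles(r.mol)}\t{r.id}\n")
        with open(out / "activities.csv", "w") as fh:
            fh.write("id,ic50_nM\n")
            for r in self.records:
                fh.write(f"{r.id},{r.ic50:.6f}\n")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


def planted_ground_truth() -> dict:
    """Geometry of the planted pharmacophore and of the effect regions.

    Derived from the unsubstituted reference scaffold's lowest-energy
    conformer (fixed internal seed, so it is identical for every library
    seed).  Coordinates are centered on the planted-feature centroid.

    Regions mirror the generator's activity model: 'beneficial' is the
    zinc-binding/amide zone around the planted acceptor and donor features —
    the substituents inactives lack, and the dominant positive activity term;
    'substituent_beneficial' is the weakly potency-raising para position of
    the aminophenyl ring; 'bulk' is the sterically penalized cap meta
    position.  'beneficial' and 'bulk' sit on opposite ends of the scaffold,
    so coefficient-field attribution between them is unambiguous.
    """
    ref = Variant("full", "phenyl", "H", "H", "H")
    rec = MoleculeRecord(id="__ref__", mol=Chem.MolFromSmiles(ref.smiles))
    ens = generate_conformers(rec, max_confs=20, seed=_GEOMETRY_SEED)
    coords, _ = ens.conformers[0]
    feats = perceive_features(ens.mol, coords)
    motif = [f for f in feats if f.kind in "ADR"]
    kinds = "".join(sorted(f.kind for f in motif))
    if kinds != "ADDRR":  # construction guarantee
        raise RuntimeError(f"reference scaffold perceived as {kinds}, not ADDRR")
    pos = np.array([f.position for f in motif])
    centroid = pos.mean(axis=0)
    pos -= centroid
    diff = pos[:, None, :] - pos[None, :, :]
    dists = np.sort(diff.__pow__(2).sum(-1)[np.triu_indices(5, 1)] ** 0.5)

    # cap ring = ring bonded to the carbonyl carbon (atom 1 in construction
    # order: O=C(...)...); aminophenyl ring = ring bonded to the amide N
    mol = ens.mol
    carbonyl_c = 1
    assert mol.GetAtomWithIdx(carbonyl_c).GetSymbol() == "C"
    cap_attach = next(
        n.GetIdx()
        for n in mol.GetAtomWithIdx(carbonyl_c).GetNeighbors()
        if n.GetIsAromatic()
    )
    amide_n = next(
        n.GetIdx()
        for n in mol.GetAtomWithIdx(carbonyl_c).GetNeighbors()
        if n.GetSymbol() == "N"
    )
    zbg_attach = next(
        n.GetIdx()
        for n in mol.GetAtomWithIdx(amide_n).GetNeighbors()
        if n.GetIsAromatic()
    )
    rings = mol.GetRingInfo().AtomRings()
    cap_ring = next(r for r in rings if cap_attach in r)
    zbg_ring = next(r for r in rings if zbg_attach in r)

    def ring_position(ring, attach, which):
        ring_coords = coords[list(ring)]
        d = np.linalg.norm(ring_coords - coords[attach], axis=1)
        if which == "para":
            return ring[int(np.argmax(d))], ring_coords.mean(axis=0)
        return ring[int(np.argsort(d)[-2])], ring_coords.mean(axis=0)

    def region(atom_idx, ring_centroid):
        outward = coords[atom_idx] - ring_centroid
        outward /= np.linalg.norm(outward)
        center = coords[atom_idx] + 2.2 * outward - centroid
        return {"center": center.tolist(), "radius": 3.0}

    z_atom, z_centroid = ring_position(zbg_ring, zbg_attach, "para")
    m_atom, m_centroid = ring_position(cap_ring, cap_attach, "meta")
    ad_centers = [
        list(p) for p, f in zip(pos.tolist(), motif) if f.kind in ("A", "D")
    ]
    return {
        "kinds": kinds,
        "feature_kinds": [f.kind for f in motif],
        "feature_positions": pos.tolist(),
        "sorted_distances": dists.tolist(),
        "regions": {
            "beneficial": {"centers": ad_centers, "radius": 2.5},
            "substituent_beneficial": {
                "centers": [region(z_atom, z_centroid)["center"]],
                "radius": 3.0,
            },
            "bulk": {
                "centers": [region(m_atom, m_centroid)["center"]],
                "radius": 3.0,
            },
        },
    }


def generate_library(spec: SyntheticLibrarySpec) -> SyntheticLibrary:
    """Sample a library realizing the spec's class counts.

    Variants are pooled by their noiseless activity class, sampled without
    replacement per class, then Gaussian noise is added to the activities and
    the result clipped to the 6 nM - 50 uM window.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    variants = enumerate_variants()
    pools: dict[ActivityClass, list[int]] = {}
    for i, v in enumerate(variants):
        cls = classify_activity(from_pic50(v.pic50_true))
        pools.setdefault(cls, []).append(i)

    chosen: list[int] = []
    for cls, n in (
        (ActivityClass.ACTIVE, spec.n_actives),
        (ActivityClass.MODERATE, spec.n_moderate),
        (ActivityClass.INACTIVE, spec.n_inactive),
    ):
        pool = pools.get(cls, [])
        if n > len(pool):
            raise ValueError(
                f"requested {n} {cls.value} compounds but the scaffold space "
                f"only provides {len(pool)}"
            )
        picked = rng.choice(len(pool), size=n, replace=False)
        chosen.extend(pool[i] for i in sorted(picked.tolist()))

    chosen.sort()
    records: list[MoleculeRecord] = []
    gt_compounds = []
    noise = rng.normal(0.0, spec.noise_sigma, size=len(chosen))
    for row, (vi, eps) in enumerate(zip(chosen, noise)):
        v = variants[vi]
        pic50_noisy = float(np.clip(v.pic50_true + eps, PIC50_MIN, PIC50_MAX))
        ic50 = from_pic50(pic50_noisy)
        rid = f"syn-{row + 1:04d}"
        mol = Chem.MolFromSmiles(v.smiles)
        if mol is None:
            raise RuntimeError(f"internal scaffold SMILES failed: {v.smiles}")
        records.append(
            MoleculeRecord(
                id=rid,
                mol=mol,
                ic50=ic50,
                pic50=pic50_noisy,
                activity_class=classify_activity(ic50),
            )
        )
        gt_compounds.append(
            {
                "id": rid,
                "smiles": v.smiles,
                "zbg": v.zbg,
                "cap": v.cap,
                "p": v.p,
                "z": v.z,
                "m": v.m,
                "motif": v.has_motif,
                "pic50_true": v.pic50_true,
                "pic50_noisy": pic50_noisy,
                "ic50_nM": ic50,
            }
        )

    ground_truth = {
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "planted": planted_ground_truth(),
        "compounds": gt_compounds,
    }
    return SyntheticLibrary(spec=spec, records=records, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# decoys

_DECOY_SCAFFOLDS = (
    "c1cc{S1}ccc1Oc1ccc{S2}cc1",          # diaryl ether
    "c1cc{S1}ccc1C(=O)c1ccc{S2}cc1",      # benzophenone
    "c1cc{S1}ccc1Cc1ccc{S2}cc1",          # diphenylmethane
    "c1cc{S1}ccc1Oc1ccc{S2}cn1",          # phenoxypyridine
    "c1cc{S1}ccc1S(=O)(=O)c1ccc{S2}cc1",  # diaryl sulfone
    "c1cc{S1}ccc1C=Cc1ccc{S2}cc1",        # stilbene
    "c1cc{S1}ccc1OCc1ccc{S2}cc1",         # benzyl aryl ether
    "c1cc{S1}ccc1C(=O)Oc1ccc{S2}cc1",     # phenyl benzoate
    "c1cc{S1}ccc1Sc1ccc{S2}cc1",          # diaryl sulfide
    "c1cc{S1}ccc1CCc1ccc{S2}cc1",         # bibenzyl
    "c1cc{S1}ccc1Oc1ccc{S2}nc1",          # phenoxypyridine (2-isomer)
    "c1cc{S1}ccc1C(=O)c1ccc{S2}cn1",      # phenyl pyridyl ketone
    "c1cc{S1}ccc1S(=O)(=O)c1ccc{S2}cn1",  # phenyl pyridyl sulfone
    "c1cc{S1}ccc1OCCOc1ccc{S2}cc1",       # ethylene glycol diaryl ether
    "c1cc{S1}ccc1C(=O)Cc1ccc{S2}cc1",     # deoxybenzoin
)
_DECOY_SUBS = (
    "", "F", "Cl", "Br", "C", "CC", "OC", "C(C)C", "C(F)(F)F", "OCC",
    "CC(C)C", "OC(C)C", "C#N", "S(C)(=O)=O", "OC(F)(F)F", "CCC",
)


def _decoy_pool() -> list[Chem.Mol]:
    pool = []
    seen = set()
    for scaf in _DECOY_SCAFFOLDS:
        for s1 in _DECOY_SUBS:
            for s2 in _DECOY_SUBS:
                smi = scaf.format(S1=_b(s1), S2=_b(s2))
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                canon = Chem.MolToSmiles(mol)
                if canon in seen:
                    continue
                seen.add(canon)
                pool.append(mol)
    return pool


def _lipinski_ok(mol) -> bool:
    return (
        Descriptors.MolWt(mol) <= 500
        and Crippen.MolLogP(mol) <= 5
        and Descriptors.NumHDonors(mol) <= 5
        and Descriptors.NumHAcceptors(mol) <= 10
    )


def generate_decoys(
    actives: list[MoleculeRecord],
    n_per: int = 50,
    seed: int = 0,
    mw_window: float = 25.0,
    logp_window: float = 1.0,
    tanimoto_max: float = 0.4,
) -> list[MoleculeRecord]:
    """Property-matched, topologically dissimilar decoys for a set of actives.

    Candidates come from a combinatorial non-amide scaffold pool and must,
    for their paired active, match molecular weight within ``mw_window`` and
    computed logP within ``logp_window``, carry the same net formal charge,
    be drug-like (Lipinski), and have 2D path-fingerprint Tanimoto below
    ``tanimoto_max`` to *every* active.  Each pool molecule is emitted at
    most once.  If a pairing cannot be filled, a warning reports the
    achieved count.
    """
    import warnings

    if not actives:
        raise ValueError("need at least one active to pair decoys against")
    if n_per == 0:
        return []
    rng = np.random.default_rng(seed)
    pool = _decoy_pool()
    active_fps = [Chem.RDKFingerprint(r.mol) for r in actives]
    active_charges = {sum(a.GetFormalCharge() for a in r.mol.GetAtoms()) for r in actives}

    cand = []
    for mol in pool:
        if not _lipinski_ok(mol):
            continue
        fp = Chem.RDKFingerprint(mol)
        if any(DataStructs.TanimotoSimilarity(fp, afp) >= tanimoto_max for afp in active_fps):
            continue
        cand.append(
            (
                mol,
                Descriptors.MolWt(mol),
                Crippen.MolLogP(mol),
                sum(a.GetFormalCharge() for a in mol.GetAtoms()),
            )
        )

    used: set[int] = set()
    out: list[MoleculeRecord] = []
    for rec in actives:
        mw = Descriptors.MolWt(rec.mol)
        logp = Crippen.MolLogP(rec.mol)
        chg = sum(a.GetFormalCharge() for a in rec.mol.GetAtoms())
        eligible = [
            i
            for i, (_, cmw, clogp, cchg) in enumerate(cand)
            if i not in used
            and abs(cmw - mw) <= mw_window
            and abs(clogp - logp) <= logp_window
            and cchg == chg
        ]
        take = min(n_per, len(eligible))
        if take < n_per:
            warnings.warn(
                f"decoy pool exhausted for active {rec.id}: {take}/{n_per}"
            )
        picked = rng.choice(len(eligible), size=take, replace=False) if take else []
        for j in sorted(int(x) for x in picked):
            used.add(eligible[j])
            out.append(
                MoleculeRecord(
                    id=f"dec-{len(out) + 1:04d}",
                    mol=cand[eligible[j]][0],
                    role=Role.DECOY,
                )
            )
    return out
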