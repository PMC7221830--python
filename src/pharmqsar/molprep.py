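"""Dataset ingest, ionization, conformer generation and activity handling.

The preparation stage of the modelling pipeline: molecules arrive as SMILES
or SDF plus a CSV activity table (IC50 in nM or pIC50 directly), are assigned
their most probable ionization state at physiological pH by a small rule
table, and are expanded into pruned 3D conformer ensembles (stochastic
embedding + force-field minimization, retaining conformers within an energy
window and removing redundant geometries by best-fit heavy-atom RMSD).

Activity conventions
--------------------
pIC50 is on the micromolar scale: ``pIC50 = -log10(IC50[nM] / 1000)``, so
1 uM -> 0.0 and 10 nM -> 2.0.  Potency classes: active (IC50 <= 10 nM),
moderate (10 nM < IC50 < 5 uM), inactive (5 uM <= IC50 <= 50 uM); anything
above 50 uM is outside the modelled domain.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem import rdMolAlign

__all__ = [
    "ActivityClass",
    "Role",
    "MoleculeRecord",
    "ConformerEnsemble",
    "read_dataset",
    "ionize",
    "generate_conformers",
    "classify_activity",
    "to_pic50",
    "from_pic50",
    "split_dataset",
]

KCAL_TO_KJ = 4.184


class ActivityClass(str, Enum):
    ACTIVE = "active"
    MODERATE = "moderate"
    INACTIVE = "inactive"
    OUT_OF_DOMAIN = "out_of_domain"


class Role(str, Enum):
    TRAIN = "train"
    TEST = "test"
    EXTERNAL = "external"
    DECOY = "decoy"
    UNASSIGNED = "unassigned"


@dataclass
class MoleculeRecord:
    """A compound with (optional) activity annotations."""

    id: str
    mol: Chem.Mol
    ic50: float | None = None  # nM
    pic50: float | None = None  # -log10(IC50 / uM)
    activity_class: ActivityClass | None = None
    role: Role = Role.UNASSIGNED

    def __post_init__(self):
        if self.ic50 is not None and self.pic50 is not None:
            if abs(self.pic50 + math.log10(self.ic50 / 1000.0)) > 1e-9:
                raise ValueError(
                    f"record {self.id}: ic50 and pic50 are inconsistent"
                )


@dataclass
class ConformerEnsemble:
    """A molecule's pruned conformer set.

    ``conformers`` holds ``(coords, rel_energy)`` pairs: coordinates in
    Angstrom over all atoms (explicit hydrogens) and relative energy in
    kJ/mol above the ensemble minimum.  ``mol`` retains the hydrogenated
    RDKit molecule whose atom order matches the coordinate rows.
    """

    molecule_id: str
    conformers: list[tuple[np.ndarray, float]]
    mol: Chem.Mol = None
    pic50: float | None = None


def to_pic50(ic50: float) -> float:
    """Convert IC50 in nM to pIC50 on the micromolar scale."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return -math.log10(ic50 / 1000.0)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: pIC50 (uM scale) back to IC50 in nM."""
    return 1000.0 * 10.0 ** (-pic50)


def classify_activity(ic50: float) -> ActivityClass:
    """Potency class from IC50 in nM.

    Boundaries are inclusive on the stated thresholds: 10 nM is active and
    5 uM (5000 nM) is already inactive; above 50 uM the compound falls
    outside the modelled activity domain.
    """
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    if ic50 <= 10.0:
        return ActivityClass.ACTIVE
    if ic50 < 5000.0:
        return ActivityClass.MODERATE
    if ic50 <= 50000.0:
        return ActivityClass.INACTIVE
    return ActivityClass.OUT_OF_DOMAIN


# ---------------------------------------------------------------------------
# ingest


def _read_structures(path: Path) -> list[tuple[str, Chem.Mol]]:
    path = Path(path)
    out: list[tuple[str, Chem.Mol]] = []
    if path.suffix.lower() in (".sdf", ".sd"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"{path}: unparsable SDF record {i + 1}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            out.append((name.strip() or f"mol{i + 1}", mol))
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                name = parts[1].strip() if len(parts) > 1 else f"mol{ln}"
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    raise ValueError(f"{path}: unparsable structure at line {ln}")
                out.append((name, mol))
    return out


def _read_activities(path: Path) -> dict[str, dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        has_ic50 = "ic50_nM" in cols
        has_pic50 = "pic50" in cols
        if "id" not in cols or has_ic50 == has_pic50:
            raise ValueError(
                f"{path}: activity CSV must have columns 'id' and exactly one "
                "of 'ic50_nM' / 'pic50'"
            )
        table: dict[str, dict] = {}
        for row in reader:
            rid = row["id"].strip()
            if rid in table:
                raise ValueError(f"{path}: duplicate id '{rid}' in activity table")
            if has_ic50:
                ic50 = float(row["ic50_nM"])
                if ic50 <= 0:
                    raise ValueError(
                        f"{path}: non-positive IC50 for id '{rid}': {ic50}"
                    )
                table[rid] = {"ic50": ic50, "pic50": to_pic50(ic50)}
            else:
                table[rid] = {"ic50": None, "pic50": float(row["pic50"])}
    return table


def read_dataset(structures_path, activity_path=None) -> list[MoleculeRecord]:
    """Read structures (SMILES or SDF) and an optional activity CSV.

    Order-preserving: one record per structure in file order.  Structures
    without an activity row keep empty activity fields and
    ``role=unassigned``.
    """
    structures = _read_structures(Path(structures_path))
    seen: set[str] = set()
    for rid, _ in structures:
        if rid in seen:
            raise ValueError(f"duplicate id '{rid}' in structure file")
        seen.add(rid)
    activities = _read_activities(Path(activity_path)) if activity_path else {}
    records = []
    for rid, mol in structures:
        act = activities.get(rid)
        if act is None:
            records.append(MoleculeRecord(id=rid, mol=mol))
        else:
            ic50 = act["ic50"]
            records.append(
                MoleculeRecord(
                    id=rid,
                    mol=mol,
                    ic50=ic50,
                    pic50=act["pic50"],
                    activity_class=classify_activity(ic50) if ic50 else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# ionization

# Rule-based protonation at pH 7.4: groups whose aqueous pKa is far from
# physiological pH on the acidic side lose a proton, strong bases gain one.
# Anilines, amides and azine nitrogens are left neutral.
_ACID_SMARTS = (
    "[CX3](=O)[OX2H1]",          # carboxylic acid -> carboxylate
    "[SX4](=O)(=O)[OX2H1]",      # sulfonic acid -> sulfonate
)
_BASE_SMARTS = (
    # aliphatic amine: sp3 N, not amide/aniline/adjacent-to-unsaturation
    "[NX3;H2,H1,H0;+0;!$(N-a);!$(N-[#6]=[O,S,N]);!$(N-[S,P]=O);!$(N=*);!$(N#*)]",
    # amidine / guanidine imine nitrogen
    "[NX2;+0]=[CX3]([NX3;+0])",
)


def ionize(record: MoleculeRecord, pH: float = 7.4) -> MoleculeRecord:
    """Assign the most probable ionization state at physiological pH.

    Total rule table (never fails): carboxylic and sulfonic acids are
    deprotonated; aliphatic amines, amidines and guanidines are protonated;
    anilines, amides and pyridine-type nitrogens stay neutral.  The ``pH``
    argument documents the contract; the rules encode the 7.4 +/- 0.2 regime
    and do not interpolate.
    """
    mol = Chem.RWMol(record.mol)
    for smarts in _ACID_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            o = mol.GetAtomWithIdx(match[-1])
            if o.GetFormalCharge() == 0 and o.GetTotalNumHs() >= 1:
                o.SetFormalCharge(-1)
                o.SetNumExplicitHs(0)
                o.SetNoImplicit(True)
    for smarts in _BASE_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            n = mol.GetAtomWithIdx(match[0])
            if n.GetFormalCharge() == 0:
                n.SetFormalCharge(1)
                n.SetNumExplicitHs(n.GetTotalNumHs() + 1)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return replace(record, mol=out)


def net_charge(mol: Chem.Mol) -> int:
    return sum(a.GetFormalCharge() for a in mol.GetAtoms())


# ---------------------------------------------------------------------------
# conformers


def _heavy_copy(mol: Chem.Mol) -> Chem.Mol:
    return Chem.RemoveHs(Chem.Mol(mol))


def _prune(
    mol: Chem.Mol, energies: list[float], window: float, rmsd_cut: float
) -> list[int]:
    """Greedy energy-ordered pruning honoring window and redundancy cutoff.

    Keeps the lowest-energy conformer, then each next conformer only if it is
    within ``window`` kJ/mol of the minimum and at best-fit heavy-atom RMSD
    >= ``rmsd_cut`` from every conformer already kept.
    """
    order = sorted(range(len(energies)), key=lambda i: (energies[i], i))
    e_min = energies[order[0]]
    heavy = _heavy_copy(mol)
    kept: list[int] = []
    for i in order:
        if energies[i] - e_min > window + 1e-9:
            continue
        redundant = False
        for j in kept:
            rms = rdMolAlign.GetBestRMS(heavy, heavy, prbId=i, refId=j)
            if rms < rmsd_cut:
                redundant = True
                break
        if not redundant:
            kept.append(i)
    return kept


def generate_conformers(
    record: MoleculeRecord,
    max_confs: int = 100,
    window: float = 21.0,
    rmsd_cut: float = 0.5,
    seed: int = 0,
    max_iters: int = 2000,
    grad_tol: float = 0.001,
) -> ConformerEnsemble:
    """Stochastic conformer search with energy-window / RMSD pruning.

    ETKDG distance-geometry embedding provides ``max_confs`` starting points;
    each is locally minimized with MMFF94 (capped at ``max_iters`` iterations,
    ``grad_tol`` force tolerance).  Conformers above ``window`` kJ/mol over
    the minimum or within ``rmsd_cut`` Angstrom (best-fit heavy-atom RMSD) of
    an already-kept conformer are discarded.  Deterministic for a fixed seed.
    """
    mol = Chem.AddHs(Chem.Mol(record.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.numThreads = 1
    params.pruneRmsThresh = -1.0
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=max_confs, params=params)
    if len(conf_ids) == 0:
        raise ValueError(f"3D embedding failed for molecule '{record.id}'")
    props = AllChem.MMFFGetMoleculeProperties(mol)
    energies = []
    if props is not None:
        for cid in conf_ids:
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
            ff.Minimize(maxIts=max_iters, forceTol=grad_tol)
            energies.append(ff.CalcEnergy() * KCAL_TO_KJ)
    else:  # exotic atoms unsupported by MMFF: fall back to UFF
        for cid in conf_ids:
            ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
            ff.Minimize(maxIts=max_iters, forceTol=grad_tol)
            energies.append(ff.CalcEnergy() * KCAL_TO_KJ)
    kept = _prune(mol, energies, window, rmsd_cut)
    e_min = min(energies[i] for i in kept)
    conformers = []
    for i in kept:
        coords = np.array(mol.GetConformer(conf_ids[i]).GetPositions(), dtype=float)
        conformers.append((coords, energies[i] - e_min))
    conformers.sort(key=lambda ce: ce[1])
    return ConformerEnsemble(
        molecule_id=record.id, conformers=conformers, mol=mol, pic50=record.pic50
    )


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    records: list[MoleculeRecord],
    train_frac: float = 0.7,
    n_bins: int = 5,
    seed: int = 0,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Stratified random train/test split over pIC50 quantile bins.

    Records are binned by pIC50 quantiles, each bin is split at
    ``train_frac`` and the per-bin train counts are rounded by the largest
    remainder so that the overall train size equals
    ``round(n * train_frac)``.  Deterministic per seed.
    """
    if any(r.pic50 is None for r in records):
        raise ValueError("split_dataset requires pic50 on every record")
    n = len(records)
    if n < n_bins:
        warnings.warn(
            f"only {n} records for {n_bins} bins; falling back to a single bin"
        )
        n_bins = 1
    y = np.array([r.pic50 for r in records], dtype=float)
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1]) if n_bins > 1 else []
    bin_idx = np.digitize(y, edges) if n_bins > 1 else np.zeros(n, dtype=int)

    bins: dict[int, list[int]] = {}
    for i, b in enumerate(bin_idx):
        bins.setdefault(int(b), []).append(i)
    total_train = int(round(n * train_frac))

    quotas = {b: len(idx) * train_frac for b, idx in bins.items()}
    base = {b: int(math.floor(q)) for b, q in quotas.items()}
    short = total_train - sum(base.values())
    order = sorted(bins, key=lambda b: (-(quotas[b] - base[b]), b))
    for b in order[: max(short, 0)]:
        base[b] += 1

    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for b in sorted(bins):
        idx = np.array(bins[b])
        rng.shuffle(idx)
        train_ids.extend(idx[: base[b]].tolist())
        test_ids.extend(idx[base[b]:].tolist())
    train = [replace(records[i], role=Role.TRAIN) for i in sorted(train_ids)]
    test = [replace(records[i], role=Role.TEST) for i in sorted(test_ids)]
    return train, test
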