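import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign, rdMolTransforms

from pharmqsar import (
    ActivityClass,
    MoleculeRecord,
    classify_activity,
    from_pic50,
    generate_conformers,
    ionize,
    read_dataset,
    split_dataset,
    to_pic50,
)
from pharmqsar.molprep import KCAL_TO_KJ, net_charge


# ---------------------------------------------------------------------------
# activity transforms


@pytest.mark.parametrize(
    "ic50,expected",
    [(1000.0, 0.0), (6.0, 2.2218), (10.0, 2.0)],
)
def test_pic50_reference_points(ic50, expected):
    assert to_pic50(ic50) == pytest.approx(expected, abs=5e-5)


@given(st.floats(min_value=1e-3, max_value=1e8))
@settings(max_examples=300, deadline=None)
def test_pic50_roundtrip(ic50):
    assert from_pic50(to_pic50(ic50)) == pytest.approx(ic50, rel=1e-9)


@pytest.mark.parametrize("bad", [0.0, -1.0, -50.0])
def test_pic50_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        to_pic50(bad)


@pytest.mark.parametrize(
    "ic50,cls",
    [
        (6.0, ActivityClass.ACTIVE),
        (10.0, ActivityClass.ACTIVE),  # boundary inclusive
        (10.0001, ActivityClass.MODERATE),
        (4999.9, ActivityClass.MODERATE),
        (5000.0, ActivityClass.INACTIVE),
        (50000.0, ActivityClass.INACTIVE),
        (50001.0, ActivityClass.OUT_OF_DOMAIN),
    ],
)
def test_activity_classification(ic50, cls):
    assert classify_activity(ic50) == cls


def test_classification_monotone_in_potency(rng):
    """The class can only step towards less potent as IC50 grows."""
    order = {
        ActivityClass.ACTIVE: 0,
        ActivityClass.MODERATE: 1,
        ActivityClass.INACTIVE: 2,
        ActivityClass.OUT_OF_DOMAIN: 3,
    }
    values = np.sort(rng.uniform(0.1, 60000.0, size=500))
    ranks = [order[classify_activity(v)] for v in values]
    assert all(a <= b for a, b in zip(ranks, ranks[1:]))
    with pytest.raises(ValueError):
        classify_activity(0.0)


# ---------------------------------------------------------------------------
# ingest


def _write_dataset(tmp_path, smiles_rows, csv_text):
    smi = tmp_path / "in.smi"
    smi.write_text("".join(f"{s}\t{i}\n" for s, i in smiles_rows))
    csvf = tmp_path / "act.csv"
    csvf.write_text(csv_text)
    return smi, csvf


def test_read_dataset_assigns_classes(tmp_path):
    smi, csvf = _write_dataset(
        tmp_path, [("c1ccccc1", "17")], "id,ic50_nM\n17,6.0\n"
    )
    (rec,) = read_dataset(smi, csvf)
    assert rec.id == "17"
    assert rec.activity_class == ActivityClass.ACTIVE
    assert rec.pic50 == pytest.approx(to_pic50(6.0))


def test_read_dataset_without_activity(tmp_path):
    smi = tmp_path / "in.smi"
    smi.write_text("CCO\tx1\n")
    (rec,) = read_dataset(smi)
    assert rec.ic50 is None and rec.pic50 is None
    assert rec.role.value == "unassigned"


def test_read_dataset_errors(tmp_path):
    smi, csvf = _write_dataset(
        tmp_path, [("CCO", "a")], "id,ic50_nM\na,-1\n"
    )
    with pytest.raises(ValueError, match="non-positive"):
        read_dataset(smi, csvf)

    smi2 = tmp_path / "dup.smi"
    smi2.write_text("CCO\ta\nCCC\ta\n")
    with pytest.raises(ValueError, match="duplicate id 'a'"):
        read_dataset(smi2)

    smi3 = tmp_path / "bad.smi"
    smi3.write_text("CCO\ta\nnot_a_smiles(((\tb\n")
    with pytest.raises(ValueError, match="line 2"):
        read_dataset(smi3)


# ---------------------------------------------------------------------------
# ionization rules


def test_ionize_deprotonates_benzoic_acid():
    rec = ionize(MoleculeRecord(id="ba", mol=Chem.MolFromSmiles("OC(=O)c1ccccc1")))
    assert net_charge(rec.mol) == -1


def test_ionize_leaves_aniline_and_amide():
    rec = ionize(
        MoleculeRecord(id="sc", mol=Chem.MolFromSmiles("Nc1ccccc1NC(=O)c1ccccc1"))
    )
    assert net_charge(rec.mol) == 0
    assert Chem.MolToSmiles(rec.mol) == Chem.MolToSmiles(
        Chem.MolFromSmiles("Nc1ccccc1NC(=O)c1ccccc1")
    )


def test_ionize_protonates_benzylic_amine():
    rec = ionize(
        MoleculeRecord(id="am", mol=Chem.MolFromSmiles("NCc1ccc(C(N)=O)cc1"))
    )
    assert net_charge(rec.mol) == 1
    charged = [a for a in rec.mol.GetAtoms() if a.GetFormalCharge() == 1]
    assert len(charged) == 1
    # the protonated atom is the benzylic amine, not the amide nitrogen
    nbr_symbols = sorted(n.GetSymbol() for n in charged[0].GetNeighbors())
    assert nbr_symbols == ["C"]


# ---------------------------------------------------------------------------
# conformers


def test_benzene_is_rigid():
    ens = generate_conformers(
        MoleculeRecord(id="bz", mol=Chem.MolFromSmiles("c1ccccc1")),
        max_confs=20,
        seed=1,
    )
    assert len(ens.conformers) == 1
    assert ens.conformers[0][1] == 0.0


def test_butane_ensemble_invariants():
    ens = generate_conformers(
        MoleculeRecord(id="bu", mol=Chem.MolFromSmiles("CCCC")), max_confs=30, seed=3
    )
    energies = [e for _, e in ens.conformers]
    assert min(energies) == 0.0
    assert all(0 <= e <= 21.0 for e in energies)
    heavy = Chem.RemoveHs(Chem.Mol(ens.mol))
    n = len(ens.conformers)
    for i in range(n):
        for j in range(i + 1, n):
            assert rdMolAlign.GetBestRMS(heavy, heavy, prbId=i, refId=j) >= 0.5


def test_conformer_determinism():
    rec = MoleculeRecord(id="x", mol=Chem.MolFromSmiles("CCOC(=O)c1ccccc1"))
    a = generate_conformers(rec, max_confs=15, seed=9)
    b = generate_conformers(rec, max_confs=15, seed=9)
    assert len(a.conformers) == len(b.conformers)
    for (ca, ea), (cb, eb) in zip(a.conformers, b.conformers):
        assert ea == pytest.approx(eb, abs=1e-9)
        assert np.allclose(ca, cb)


def _torsion_scan_count(smiles, window=21.0, rmsd_cut=0.5):
    """Independent oracle: exhaustive 120-degree torsion grid over the carbon
    backbone, each point locally minimized, then pruned by the same
    energy-window / best-fit-RMSD rule (re-implemented here)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    props = AllChem.MMFFGetMoleculeProperties(mol)
    ff = AllChem.MMFFGetMoleculeForceField(mol, props)
    ff.Minimize(maxIts=2000, forceTol=0.001)
    chain = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
    torsions = [tuple(chain[i : i + 4]) for i in range(len(chain) - 3)]

    import itertools

    geoms, energies = [], []
    for angles in itertools.product((60.0, 180.0, 300.0), repeat=len(torsions)):
        work = Chem.Mol(mol)
        conf = work.GetConformer()
        for tor, ang in zip(torsions, angles):
            rdMolTransforms.SetDihedralDeg(conf, *tor, ang)
        p = AllChem.MMFFGetMoleculeProperties(work)
        f = AllChem.MMFFGetMoleculeForceField(work, p)
        f.Minimize(maxIts=2000, forceTol=0.001)
        geoms.append(work)
        energies.append(f.CalcEnergy() * KCAL_TO_KJ)

    order = np.argsort(energies, kind="stable")
    e_min = energies[order[0]]
    combined = Chem.Mol(mol)
    combined.RemoveAllConformers()
    for g in geoms:
        c = Chem.Conformer(g.GetConformer())
        combined.AddConformer(c, assignId=True)
    heavy = Chem.RemoveHs(combined)
    kept = []
    for i in order:
        if energies[i] - e_min > window:
            continue
        if all(
            rdMolAlign.GetBestRMS(heavy, heavy, prbId=int(i), refId=int(j)) >= rmsd_cut
            for j in kept
        ):
            kept.append(int(i))
    return len(kept)


def test_hexane_matches_torsion_grid_oracle():
    """Stochastic search finds exactly the staggered-rotamer minima an
    exhaustive 120-degree torsion scan finds after identical pruning."""
    expected = _torsion_scan_count("CCCCCC")
    ens = generate_conformers(
        MoleculeRecord(id="hex", mol=Chem.MolFromSmiles("CCCCCC")),
        max_confs=120,
        seed=4,
    )
    assert len(ens.conformers) == expected


def test_ensemble_invariant_under_canonicalized_reordering():
    """Two input orderings of the same molecule, canonicalized, give the same
    pruned ensemble (sizes and energy spectrum)."""
    def canonical(smiles):
        return Chem.MolFromSmiles(Chem.MolToSmiles(Chem.MolFromSmiles(smiles)))

    a = generate_conformers(
        MoleculeRecord(id="a", mol=canonical("CC(=O)Nc1ccccc1")), max_confs=20, seed=11
    )
    b = generate_conformers(
        MoleculeRecord(id="b", mol=canonical("c1ccccc1NC(C)=O")), max_confs=20, seed=11
    )
    assert len(a.conformers) == len(b.conformers)
    for (_, ea), (_, eb) in zip(a.conformers, b.conformers):
        assert ea == pytest.approx(eb, abs=1e-6)


# ---------------------------------------------------------------------------
# splitting


def _records_with_pic50(values):
    mol = Chem.MolFromSmiles("C")
    return [
        MoleculeRecord(id=f"r{i}", mol=mol, pic50=float(v))
        for i, v in enumerate(values)
    ]


def test_split_370_gives_259_111(rng):
    records = _records_with_pic50(rng.normal(0, 1.5, size=370))
    train, test = split_dataset(records, train_frac=0.7, n_bins=5, seed=1)
    assert (len(train), len(test)) == (259, 111)
    assert {r.id for r in train} | {r.id for r in test} == {r.id for r in records}
    assert not ({r.id for r in train} & {r.id for r in test})


def test_split_identical_activities_rounds_7_3():
    records = _records_with_pic50([1.0] * 10)
    train, test = split_dataset(records, train_frac=0.7, n_bins=5, seed=0)
    assert (len(train), len(test)) == (7, 3)


def test_split_deterministic_and_stratified(rng):
    records = _records_with_pic50(rng.normal(0, 1.5, size=123))
    t1, s1 = split_dataset(records, seed=5)
    t2, s2 = split_dataset(records, seed=5)
    assert [r.id for r in t1] == [r.id for r in t2]
    assert [r.id for r in s1] == [r.id for r in s2]
    # per-bin proportion deviates from train_frac by less than one count
    y = np.array([r.pic50 for r in records])
    edges = np.quantile(y, np.linspace(0, 1, 6)[1:-1])
    train_ids = {r.id for r in t1}
    for b in range(5):
        members = [r for r in records if np.digitize(r.pic50, edges) == b]
        in_train = sum(1 for r in members if r.id in train_ids)
        assert abs(in_train - 0.7 * len(members)) < 1.0


def test_split_fewer_records_than_bins_warns():
    records = _records_with_pic50([1.0, 2.0, 3.0])
    with pytest.warns(UserWarning, match="single bin"):
        train, test = split_dataset(records, n_bins=5, seed=0)
    assert len(train) + len(test) == 3
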