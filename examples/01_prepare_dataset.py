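"""Ingest a small SMILES/CSV dataset, ionize at pH 7.4 and build conformers.

Writes nothing: prints the activity bookkeeping (pIC50 on the micromolar
scale, potency classes) and the pruned conformer ensembles (count and energy
spread per molecule).
"""

import tempfile
from pathlib import Path

from pharmqsar import generate_conformers, ionize, read_dataset, split_dataset

SMILES = """\
O=C(c1ccccc1)Nc1ccccc1N\tcpd-1
O=C(c1ccc(F)cc1)Nc1ccccc1N\tcpd-2
O=C(c1ccc(OC)cc1)Nc1ccccc1N\tcpd-3
OC(=O)c1ccccc1\tcpd-4
"""
ACTIVITIES = """\
id,ic50_nM
cpd-1,9.0
cpd-2,6.5
cpd-3,120.0
cpd-4,30000.0
"""

with tempfile.TemporaryDirectory() as tmp:
    smi = Path(tmp) / "in.smi"
    smi.write_text(SMILES)
    csv = Path(tmp) / "act.csv"
    csv.write_text(ACTIVITIES)
    records = [ionize(r) for r in read_dataset(smi, csv)]

print("id      IC50/nM   pIC50   class")
for r in records:
    print(f"{r.id:<7} {r.ic50:>8.1f} {r.pic50:>7.3f}   {r.activity_class.value}")

train, test = split_dataset(records, train_frac=0.7, n_bins=2, seed=1)
print(f"\nstratified 70/30 split: {len(train)} train / {len(test)} test")

print("\nconformer ensembles (21 kJ/mol window, 0.5 A redundancy cutoff):")
for r in records:
    ens = generate_conformers(r, max_confs=20, seed=7)
    energies = [e for _, e in ens.conformers]
    print(
        f"{r.id}: {len(ens.conformers)} conformers, "
        f"rel. energies 0 .. {max(energies):.1f} kJ/mol"
    )
# Each line shows how many distinct low-energy shapes survive pruning;
# the benzamides keep a handful of amide/ring rotamers.
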