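# pharmqsar

Pharmacophore-aligned, atom-based 3D-QSAR modelling and virtual-screening
validation for congeneric inhibitor series — built around the benzamide
(2-aminophenylamide) class of HDAC1 inhibitors.

Medicinal chemists working on a congeneric series often need a fast,
ligand-based filter: given a few hundred compounds with measured IC50s, build
a model that predicts the potency of new analogues and ranks large libraries
so that true binders surface at the top.  `pharmqsar` implements that
workflow end to end:

1. **Preparation** — ingest SMILES/SDF + activity CSV, assign ionization
   states at pH 7.4 by rule, generate pruned conformer ensembles (ETKDG +
   MMFF94; 21 kJ/mol energy window, 0.5 Å redundancy cutoff).
2. **Pharmacophore elucidation** — perceive A/D/H/N/P/R features, enumerate
   common 5-point hypotheses across the most potent ligands, and rank them by
   the *adjusted survival score* (survival − inactive score), so the winning
   hypothesis is one the actives satisfy and the inactives do not.
3. **Alignment** — kind-respecting feature assignment + Kabsch least-squares
   superposition; the selected hypothesis is the alignment rule.
4. **QSAR** — binary occupancy of 0.5 Å grid cubes by classified heavy atoms,
   regressed against pIC50 (µM scale) by PLS with 1–7 latent factors:

   R², SD, F/P per factor count; leave-n-out Q² = 1 − PRESS/SS_tot; and

       Q²_F3 = 1 − [Σ(yᵢ − ŷᵢ)²/n_OUT] / [Σ(yᵢ − ȳ_TR)²/n_TR]

5. **Screening validation** — rank actives + property-matched decoys and
   report EF = (Ha/Ht)/(A/D), the Güner–Henry score
   GH = [Ha(3A+Ht)/(4·Ht·A)]·[1 − (Ht−Ha)/(D−A)], %YA, %RA and the ROC/AUC.

A seed-controlled synthetic-library generator (`pharmqsar.synthlib`) plants a
known ADDRR pharmacophore and activity model in benzamide-like scaffolds and
builds property-matched decoys, so every stage is testable without external
data.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from pharmqsar.pipeline import run_synthetic_study

res = run_synthetic_study(seed=1)   # 300 compounds + ~1000 decoys
r = res.report
print(f"hypothesis: {res.hypothesis.variant_label}  "
      f"(planted motif recovered: {res.recovered_planted})")
print(f"model: {res.model.n_factors} factors  "
      f"R2={res.model.stats['r2']:.3f}  Q2={res.q2:.3f}  r2_ext={res.r2_ext:.3f}")
print(f"screen: Ha={r.Ha}/Ht={r.Ht} of A={r.A} in D={r.D}  "
      f"EF={r.ef:.1f}  GH={r.gh:.2f}  AUC={r.auc:.2f}")
```

prints

```
hypothesis: ADDRR  (planted motif recovered: True)
model: 5 factors  R2=0.954  Q2=0.924  r2_ext=0.935
screen: Ha=20/Ht=30 of A=20 in D=1020  EF=34.0  GH=0.74  AUC=1.00
```

The selected hypothesis is the planted one-acceptor/two-donor/two-ring
arrangement; the 5-factor PLS model explains 95% of training variance and
generalizes (cross-validated Q² and held-out r² above 0.9 under the
generator's 0.3-pIC50-unit noise); on the decoy screen all 20 known actives
rank inside the top 30 of ~1000 molecules, giving a Güner–Henry score of
0.74 (above the 0.5 reliability rule of thumb) and essentially perfect
active/decoy separation.

The `examples/` directory holds one short narrative script per capability
(preparation, pharmacophore elucidation, QSAR training, screening
validation).  A thin CLI mirrors the stages:

```bash
pharmqsar fixtures --preset small --seed 1 --out scratch/lib
pharmqsar prep --structures scratch/lib/library.smi \
               --activities scratch/lib/activities.csv --seed 1 --out scratch/prep
pharmqsar hypo --actives actives.smi --inactives inactives.smi --out hypo.json
pharmqsar train --train train.smi --activities act.csv --hypo hypo.json \
                --seed 1 --out model.json
pharmqsar predict --model model.json --in query.smi --out pred.csv
pharmqsar validate --model model.json --library lib.smi --actives ids.txt \
                   --hits 30 --out report/
```

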