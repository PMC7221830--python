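"""End-to-end orchestration: library -> pharmacophore -> QSAR -> validation.

Wires the individual stages together the way a screening campaign would run
them; used by the command-line interface, the examples and the validation
study on synthetic libraries.  All randomness flows from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .molprep import MoleculeRecord, generate_conformers, split_dataset
from .pharmacophore import (
    Hypothesis,
    ensemble_features,
    enumerate_hypotheses,
    score_hypothesis,
    select_best,
)
from .qsar import (
    QSARModel,
    cross_validate,
    fit_pls,
    prepare_training_data,
    select_model,
)
from .screening import EnrichmentReport, evaluate_screen, external_validation
from .synthlib import SyntheticLibrarySpec, generate_decoys, generate_library

__all__ = ["PipelineResult", "prepare_ensembles", "run_synthetic_study", "hypothesis_matches_planted"]


def prepare_ensembles(records: list[MoleculeRecord], max_confs: int, seed: int):
    """Conformer ensembles + perceived features for a list of records.

    Per-molecule embedding seeds are derived from ``seed`` and the record
    index so ensembles are independent yet reproducible.
    """
    ensembles, features = [], []
    for i, rec in enumerate(records):
        ens = generate_conformers(
            rec, max_confs=max_confs, seed=(seed * 9973 + i) & 0x7FFFFFFF
        )
        ensembles.append(ens)
        features.append(ensemble_features(ens))
    return ensembles, features


def hypothesis_matches_planted(
    hypothesis: Hypothesis, planted: dict, bin_width: float = 1.0
) -> bool:
    """Does a hypothesis recover the planted motif (kinds + distances)?"""
    if hypothesis.variant_label != planted["kinds"]:
        return False
    d_hyp = hypothesis.sorted_distances
    d_ref = np.asarray(planted["sorted_distances"])
    return bool(np.all(np.abs(d_hyp - d_ref) <= bin_width))


@dataclass
class PipelineResult:
    library: object
    hypothesis: Hypothesis
    n_candidates: int
    models: list[QSARModel]
    model: QSARModel
    q2: float
    r2_ext: float
    report: EnrichmentReport
    recovered_planted: bool
    X_train: np.ndarray = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)


def run_synthetic_study(
    seed: int,
    spec: SyntheticLibrarySpec | None = None,
    n_pharm_actives: int = 20,
    n_pharm_inactives: int = 20,
    max_confs_library: int = 10,
    max_confs_decoys: int = 2,
    spacing: float = 0.5,
    max_factors: int = 7,
    align_tol: float = 2.0,
    hit_count: int = 30,
    experimental_error: float | None = None,
) -> PipelineResult:
    """Full study on one synthetic library.

    Generates the library, elucidates the common-feature pharmacophore from
    the most potent compounds (scored against the least potent), trains
    occupancy-grid PLS models with 1..``max_factors`` factors on a stratified
    70/30 split, selects a model, and validates by cross-validated Q^2, test
    set r^2 and a property-matched decoy screen (EF, GH, %YA, %RA, ROC/AUC).
    """
    spec = spec or SyntheticLibrarySpec(seed=seed)
    lib = generate_library(spec)
    ensembles, features = prepare_ensembles(lib.records, max_confs_library, seed)
    for ens, rec in zip(ensembles, lib.records):
        ens.pic50 = rec.pic50

    order = np.argsort([-r.pic50 for r in lib.records], kind="stable")
    act_idx = order[:n_pharm_actives].tolist()
    inact_idx = order[::-1][:n_pharm_inactives].tolist()
    act_ens = [ensembles[i] for i in act_idx]
    act_feats = [features[i] for i in act_idx]
    inact_ens = [ensembles[i] for i in inact_idx]
    inact_feats = [features[i] for i in inact_idx]

    candidates = enumerate_hypotheses(
        act_ens, k=5, bin_width=1.0, tolerance=align_tol,
        features_per_active=act_feats,
    )
    if not candidates:
        raise RuntimeError("no common pharmacophore found among the actives")
    scored = [
        score_hypothesis(
            c, act_ens, inact_ens,
            features_actives=act_feats, features_inactives=inact_feats,
        )
        for c in candidates
    ]
    best = select_best(scored)
    recovered = hypothesis_matches_planted(best, lib.ground_truth["planted"])

    train, test = split_dataset(lib.records, train_frac=0.7, n_bins=5, seed=seed)
    by_id = {r.id: i for i, r in enumerate(lib.records)}
    train_ens = [ensembles[by_id[r.id]] for r in train]
    train_feats = [features[by_id[r.id]] for r in train]
    test_ens = [ensembles[by_id[r.id]] for r in test]
    test_feats = [features[by_id[r.id]] for r in test]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-matching molecules are expected
        X, y, ids, grid, active_cubes, _ = prepare_training_data(
            best, train_ens, spacing=spacing, tol=align_tol, features=train_feats
        )
    models = []
    for nf in range(1, max_factors + 1):
        fit = fit_pls(X, y, nf)
        models.append(
            QSARModel(
                hypothesis=best, grid=grid, active_cubes=active_cubes,
                n_factors=nf, coefficients=fit["coef"], intercept=fit["intercept"],
                y_mean_train=fit["y_mean"], floor=float(y.min()),
                training_ids=list(ids),
                fitted_values={i: float(v) for i, v in zip(ids, fit["fitted"])},
                stats={k: fit[k] for k in ("r2", "sd", "f", "p")},
                align_tol=align_tol,
            )
        )
    err = experimental_error if experimental_error is not None else spec.noise_sigma
    chosen = select_model(models, err)
    q2 = cross_validate(X, y, chosen.n_factors, n_folds=10, seed=seed)
    chosen.stats["q2"] = q2

    r2_ext, _ = external_validation(chosen, test_ens, features=test_feats)

    screen_actives = [lib.records[i] for i in act_idx]
    decoys = generate_decoys(screen_actives, spec.n_decoys_per_active, seed=seed)
    decoy_ens, decoy_feats = prepare_ensembles(decoys, max_confs_decoys, seed + 1)
    screen_lib = act_ens + decoy_ens
    screen_feats = act_feats + decoy_feats
    report = evaluate_screen(
        chosen, screen_lib,
        active_ids=[e.molecule_id for e in act_ens],
        hit_count=hit_count, features=screen_feats,
    )
    return PipelineResult(
        library=lib, hypothesis=best, n_candidates=len(candidates),
        models=models, model=chosen, q2=q2, r2_ext=r2_ext, report=report,
        recovered_planted=recovered, X_train=X, y_train=y,
    )
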