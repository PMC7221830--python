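"""Virtual-screening validation: enrichment metrics and ROC analysis.

Given a fitted QSAR model and a library of actives plus presumed-inactive
decoys, the library is ranked by predicted pIC50 and the classical
retrieval metrics are computed over the top of the ranking:

    EF   = (Ha / Ht) / (A / D)                       enrichment factor
    GH   = [Ha (3A + Ht) / (4 Ht A)] [1 - (Ht - Ha)/(D - A)]   Guner-Henry
    %YA  = 100 Ha / Ht                               yield of actives
    %RA  = 100 Ha / A                                ratio of actives

with Ht the hit-list size, Ha the actives among the hits, A the total
actives and D the library size.  The ROC curve sweeps all score thresholds;
tied scores contribute diagonal segments so the trapezoid AUC equals the
normalized Mann-Whitney rank-sum statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .qsar import QSARModel, predict

__all__ = [
    "EnrichmentReport",
    "screen",
    "enrichment_factor",
    "gh_score",
    "yield_and_ratio",
    "roc_curve",
    "external_validation",
    "evaluate_screen",
]


@dataclass
class EnrichmentReport:
    Ha: int
    Ht: int
    A: int
    D: int
    ef: float
    gh: float
    pct_ya: float
    pct_ra: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "Ha": self.Ha,
            "Ht": self.Ht,
            "A": self.A,
            "D": self.D,
            "EF": self.ef,
            "GH": self.gh,
            "pct_YA": self.pct_ya,
            "pct_RA": self.pct_ra,
            "AUC": self.auc,
            "roc_points": self.roc_points,
        }


def _check_counts(Ha, Ht, A, D, need_d_gt_a=False):
    Ha, Ht, A, D = (np.asarray(v) for v in (Ha, Ht, A, D))
    if np.any(Ht < 1) or np.any(A < 1):
        raise ValueError("Ht and A must be >= 1")
    if np.any(D < A):
        raise ValueError("library size D must be >= number of actives A")
    if need_d_gt_a and np.any(D <= A):
        raise ValueError("Guner-Henry score requires D > A")
    if np.any(Ha < 0) or np.any(Ha > np.minimum(Ht, A)):
        raise ValueError("Ha must satisfy 0 <= Ha <= min(Ht, A)")
    if np.any(Ht > D):
        raise ValueError("hit list cannot exceed the library size")
    if np.any(Ht - Ha > D - A):
        raise ValueError(
            "hit list cannot contain more inactives (Ht - Ha) than the "
            "library holds (D - A)"
        )


def enrichment_factor(Ha, Ht, A, D):
    """Enrichment factor EF = (Ha/Ht) / (A/D); accepts scalars or arrays."""
    _check_counts(Ha, Ht, A, D)
    return (np.asarray(Ha) / np.asarray(Ht)) / (np.asarray(A) / np.asarray(D))


def gh_score(Ha, Ht, A, D):
    """Guner-Henry goodness-of-hit score, in [0, 1]; scalars or arrays.

    GH = [Ha(3A + Ht) / (4 Ht A)] * [1 - (Ht - Ha)/(D - A)].
    """
    _check_counts(Ha, Ht, A, D, need_d_gt_a=True)
    Ha = np.asarray(Ha, dtype=float)
    Ht = np.asarray(Ht, dtype=float)
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    return (Ha * (3 * A + Ht) / (4 * Ht * A)) * (1 - (Ht - Ha) / (D - A))


def yield_and_ratio(Ha, Ht, A):
    """(%YA, %RA) = (100 Ha/Ht, 100 Ha/A)."""
    if Ht < 1 or A < 1:
        raise ValueError("Ht and A must be >= 1")
    return 100.0 * Ha / Ht, 100.0 * Ha / A


def hit_list_size(D: int, hit_fraction: float = 0.01, hit_count: int | None = None) -> int:
    """Size of the hit list: an explicit ``hit_count`` wins; otherwise the
    library fraction, rounded to nearest, never below one hit."""
    if hit_count is not None:
        if hit_count < 1:
            raise ValueError("hit_count must be >= 1")
        return min(hit_count, D)
    return max(1, min(D, int(round(D * hit_fraction))))


def screen(
    model: QSARModel,
    library: list,
    hit_fraction: float = 0.01,
    hit_count: int | None = None,
    features: list | None = None,
):
    """Rank a library by predicted pIC50 and cut a hit list.

    Unmatched molecules receive the model's floor prediction.  Ties are
    broken by molecule id so the ranking is reproducible.  The hit list is
    the top ``hit_count`` entries, or ``round(D * hit_fraction)`` (at least
    1) when no explicit count is given.

    Returns ``(ranked, hit_ids)``: ``ranked`` is a list of
    ``(id, prediction, matched)`` in rank order.
    """
    if not library:
        raise ValueError("empty screening library")
    rows = []
    for i, ens in enumerate(library):
        pred, matched = predict(
            model, ens, features=features[i] if features is not None else None
        )
        rows.append((ens.molecule_id, pred, matched))
    rows.sort(key=lambda r: (-r[1], r[0]))
    ht = hit_list_size(len(rows), hit_fraction, hit_count)
    hit_ids = {r[0] for r in rows[:ht]}
    return rows, hit_ids


def roc_curve(scores: dict[str, float], active_ids) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) and trapezoid AUC from per-molecule scores.

    Tied scores produce diagonal segments (average-rank convention), so the
    AUC equals the normalized Mann-Whitney statistic.
    """
    active_ids = set(active_ids)
    ids = sorted(scores)
    y_true = np.array([1 if i in active_ids else 0 for i in ids])
    y_score = np.array([scores[i] for i in ids], dtype=float)
    if y_true.min() == y_true.max():
        raise ValueError("ROC needs at least one active and one inactive")
    fpr, tpr, _ = _sk_roc_curve(y_true, y_score, drop_intermediate=False)
    auc = float(roc_auc_score(y_true, y_score))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_screen(
    model: QSARModel,
    library: list,
    active_ids,
    hit_fraction: float = 0.01,
    hit_count: int | None = None,
    features: list | None = None,
) -> EnrichmentReport:
    """Screen a library and assemble the full enrichment report."""
    ranked, hit_ids = screen(
        model, library, hit_fraction=hit_fraction, hit_count=hit_count, features=features
    )
    active_ids = set(active_ids)
    D = len(ranked)
    A = sum(1 for r in ranked if r[0] in active_ids)
    Ht = len(hit_ids)
    Ha = len(hit_ids & active_ids)
    ef = float(enrichment_factor(Ha, Ht, A, D))
    gh = float(gh_score(Ha, Ht, A, D)) if D > A else float("nan")
    ya, ra = yield_and_ratio(Ha, Ht, A)
    points, auc = roc_curve({r[0]: r[1] for r in ranked}, active_ids)
    return EnrichmentReport(
        Ha=Ha, Ht=Ht, A=A, D=D, ef=ef, gh=gh, pct_ya=ya, pct_ra=ra,
        roc_points=points, auc=auc,
    )


def external_validation(
    model: QSARModel, external: list, features: list | None = None
) -> tuple[float, list[tuple[str, float, float]]]:
    """Squared Pearson correlation of predicted vs experimental pIC50.

    ``external`` ensembles must carry pIC50 and must not overlap the model's
    training set.  Returns ``(r2_ext, scatter)`` with per-molecule
    ``(id, experimental, predicted)`` rows.
    """
    train_ids = set(model.training_ids)
    overlap = sorted({e.molecule_id for e in external} & train_ids)
    if overlap:
        raise ValueError(f"external set overlaps training ids: {overlap}")
    if any(e.pic50 is None for e in external):
        raise ValueError("external records must carry pic50")
    scatter = []
    for i, ens in enumerate(external):
        pred, _ = predict(
            model, ens, features=features[i] if features is not None else None
        )
        scatter.append((ens.molecule_id, float(ens.pic50), pred))
    y_exp = np.array([s[1] for s in scatter])
    y_pred = np.array([s[2] for s in scatter])
    if np.var(y_pred) == 0 or np.var(y_exp) == 0:
        raise ValueError(
            "correlation undefined: predictions or experiments are constant"
        )
    r, _ = sstats.pearsonr(y_exp, y_pred)
    return float(r**2), scatter
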