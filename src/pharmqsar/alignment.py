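"""Rigid-body superposition and pharmacophore feature matching.

The alignment rule of the whole toolkit: ligand conformers are mapped onto a
pharmacophore hypothesis by enumerating kind-respecting assignments between
hypothesis features and perceived ligand features, and solving the
least-squares rigid superposition (Kabsch) for each assignment.  The lowest
RMSD assignment within tolerance wins.  Conformers are treated as rigid
bodies; feature direction vectors do not enter the positional least squares
(they are used only in hypothesis scoring).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["AlignedPose", "superpose", "match_and_align"]


@dataclass
class AlignedPose:
    """A conformer rigidly superposed onto a hypothesis.

    ``rotation`` / ``translation`` map ligand coordinates into the hypothesis
    reference frame: ``x_hyp = rotation @ x_lig + translation``.
    ``mapping`` pairs hypothesis feature indices with ligand feature indices.
    """

    molecule_id: str
    conformer_index: int
    rotation: np.ndarray
    translation: np.ndarray
    mapping: tuple[tuple[int, int], ...]
    rmsd: float
    matched_count: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the stored rigid transform to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation + translation mapping ``mov`` onto ``ref``."""
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    p = mov - mov_c
    q = ref - ref_c
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    t = ref_c - rot @ mov_c
    diff = (mov @ rot.T + t) - ref
    rmsd = float(np.sqrt((diff**2).sum() / len(ref)))
    return rot, t, rmsd


def superpose(
    ref_points: np.ndarray, mov_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally optimal least-squares rigid superposition of two point sets.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (``det = +1``) such that ``rotation @ mov + translation ~= ref``.

    Raises
    ------
    ValueError
        If fewer than 3 point pairs are given or either set is collinear
        (the rotation about the common axis would be undetermined).
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(mov_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(ref) < 3:
        raise ValueError("superposition requires at least 3 point pairs")
    for pts, name in ((ref, "reference"), (mov, "moving")):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError(f"{name} points are collinear; rotation is undetermined")
    return _kabsch(ref, mov)


def _batch_kabsch_rmsd(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """RMSD of the optimal rigid superposition for a batch of point sets.

    ``ref`` and ``mov`` are (m, k, 3); returns (m,) RMSDs.  Uses the fact
    that the optimal residual is ``tr(P'P + Q'Q) - 2*sum(corrected singular
    values)`` which avoids building the rotations when only RMSD is needed.
    """
    refc = ref - ref.mean(axis=1, keepdims=True)
    movc = mov - mov.mean(axis=1, keepdims=True)
    h = np.einsum("mki,mkj->mij", movc, refc)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    # For proper rotations the smallest singular value flips sign when det<0.
    corr = s.sum(axis=1) - 2.0 * s[:, -1] * (det < 0)
    sq = (refc**2).sum(axis=(1, 2)) + (movc**2).sum(axis=(1, 2)) - 2.0 * corr
    k = ref.shape[1]
    return np.sqrt(np.maximum(sq, 0.0) / k)


def _assignments(hyp_kinds, lig_kinds):
    """All kind-respecting injective maps hypothesis-feature -> ligand-feature.

    Yields tuples of ligand feature indices ordered like the hypothesis
    features.  Exhaustive; intended for <= 8 features per kind.
    """
    by_kind_h: dict[str, list[int]] = {}
    for i, kk in enumerate(hyp_kinds):
        by_kind_h.setdefault(kk, []).append(i)
    by_kind_l: dict[str, list[int]] = {}
    for i, kk in enumerate(lig_kinds):
        by_kind_l.setdefault(kk, []).append(i)
    kinds = sorted(by_kind_h)
    for kk in kinds:
        if len(by_kind_l.get(kk, [])) < len(by_kind_h[kk]):
            return  # kind deficit: no assignment exists
    pools = [
        itertools.permutations(by_kind_l[kk], len(by_kind_h[kk])) for kk in kinds
    ]
    hyp_order = [i for kk in kinds for i in by_kind_h[kk]]
    for combo in itertools.product(*pools):
        lig_idx = [j for perm in combo for j in perm]
        out = [0] * len(hyp_kinds)
        for h_i, l_i in zip(hyp_order, lig_idx):
            out[h_i] = l_i
        yield tuple(out)


def match_and_align(
    ensemble,
    features_per_conformer,
    hypothesis,
    tol: float = 2.0,
    require_all: bool = True,
) -> AlignedPose | None:
    """Find the best rigid mapping of a conformer ensemble onto a hypothesis.

    Every conformer is tried against every kind-respecting assignment of
    hypothesis features to that conformer's perceived features; in partial
    mode (``require_all=False``) each single hypothesis feature may also be
    dropped, so matches with ``k-1`` features qualify.  A pose is a match if
    its RMSD is at most ``tol``; the lowest-RMSD match is returned
    (preferring full matches over partial ones), or ``None``.
    """
    k = len(hypothesis.features)
    hyp_pos = np.array([f.position for f in hypothesis.features], dtype=float)
    hyp_kinds = [f.kind for f in hypothesis.features]

    subsets: list[tuple[int, ...]] = [tuple(range(k))]
    if not require_all and k - 1 >= 3:
        subsets += [tuple(j for j in range(k) if j != drop) for drop in range(k)]

    best: AlignedPose | None = None
    for ci, (coords, _rel_e) in enumerate(ensemble.conformers):
        feats = features_per_conformer[ci]
        if not feats:
            continue
        lig_pos = np.array([f.position for f in feats], dtype=float)
        lig_kinds = [f.kind for f in feats]
        for subset in subsets:
            sub_kinds = [hyp_kinds[j] for j in subset]
            assigns = list(_assignments(sub_kinds, lig_kinds))
            if not assigns:
                continue
            ref = hyp_pos[list(subset)]
            if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-8) < 2:
                continue
            mov = lig_pos[np.array(assigns)]  # (m, |subset|, 3)
            rmsds = _batch_kabsch_rmsd(np.broadcast_to(ref, mov.shape), mov)
            order = np.argsort(rmsds, kind="stable")
            for a_i in order:
                rmsd = float(rmsds[a_i])
                if rmsd > tol:
                    break
                matched = len(subset)
                if best is not None:
                    if (best.matched_count, -best.rmsd) >= (matched, -rmsd):
                        break
                rot, t, rmsd_exact = _kabsch(ref, mov[a_i])
                mapping = tuple(
                    (subset[p], int(assigns[a_i][p])) for p in range(matched)
                )
                best = AlignedPose(
                    molecule_id=ensemble.molecule_id,
                    conformer_index=ci,
                    rotation=rot,
                    translation=t,
                    mapping=mapping,
                    rmsd=rmsd_exact,
                    matched_count=matched,
                )
                break
    return best
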