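"""Atom-based occupancy-grid 3D-QSAR with PLS regression.

Aligned conformers are embedded in a regular cubic grid (default spacing
0.5 Angstrom).  Each heavy atom, assigned to one of six descriptor classes
(donor-H carrier, hydrophobic, negative, positive, electron-withdrawing /
acceptor, other), sets the bit of every cube whose center lies inside the
atom's van der Waals sphere.  The binary (cube, class) matrix over the
training poses is regressed against pIC50 by partial least squares with 1-7
latent factors; model quality is tracked by training R^2 / SD / F / P,
leave-n-out cross-validated Q^2 and the externally referenced Q^2_F3

    Q^2_F3 = 1 - [sum_i (y_i - yhat_i)^2 / n_OUT] / [sum_i (y_i - ybar_TR)^2 / n_TR]

which normalizes test-set error by training-set variance.  Molecules that do
not match the alignment hypothesis receive the model's floor prediction (the
minimum training pIC50), ranking them last in a screen.
"""

from __future__ import annotations

import base64
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.cross_decomposition import PLSRegression

from . import chemdata
from .alignment import match_and_align
from .pharmacophore import Hypothesis, ensemble_features

__all__ = [
    "GridSpec",
    "QSARModel",
    "occupancy_descriptor",
    "fit_pls",
    "cross_validate",
    "q2f3",
    "select_model",
    "predict",
    "export_coefficient_field",
    "prepare_training_data",
    "train_factor_scan",
]

MARGIN = 2.0  # Angstrom beyond the largest vdW radius in the tables


@dataclass
class GridSpec:
    """Regular cubic grid enclosing the aligned training poses."""

    origin: np.ndarray
    spacing: float = 0.5
    extents: tuple[int, int, int] = (0, 0, 0)
    atom_classes: tuple[str, ...] = chemdata.ATOM_CLASSES

    @classmethod
    def from_coords(cls, all_coords: np.ndarray, spacing: float = 0.5) -> "GridSpec":
        lo = all_coords.min(axis=0) - MARGIN
        hi = all_coords.max(axis=0) + MARGIN
        extents = tuple(int(math.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
        return cls(origin=np.asarray(lo, dtype=float), spacing=spacing, extents=extents)

    @property
    def n_cubes(self) -> int:
        return int(np.prod(self.extents))

    def linear_index(self, ix, iy, iz):
        nx, ny, nz = self.extents
        return (ix * ny + iy) * nz + iz

    def cube_center(self, lin: int) -> np.ndarray:
        nx, ny, nz = self.extents
        ix, rem = divmod(lin, ny * nz)
        iy, iz = divmod(rem, nz)
        return self.origin + self.spacing * np.array([ix, iy, iz], dtype=float)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "spacing": self.spacing,
            "extents": list(self.extents),
            "atom_classes": list(self.atom_classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            origin=np.array(d["origin"], dtype=float),
            spacing=d["spacing"],
            extents=tuple(d["extents"]),
            atom_classes=tuple(d["atom_classes"]),
        )


def heavy_atom_data(mol) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Indices, vdW radii and descriptor class indices of heavy atoms."""
    idx, radii, classes = [], [], []
    class_pos = {c: i for i, c in enumerate(chemdata.ATOM_CLASSES)}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1:
            continue
        idx.append(atom.GetIdx())
        radii.append(chemdata.vdw_radius(atom.GetSymbol()))
        classes.append(class_pos[chemdata.classify_atom(atom)])
    return idx, np.array(radii), np.array(classes, dtype=int)


def occupancy_descriptor(
    coords: np.ndarray,
    radii: np.ndarray,
    class_indices: np.ndarray,
    grid: GridSpec,
) -> tuple[set[tuple[int, int]], int]:
    """Occupancy bits of one pose: ``{(cube_linear_index, class_index)}``.

    A bit is set iff a cube center lies inside (<=) the vdW sphere of an atom
    of that class.  Atoms whose spheres reach outside the grid have those
    out-of-extent cubes ignored; the count of ignored cubes is returned.
    """
    bits: set[tuple[int, int]] = set()
    ignored = 0
    nx, ny, nz = grid.extents
    h = grid.spacing
    for pos, r, cls in zip(coords, radii, class_indices):
        rel = (pos - grid.origin) / h
        lo = np.floor(rel - r / h).astype(int)
        hi = np.ceil(rel + r / h).astype(int)
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, np.array([nx - 1, ny - 1, nz - 1]))
        # out-of-extent cubes the sphere would have covered
        if any(lo[d] < 0 or hi[d] > e - 1 for d, e in enumerate((nx, ny, nz))):
            full_axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
            fx, fy, fz = np.meshgrid(*full_axes, indexing="ij")
            fcenters = grid.origin + h * np.stack([fx, fy, fz], axis=-1)
            finside = ((fcenters - pos) ** 2).sum(axis=-1) <= r * r + 1e-12
            outside = (
                (fx < 0) | (fx > nx - 1) | (fy < 0) | (fy > ny - 1) | (fz < 0) | (fz > nz - 1)
            )
            ignored += int((finside & outside).sum())
        axes = [np.arange(lo_c[d], hi_c[d] + 1) for d in range(3)]
        if any(len(a) == 0 for a in axes):
            continue
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        centers = grid.origin + h * np.stack([gx, gy, gz], axis=-1)
        inside = ((centers - pos) ** 2).sum(axis=-1) <= r * r + 1e-12
        for ix, iy, iz in zip(gx[inside], gy[inside], gz[inside]):
            bits.add((grid.linear_index(int(ix), int(iy), int(iz)), int(cls)))
    return bits, ignored


@dataclass
class QSARModel:
    """Fitted occupancy-grid PLS model."""

    hypothesis: Hypothesis
    grid: GridSpec
    active_cubes: list[int]
    n_factors: int
    coefficients: np.ndarray  # (n_active_cubes * n_classes,)
    intercept: float
    y_mean_train: float
    floor: float
    training_ids: list[str] = field(default_factory=list)
    fitted_values: dict[str, float] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    align_tol: float = 2.0

    @property
    def cube_index(self) -> dict[int, int]:
        return {c: i for i, c in enumerate(self.active_cubes)}

    def descriptor_vector(self, bits: set[tuple[int, int]]) -> np.ndarray:
        """Binary vector over (active cube, class) columns; bits in cubes not
        occupied by any training pose are dropped."""
        n_cls = len(self.grid.atom_classes)
        x = np.zeros(len(self.active_cubes) * n_cls)
        cidx = self.cube_index
        for cube, cls in bits:
            pos = cidx.get(cube)
            if pos is not None:
                x[pos * n_cls + cls] = 1.0
        return x

    def save(self, path) -> None:
        payload = {
            "version": 1,
            "hypothesis": self.hypothesis.to_dict(),
            "grid": self.grid.to_dict(),
            "active_cubes": self.active_cubes,
            "n_factors": self.n_factors,
            "intercept": self.intercept,
            "y_mean_train": self.y_mean_train,
            "floor": self.floor,
            "training_ids": self.training_ids,
            "fitted_values": self.fitted_values,
            "stats": self.stats,
            "align_tol": self.align_tol,
            "coefficients_b64": base64.b64encode(
                np.asarray(self.coefficients, dtype=np.float64).tobytes()
            ).decode("ascii"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "QSARModel":
        with open(path) as fh:
            d = json.load(fh)
        coef = np.frombuffer(
            base64.b64decode(d["coefficients_b64"]), dtype=np.float64
        ).copy()
        return cls(
            hypothesis=Hypothesis.from_dict(d["hypothesis"]),
            grid=GridSpec.from_dict(d["grid"]),
            active_cubes=list(d["active_cubes"]),
            n_factors=d["n_factors"],
            coefficients=coef,
            intercept=d["intercept"],
            y_mean_train=d["y_mean_train"],
            floor=d["floor"],
            training_ids=list(d["training_ids"]),
            fitted_values=dict(d["fitted_values"]),
            stats=dict(d["stats"]),
            align_tol=d["align_tol"],
        )


# ---------------------------------------------------------------------------
# PLS core


def _pls_fit_raw(X: np.ndarray, y: np.ndarray, n_factors: int):
    """Centered PLS fit; returns (coef, x_mean, y_mean)."""
    pls = PLSRegression(n_components=n_factors, scale=False)
    pls.fit(X, y)
    coef = pls.coef_.reshape(-1)
    return coef, X.mean(axis=0), float(y.mean())


def fit_pls(X: np.ndarray, y: np.ndarray, n_factors: int) -> dict:
    """Fit a PLS regression with ``n_factors`` latent variables.

    Returns a dict with ``coef`` / ``intercept`` (on raw X), fitted values
    and training statistics: R^2, SD (regression standard deviation with
    n - factors - 1 denominator), F and its p-value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n or n < n_factors + 2:
        raise ValueError("need rows(X) = len(y) >= n_factors + 2")
    if np.var(y) == 0:
        raise ValueError("response is constant; nothing to regress")
    if X.size <= 200_000:  # rank check only when affordable
        rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
        if n_factors > rank:
            raise ValueError(
                f"n_factors={n_factors} exceeds descriptor rank {rank}; "
                f"at most {rank} factors are extractable"
            )
    coef, x_mean, y_mean = _pls_fit_raw(X, y, n_factors)
    intercept = y_mean - float(x_mean @ coef)
    y_fit = X @ coef + intercept
    ss_res = float(((y - y_fit) ** 2).sum())
    ss_tot = float(((y - y_mean) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    dof = n - n_factors - 1
    sd = math.sqrt(ss_res / dof) if dof > 0 else float("nan")
    if ss_res > 0 and dof > 0:
        f_stat = ((ss_tot - ss_res) / n_factors) / (ss_res / dof)
        p_val = float(sstats.f.sf(f_stat, n_factors, dof))
    else:
        f_stat, p_val = float("inf"), 0.0
    return {
        "coef": coef,
        "intercept": intercept,
        "y_mean": y_mean,
        "fitted": y_fit,
        "r2": r2,
        "sd": sd,
        "f": f_stat,
        "p": p_val,
        "n_factors": n_factors,
    }


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels stratified by response: consecutive y-sorted blocks are
    scattered one-per-fold (seeded), so every fold spans the response range."""
    n = len(y)
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        labels = rng.permutation(n_folds)[: len(block)]
        folds[block] = labels
    return folds


def cross_validate(
    X: np.ndarray, y: np.ndarray, n_factors: int, n_folds: int = 10, seed: int = 0
) -> float:
    """Leave-n-out cross-validated Q^2 (stratified folds, seeded).

    Q^2 = 1 - PRESS / SS_tot over the concatenated held-out predictions,
    with SS_tot about the grand mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = _stratified_folds(y, n_folds, seed)
    y_pred = np.empty_like(y)
    for f in range(n_folds):
        mask = folds == f
        if mask.sum() == 0:
            raise ValueError(f"fold {f} is empty")
        coef, x_mean, y_mean = _pls_fit_raw(X[~mask], y[~mask], n_factors)
        y_pred[mask] = (X[mask] - x_mean) @ coef + y_mean
    press = float(((y - y_pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


def q2f3(y_out, y_pred_out, y_train) -> float:
    """Externally referenced predictive metric Q^2_F3.

    ``1 - [mean squared test error] / [training variance about the training
    mean]`` with the biased (1/n) variance convention on both sides.
    """
    y_out = np.asarray(y_out, dtype=float)
    y_pred_out = np.asarray(y_pred_out, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if len(y_out) != len(y_pred_out) or len(y_out) < 1:
        raise ValueError("y_out and y_pred_out must be equal length >= 1")
    if len(y_train) < 2:
        raise ValueError("need at least 2 training responses")
    denom = float(((y_train - y_train.mean()) ** 2).sum()) / len(y_train)
    if denom == 0:
        raise ValueError("training responses have zero variance")
    num = float(((y_out - y_pred_out) ** 2).sum()) / len(y_out)
    return 1.0 - num / denom


def select_model(models: list[QSARModel], experimental_error: float) -> QSARModel:
    """Pick the smallest factor count whose regression SD has dropped to the
    experimental error; fall back to the maximum-Q^2 model if none has."""
    if not models:
        raise ValueError("no fitted models to select from")
    ordered = sorted(models, key=lambda m: m.n_factors)
    for m in ordered:
        if m.stats.get("sd", float("inf")) <= experimental_error:
            return m
    with_q2 = [m for m in ordered if "q2" in m.stats]
    if with_q2:
        return max(with_q2, key=lambda m: m.stats["q2"])
    return max(ordered, key=lambda m: m.stats.get("r2", float("-inf")))


# ---------------------------------------------------------------------------
# model assembly / prediction


def prepare_training_data(
    hypothesis: Hypothesis,
    ensembles: list,
    spacing: float = 0.5,
    tol: float = 2.0,
    require_all: bool = False,
    features: list | None = None,
):
    """Align ensembles to the hypothesis and build the occupancy matrix.

    Returns ``(X, y, ids, grid, active_cubes, n_ignored)``.  Molecules that
    fail to match are dropped with a warning (they cannot be placed in the
    common reference frame).
    """
    if features is None:
        features = [ensemble_features(e) for e in ensembles]
    poses, kept = [], []
    for ei, (ens, feats) in enumerate(zip(ensembles, features)):
        pose = match_and_align(ens, feats, hypothesis, tol=tol, require_all=require_all)
        if pose is None:
            warnings.warn(f"molecule {ens.molecule_id} does not match the hypothesis")
            continue
        poses.append(pose)
        kept.append(ei)
    if not poses:
        raise ValueError("no training molecule matches the hypothesis")

    atom_data = {}
    all_coords = []
    for ei, pose in zip(kept, poses):
        ens = ensembles[ei]
        idx, radii, classes = heavy_atom_data(ens.mol)
        coords = pose.transform(ens.conformers[pose.conformer_index][0][idx])
        atom_data[ei] = (coords, radii, classes)
        all_coords.append(coords)
    grid = GridSpec.from_coords(np.vstack(all_coords), spacing=spacing)

    bit_sets = []
    n_ignored = 0
    cubes: set[int] = set()
    for ei in kept:
        bits, ign = occupancy_descriptor(*atom_data[ei], grid)
        bit_sets.append(bits)
        n_ignored += ign
        cubes.update(c for c, _ in bits)
    active_cubes = sorted(cubes)
    cube_pos = {c: i for i, c in enumerate(active_cubes)}
    n_cls = len(grid.atom_classes)
    X = np.zeros((len(kept), len(active_cubes) * n_cls))
    for row, bits in enumerate(bit_sets):
        for cube, cls in bits:
            X[row, cube_pos[cube] * n_cls + cls] = 1.0
    y = np.array([ensembles[ei].pic50 for ei in kept], dtype=float)
    ids = [ensembles[ei].molecule_id for ei in kept]
    return X, y, ids, grid, active_cubes, n_ignored


def train_factor_scan(
    hypothesis: Hypothesis,
    ensembles: list,
    max_factors: int = 7,
    spacing: float = 0.5,
    tol: float = 2.0,
    seed: int = 0,
    cv_folds: int = 10,
    cv_factors: set[int] | None = None,
    features: list | None = None,
) -> list[QSARModel]:
    """Fit PLS models with 1..max_factors latent variables on one alignment.

    ``cv_factors`` limits which factor counts get the (costly) cross-validated
    Q^2; by default only the largest does.
    """
    X, y, ids, grid, active_cubes, _ = prepare_training_data(
        hypothesis, ensembles, spacing=spacing, tol=tol, features=features
    )
    models = []
    cv_set = cv_factors if cv_factors is not None else {max_factors}
    for nf in range(1, max_factors + 1):
        fit = fit_pls(X, y, nf)
        stats_d = {k: fit[k] for k in ("r2", "sd", "f", "p")}
        if nf in cv_set:
            stats_d["q2"] = cross_validate(X, y, nf, n_folds=cv_folds, seed=seed)
        model = QSARModel(
            hypothesis=hypothesis,
            grid=grid,
            active_cubes=active_cubes,
            n_factors=nf,
            coefficients=fit["coef"],
            intercept=fit["intercept"],
            y_mean_train=fit["y_mean"],
            floor=float(y.min()),
            training_ids=list(ids),
            fitted_values={i: float(v) for i, v in zip(ids, fit["fitted"])},
            stats=stats_d,
            align_tol=tol,
        )
        models.append(model)
    return models


def predict(model: QSARModel, ensemble, features=None) -> tuple[float, bool]:
    """Predict pIC50 for one molecule.

    The molecule is aligned to the model's hypothesis (partial matches
    allowed, mirroring screening conditions); its occupancy bits restricted
    to the model's active cubes feed the linear PLS model.  A molecule with
    no acceptable alignment gets ``matched=False`` and the floor prediction
    (minimum training pIC50), ranking it last.
    """
    if features is None:
        features = ensemble_features(ensemble)
    pose = match_and_align(
        ensemble, features, model.hypothesis, tol=model.align_tol, require_all=False
    )
    if pose is None:
        return model.floor, False
    idx, radii, classes = heavy_atom_data(ensemble.mol)
    coords = pose.transform(ensemble.conformers[pose.conformer_index][0][idx])
    bits, _ = occupancy_descriptor(coords, radii, classes, model.grid)
    x = model.descriptor_vector(bits)
    return float(x @ model.coefficients + model.intercept), True


def export_coefficient_field(model: QSARModel, threshold: float = 1.5e-2):
    """Cube records of the PLS coefficient field above a magnitude threshold.

    Returns ``(records, n_positive, n_negative)`` where each record is
    ``(center_xyz, class_label, coefficient, sign)``.  Positive coefficients
    mark occupancy that increases predicted potency, negative ones occupancy
    that decreases it.
    """
    n_cls = len(model.grid.atom_classes)
    records = []
    n_pos = n_neg = 0
    for i, cube in enumerate(model.active_cubes):
        center = model.grid.cube_center(cube)
        for c in range(n_cls):
            coef = float(model.coefficients[i * n_cls + c])
            if abs(coef) >= threshold:
                sign = 1 if coef > 0 else -1
                records.append(
                    (tuple(center), model.grid.atom_classes[c], coef, sign)
                )
                if sign > 0:
                    n_pos += 1
                else:
                    n_neg += 1
    return records, n_pos, n_neg


def write_coefficient_field_csv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("x,y,z,atom_class,coefficient,sign\n")
        for (x, y, z), cls, coef, sign in records:
            fh.write(f"{x:.3f},{y:.3f},{z:.3f},{cls},{coef:.6g},{sign}\n")


def write_coefficient_field_pdb(records, path) -> None:
    """Pseudo-atom PDB with the coefficient in the B-factor column."""
    with open(path, "w") as fh:
        for i, ((x, y, z), cls, coef, _sign) in enumerate(records, start=1):
            fh.write(
                f"HETATM{i:5d}  C   CUB A{i % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{coef:6.2f}          "
                f" C\n"
            )
        fh.write("END\n")
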