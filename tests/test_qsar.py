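import numpy as np
import pytest
from rdkit import Chem

from pharmqsar import (
    GridSpec,
    MoleculeRecord,
    QSARModel,
    cross_validate,
    export_coefficient_field,
    fit_pls,
    generate_conformers,
    occupancy_descriptor,
    predict,
    q2f3,
    select_model,
)
from pharmqsar.alignment import superpose
from pharmqsar.pharmacophore import FeaturePoint, Hypothesis


# ---------------------------------------------------------------------------
# occupancy descriptors


def _bruteforce_bits(coords, radii, classes, grid):
    """Triple-loop oracle over every cube center."""
    bits = set()
    nx, ny, nz = grid.extents
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                center = grid.origin + grid.spacing * np.array([ix, iy, iz])
                for pos, r, cls in zip(coords, radii, classes):
                    if ((center - pos) ** 2).sum() <= r * r + 1e-12:
                        bits.add((grid.linear_index(ix, iy, iz), int(cls)))
    return bits


def test_single_carbon_occupancy_count():
    grid = GridSpec(origin=np.array([-4.0, -4.0, -4.0]), spacing=0.5,
                    extents=(17, 17, 17))
    coords = np.array([[0.0, 0.0, 0.0]])  # on a cube center
    radii = np.array([1.70])
    classes = np.array([1])
    bits, ignored = occupancy_descriptor(coords, radii, classes, grid)
    oracle = _bruteforce_bits(coords, radii, classes, grid)
    assert bits == oracle
    assert ignored == 0


def test_zero_atoms_gives_empty_descriptor():
    grid = GridSpec(origin=np.zeros(3), spacing=0.5, extents=(5, 5, 5))
    bits, ignored = occupancy_descriptor(
        np.zeros((0, 3)), np.zeros(0), np.zeros(0, dtype=int), grid
    )
    assert bits == set() and ignored == 0


def test_out_of_grid_atoms_counted():
    grid = GridSpec(origin=np.zeros(3), spacing=0.5, extents=(4, 4, 4))
    coords = np.array([[10.0, 10.0, 10.0]])
    bits, ignored = occupancy_descriptor(coords, np.array([1.5]), np.array([0]), grid)
    assert bits == set()
    assert ignored > 0


def test_occupancy_matches_bruteforce_on_random_molecules(rng):
    """50 random pseudo-molecules against the exhaustive sphere test."""
    for _ in range(50):
        n = rng.integers(3, 12)
        coords = rng.normal(0, 1.5, size=(n, 3))
        radii = rng.uniform(1.2, 2.0, size=n)
        classes = rng.integers(0, 6, size=n)
        grid = GridSpec.from_coords(coords, spacing=0.7)
        bits, _ = occupancy_descriptor(coords, radii, classes, grid)
        assert bits == _bruteforce_bits(coords, radii, classes, grid)


# ---------------------------------------------------------------------------
# PLS


def test_pls_at_full_rank_equals_least_squares(rng):
    X = rng.normal(size=(20, 5))
    y = rng.normal(size=20)
    fit = fit_pls(X, y, n_factors=5)
    # independent normal-equations oracle on centered data
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    y_ols = Xc @ beta + y.mean()
    assert np.allclose(fit["fitted"], y_ols, atol=1e-8)


def test_pls_recovers_noiseless_single_factor(rng):
    # centered orthogonal columns: one latent factor suffices for a
    # one-column signal
    Z = rng.normal(size=(30, 4))
    X, _ = np.linalg.qr(Z - Z.mean(axis=0))
    y = 2.0 * X[:, 1]
    fit = fit_pls(X, y, n_factors=1)
    assert fit["r2"] == pytest.approx(1.0, abs=1e-9)


def test_pls_input_validation(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(ValueError, match="constant"):
        fit_pls(X, np.ones(10), 1)
    X[:, 2] = X[:, 0] + X[:, 1]  # rank 2
    y = rng.normal(size=10)
    with pytest.raises(ValueError, match="rank"):
        fit_pls(X, y, n_factors=3)


def test_cross_validation_recovers_noiseless_signal(rng):
    X = rng.normal(size=(60, 5))
    w = rng.normal(size=5)
    y = X @ w
    q2 = cross_validate(X, y, n_factors=5, n_folds=10, seed=1)
    assert q2 >= 0.999
    assert cross_validate(X, y, 5, seed=3) == cross_validate(X, y, 5, seed=3)


def test_y_scrambling_destroys_q2(rng):
    """Permuting the response against the descriptors drives cross-validated
    Q^2 at or below zero in at least 95% of 100 trials."""
    n = 60
    X = rng.normal(size=(n, 10))
    w = rng.normal(size=10)
    y = X @ w + rng.normal(0, 0.3, size=n)
    bad = 0
    for seed in range(100):
        perm = np.random.default_rng(seed).permutation(n)
        q2 = cross_validate(X, y[perm], n_factors=5, n_folds=10, seed=seed)
        if q2 <= 0:
            bad += 1
    assert bad >= 95


def test_q2f3_reference_cases():
    y_train = [0.0, 1.0, 2.0]
    assert q2f3([1.0, 2.0], [1.0, 2.0], y_train) == pytest.approx(1.0)
    # hand evaluation: num = ((1-0)^2 + 0)/2 = 0.5; denom = 2/3; 1 - 0.75 = 0.25
    assert q2f3([1.0, 2.0], [0.0, 2.0], y_train) == pytest.approx(0.25)
    with pytest.raises(ValueError, match="zero variance"):
        q2f3([1.0], [0.5], [2.0, 2.0])
    with pytest.raises(ValueError):
        q2f3([1.0, 2.0], [1.0], y_train)


def test_q2f3_mean_predictor_is_near_zero(rng):
    """Predicting the training mean for test data drawn with the training
    variance gives Q^2_F3 around zero."""
    y_train = rng.normal(0, 1.0, size=5000)
    y_out = rng.normal(0, 1.0, size=20000)
    pred = np.full_like(y_out, y_train.mean())
    assert abs(q2f3(y_out, pred, y_train)) < 0.05


def test_q2f3_never_exceeds_one(rng):
    for _ in range(50):
        yt = rng.normal(size=10)
        yo = rng.normal(size=6)
        yp = rng.normal(size=6)
        assert q2f3(yo, yp, yt) <= 1.0


# ---------------------------------------------------------------------------
# model selection


def _dummy_model(nf, sd, q2=None):
    h = Hypothesis(features=[FeaturePoint("A", (0, 0, 0))])
    stats = {"sd": sd, "r2": 0.5}
    if q2 is not None:
        stats["q2"] = q2
    return QSARModel(
        hypothesis=h, grid=GridSpec(origin=np.zeros(3), extents=(1, 1, 1)),
        active_cubes=[0], n_factors=nf, coefficients=np.zeros(6), intercept=0.0,
        y_mean_train=0.0, floor=0.0, stats=stats,
    )


def test_select_model_sd_rule():
    models = [_dummy_model(i + 1, sd) for i, sd in enumerate((0.7, 0.5, 0.3, 0.18))]
    assert select_model(models, 0.2).n_factors == 4


def test_select_model_q2_fallback():
    models = [
        _dummy_model(1, 0.9, q2=0.3),
        _dummy_model(2, 0.8, q2=0.6),
        _dummy_model(3, 0.7, q2=0.5),
    ]
    assert select_model(models, 0.2).n_factors == 2
    (single,) = [_dummy_model(1, 0.9, q2=0.1)]
    assert select_model([single], 0.0001) is single


# ---------------------------------------------------------------------------
# fitted-model behaviour (shared synthetic study)


def test_training_r2_monotone_in_factors(small_study):
    r2s = [m.stats["r2"] for m in small_study.models]
    assert all(b >= a - 1e-9 for a, b in zip(r2s, r2s[1:]))


def test_q2_does_not_collapse_with_factors(small_study):
    X, y = small_study.X_train, small_study.y_train
    q2_1 = cross_validate(X, y, 1, n_folds=10, seed=7)
    q2_7 = cross_validate(X, y, 7, n_folds=10, seed=7)
    assert q2_7 >= q2_1


def test_training_predictions_consistent(small_study):
    model = small_study.model
    lib = small_study.library
    by_id = {r.id: r for r in lib.records}
    checked = 0
    for ens_id in model.training_ids[:5]:
        rec = by_id[ens_id]
        # regenerate the ensemble exactly as the pipeline prepared it
        ens = generate_conformers(
            rec,
            max_confs=10,
            seed=(7 * 9973 + [r.id for r in lib.records].index(ens_id)) & 0x7FFFFFFF,
        )
        pred, matched = predict(model, ens)
        assert matched
        assert pred == pytest.approx(model.fitted_values[ens_id], abs=1e-9)
        checked += 1
    assert checked == 5


def test_unmatched_molecule_gets_floor(small_study):
    ens = generate_conformers(
        MoleculeRecord(id="methane", mol=Chem.MolFromSmiles("C")), max_confs=3, seed=1
    )
    pred, matched = predict(small_study.model, ens)
    assert not matched
    assert pred == small_study.model.floor
    assert pred == pytest.approx(min(small_study.y_train))


def test_coefficient_field_threshold_rules(small_study):
    model = small_study.model
    records_all, n_pos, n_neg = export_coefficient_field(model, threshold=0.0)
    assert len(records_all) == len(model.active_cubes) * len(model.grid.atom_classes)
    big = float(np.abs(model.coefficients).max()) * 1.01
    records_none, *_ = export_coefficient_field(model, threshold=big)
    assert records_none == []
    records_def, n_pos_d, n_neg_d = export_coefficient_field(model)
    assert all(abs(r[2]) >= 1.5e-2 for r in records_def)
    assert n_pos_d + n_neg_d == len(records_def)


def test_positive_coefficients_concentrate_in_beneficial_region(small_study):
    """Cubes with potency-raising coefficients are enriched in the region
    where the generator rewards substituent occupancy."""
    model = small_study.model
    planted = small_study.library.ground_truth["planted"]
    # map the planted frame onto the model hypothesis frame (kind-respecting)
    hyp = model.hypothesis
    p_kinds = planted["feature_kinds"]
    p_pos = np.array(planted["feature_positions"])
    import itertools

    best = None
    d_idx = [i for i, k in enumerate(p_kinds) if k == "D"]
    r_idx = [i for i, k in enumerate(p_kinds) if k == "R"]
    a_idx = [i for i, k in enumerate(p_kinds) if k == "A"]
    hd = [i for i, f in enumerate(hyp.features) if f.kind == "D"]
    hr = [i for i, f in enumerate(hyp.features) if f.kind == "R"]
    ha = [i for i, f in enumerate(hyp.features) if f.kind == "A"]
    hyp_pos = np.array([f.position for f in hyp.features])
    for dp in itertools.permutations(d_idx):
        for rp in itertools.permutations(r_idx):
            sel = list(a_idx) + list(dp) + list(rp)
            hsel = ha + hd + hr
            rot, t, rmsd = superpose(hyp_pos[hsel], p_pos[sel])
            if best is None or rmsd < best[2]:
                best = (rot, t, rmsd)
    rot, t, rmsd = best
    assert rmsd < 1.5  # the recovered geometry is close to the planted one
    region = planted["regions"]["beneficial"]
    centers = np.array([rot @ np.array(c) + t for c in region["centers"]])
    radius = region["radius"]

    def in_region(points):
        d = np.linalg.norm(
            points[:, None, :] - centers[None, :, :], axis=-1
        ).min(axis=1)
        return (d <= radius).mean()

    records, n_pos, _ = export_coefficient_field(model, threshold=1.5e-2)
    pos_centers = np.array([r[0] for r in records if r[3] > 0])
    assert len(pos_centers) > 0
    all_centers = np.array([model.grid.cube_center(c) for c in model.active_cubes])
    frac_pos_in = in_region(pos_centers)
    frac_all_in = in_region(all_centers)
    assert frac_all_in > 0
    assert frac_pos_in >= 2.0 * frac_all_in


def test_model_json_roundtrip(tmp_path, small_study):
    model = small_study.model
    path = tmp_path / "model.json"
    model.save(path)
    back = QSARModel.load(path)
    assert back.n_factors == model.n_factors
    assert back.active_cubes == model.active_cubes
    assert np.allclose(back.coefficients, model.coefficients)
    assert back.stats == pytest.approx(model.stats)
    assert back.floor == model.floor
    assert back.grid.extents == model.grid.extents
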