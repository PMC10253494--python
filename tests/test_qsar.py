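"""Atom typing, grid occupancy encoding, PLS fitting and field maps."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from maosel.qsar import (
    ATOM_CLASSES,
    GridSpec,
    VDW_RADII,
    assign_atom_classes,
    auto_grid,
    drop_constant_columns,
    encode_occupancy,
    export_field_maps,
    fit_pls,
    read_field_map,
)
from maosel.synthetic import generate_aligned_grid_set


def embedded(smiles, seed=1):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(mol, params)
    return Chem.RemoveHs(mol)


class TestAtomClasses:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CC(C)=O", ["H", "X", "H", "W"]),  # carbonyl O is electron-withdrawing
            ("CCC", ["H", "H", "H"]),  # saturated carbons with C/H neighbours only
            ("CC(=O)[O-]", ["H", "X", "W", "N"]),  # carboxylate O is negative ionic
            ("CC(=O)O", ["H", "X", "N", "N"]),  # acid O ionized at model pH
            ("C[NH3+]", ["X", "P"]),
            ("CN", ["X", "D"]),
        ],
    )
    def test_rule_precedence(self, smiles, expected):
        assert assign_atom_classes(Chem.MolFromSmiles(smiles)) == expected

    def test_every_heavy_atom_classified(self):
        mol = Chem.MolFromSmiles("O=C1CCc2cc(OCc3ccc(I)cc3)ccc2N1")
        labels = assign_atom_classes(mol)
        assert len(labels) == mol.GetNumHeavyAtoms()
        assert set(labels) <= set(ATOM_CLASSES)


class TestEncodeOccupancy:
    def _single_atom_mol(self, symbol, position=(0.0, 0.0, 0.0)):
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom(symbol))
        conf = Chem.Conformer(1)
        conf.SetAtomPosition(0, position)
        m = mol.GetMol()
        m.AddConformer(conf)
        return m

    def test_single_carbon_occupies_nineteen_cubes(self):
        """A vdW-1.7 Å sphere on a grid node at 1.0 Å spacing covers the 19
        integer lattice points with squared norm <= 2.89 (1 + 6 + 12)."""
        mol = self._single_atom_mol("C")
        grid = GridSpec(origin=(-4.0, -4.0, -4.0), dims=(9, 9, 9), spacing=1.0)
        X, _ = encode_occupancy([mol], grid)
        assert int(X.sum()) == 19

    def test_matches_brute_force_distance_scan(self):
        mol = embedded("CC(=O)Nc1ccccc1O")
        X, grid = encode_occupancy([mol])
        labels = assign_atom_classes(mol)
        conf = mol.GetConformer()
        coords = conf.GetPositions()
        expected = np.zeros_like(X[0])
        nx, ny, nz = grid.dims
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    center = np.array(grid.origin) + np.array([i, j, k]) * grid.spacing
                    for pos, atom, cls in zip(coords, mol.GetAtoms(), labels):
                        r = VDW_RADII[atom.GetSymbol()]
                        if np.sum((center - pos) ** 2) <= r * r:
                            cube = (i * ny + j) * nz + k
                            expected[cube * 6 + ATOM_CLASSES.index(cls)] = 1
        assert np.array_equal(X[0], expected)

    def test_translation_of_frame_and_grid_is_invariant(self):
        mol = embedded("CCO")
        X1, grid = encode_occupancy([mol])
        shift = np.array([3.0, -2.0, 5.0])
        conf = mol.GetConformer()
        for i in range(mol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (np.array([p.x, p.y, p.z]) + shift).tolist())
        shifted_grid = GridSpec(
            origin=tuple(np.array(grid.origin) + shift), dims=grid.dims, spacing=grid.spacing
        )
        X2, _ = encode_occupancy([mol], shifted_grid)
        assert np.array_equal(X1, X2)

    def test_empty_list_and_out_of_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            encode_occupancy([])
        mol = self._single_atom_mol("C", (10.0, 0.0, 0.0))
        tight = GridSpec(origin=(0.0, 0.0, 0.0), dims=(3, 3, 3))
        with pytest.raises(ValueError, match="atom 0"):
            encode_occupancy([mol], tight)


class TestFitPLS:
    def test_rank_one_signal_needs_one_factor(self, rng):
        w = rng.normal(size=8)
        t = rng.normal(size=40)
        X = np.outer(t, w)
        y = 2.0 * t + 1.0
        model = fit_pls(X, y, n_factors=1, stability_subsets=0)
        assert model.factor_stats[0].r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_reference_pls_implementation(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(50, 30))
        y = rng.normal(size=50)
        for k in (1, 2, 4):
            mine = fit_pls(X, y, n_factors=k, stability_subsets=0, drop_constant=False)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.allclose(mine.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_full_rank_pls_equals_least_squares(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        model = fit_pls(X, y, n_factors=6, stability_subsets=0, drop_constant=False)
        Xd = np.column_stack([X, np.ones(30)])
        coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        assert np.allclose(model.predict(X), Xd @ coef, atol=1e-6)

    def test_coefficient_sign_recovery_across_seeds(self):
        """Planted coefficient signs recovered on >= 9/10 active cells in
        each of 20 seeded replicates at high signal-to-noise."""
        for seed in range(20):
            X, y, beta = generate_aligned_grid_set(
                200, (5, 4, 3), 10, effect_sd=1.0, noise_sd=0.1, seed=seed
            )
            model = fit_pls(X, y, n_factors=4, stability_subsets=0, drop_constant=False)
            active = np.flatnonzero(beta)
            agree = np.sum(np.sign(model.coefficients[active]) == np.sign(beta[active]))
            assert agree >= 9

    def test_training_rows_reproduce_fitted_values(self, rng):
        X, y, _ = generate_aligned_grid_set(60, (4, 3, 2), 5, noise_sd=0.2, seed=3)
        model = fit_pls(X, y, n_factors=3, stability_subsets=0)
        fitted = model.predict(X)
        assert np.corrcoef(fitted, y)[0, 1] ** 2 == pytest.approx(model.factor_stats[-1].r2, abs=1e-6)

    def test_all_zero_row_predicts_intercept(self, rng):
        X = (rng.random((40, 10)) < 0.5).astype(float)
        y = rng.normal(size=40)
        model = fit_pls(X, y, n_factors=2, stability_subsets=0, drop_constant=False)
        assert model.predict(np.zeros(10))[0] == pytest.approx(model.intercept)

    def test_input_validation(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(ValueError, match="constant y"):
            fit_pls(X, np.ones(20))
        model = fit_pls(X, rng.normal(size=20), n_factors=2, stability_subsets=0)
        with pytest.raises(ValueError, match="columns"):
            model.predict(np.zeros((3, 7)))

    def test_dropping_constant_columns_preserves_predictions(self, rng):
        X = (rng.random((40, 12)) < 0.5).astype(float)
        X[:, 3] = 1.0
        X[:, 8] = 0.0
        y = rng.normal(size=40)
        with_drop = fit_pls(X, y, n_factors=3, stability_subsets=0, drop_constant=True)
        without = fit_pls(X, y, n_factors=3, stability_subsets=0, drop_constant=False)
        assert np.allclose(with_drop.predict(X), without.predict(X), atol=1e-10)

    def test_factor_statistics_layout(self, rng):
        X, y, _ = generate_aligned_grid_set(80, (4, 3, 2), 6, noise_sd=0.3, seed=4)
        model = fit_pls(X, y, n_factors=4)
        assert [s.n_factors for s in model.factor_stats] == [1, 2, 3, 4]
        r2s = [s.r2 for s in model.factor_stats]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))  # monotone in factors
        for s in model.factor_stats:
            n, k = 80, s.n_factors
            expected_f = (s.r2 / k) / ((1 - s.r2) / (n - k - 1))
            assert s.f == pytest.approx(expected_f, rel=1e-9)
            assert 0 <= s.p <= 1
            assert s.stability is not None and s.stability <= 1.0


class TestFieldMaps:
    def _molecular_model(self, rng, target_cube=None, target_class="H"):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), dims=(2, 2, 2))
        n_cols = grid.n_cubes * 6
        X = (rng.random((40, n_cols)) < 0.5).astype(float)
        ci = ATOM_CLASSES.index(target_class)
        col = (target_cube or 3) * 6 + ci
        y = 2.0 * X[:, col] + 0.01 * rng.normal(size=40)
        return fit_pls(X, y, n_factors=4, grid=grid, stability_subsets=0, drop_constant=False), grid, col

    def test_planted_cube_carries_largest_positive_coefficient(self, rng, tmp_path):
        model, grid, col = self._molecular_model(rng)
        path = tmp_path / "field.cube"
        export_field_maps(model, "H", path)
        values, read_grid = read_field_map(path)
        assert read_grid.dims == grid.dims
        flat = values.ravel()
        assert flat.argmax() == col // 6
        assert flat.max() > 0

    def test_roundtrip_is_bit_exact(self, rng, tmp_path):
        model, _, _ = self._molecular_model(rng)
        path = tmp_path / "field.cube"
        export_field_maps(model, "H", path)
        values, _ = read_field_map(path)
        expected = model.coefficients[ATOM_CLASSES.index("H") :: 6].reshape(model.grid.dims)
        assert np.array_equal(values, expected)

    def test_negative_mask_empty_for_positive_field(self, rng, tmp_path):
        model, _, _ = self._molecular_model(rng)
        base = model.coefficients.copy()
        model.coefficients = np.abs(base)  # force an all-positive field
        path = tmp_path / "neg.cube"
        export_field_maps(model, "H", path, sign="negative")
        values, _ = read_field_map(path)
        assert np.all(values == 0)

    def test_unknown_class_rejected(self, rng, tmp_path):
        model, _, _ = self._molecular_model(rng)
        with pytest.raises(ValueError, match="unknown atom class"):
            export_field_maps(model, "Q", tmp_path / "x.cube")
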