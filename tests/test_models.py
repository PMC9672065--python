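"""Composed maps: density map, multistate functional, MSKS, full MSHK."""

import numpy as np
import pytest

from mshk.basis import project_density
from mshk.geometry import reflect_geometry
from mshk.models import (
    DensityMap,
    MSHKModel,
    MSHKSurface,
    MultistateEnergyFunctional,
    predict_msks,
    train_msks,
)
from mshk.surrogate import (
    SIGMA_V_PERMUTATION,
    surrogate_density,
    surrogate_energies,
)


@pytest.fixture(scope="module")
def scaled_inputs(tiny_training_set):
    ts = tiny_training_set
    scale = np.sqrt(ts.grid.voxel_volume)
    return ts, ts.potentials * scale


class TestDensityMap:
    def test_interpolates_training_coefficients(self, scaled_inputs):
        ts, x = scaled_inputs
        dm = DensityMap(sigma=1.5, ridge_lambda=0.0).fit(x, ts.coefficients)
        pred = dm.predict(x)
        np.testing.assert_allclose(pred, ts.coefficients, atol=1e-6)

    def test_single_sample_decays_away(self, scaled_inputs):
        ts, x = scaled_inputs
        dm = DensityMap(sigma=0.5, ridge_lambda=0.0).fit(x[:1], ts.coefficients[:1])
        np.testing.assert_allclose(dm.predict(x[:1]), ts.coefficients[:1], atol=1e-10)
        far = x[:1] + 100.0
        assert np.abs(dm.predict(far)).max() < 1e-10

    def test_out_of_sample_error_decreases_with_m(self, scaled_inputs):
        ts, x = scaled_inputs
        test = slice(60, 80)
        maes = []
        for m in (10, 30, 60):
            dm = DensityMap(sigma=2.0, ridge_lambda=1e-10).fit(x[:m], ts.coefficients[:m])
            maes.append(np.abs(dm.predict(x[test]) - ts.coefficients[test]).mean())
        assert maes[0] > maes[1] > maes[2]

    def test_shape_validation(self, scaled_inputs):
        ts, x = scaled_inputs
        with pytest.raises(ValueError, match="shape"):
            DensityMap().fit(x, ts.coefficients[:, 0, :])
        with pytest.raises(ValueError, match="every state"):
            DensityMap().fit(x[:5], ts.coefficients)


class TestMultistateEnergyFunctional:
    def test_reproduces_training_rows_at_zero_ridge(self, scaled_inputs):
        ts, _ = scaled_inputs
        u = ts.coefficients.reshape(-1, ts.coefficients.shape[-1])
        e = ts.energies.reshape(-1)
        fn = MultistateEnergyFunctional(sigma=1.0, ridge_lambda=0.0).fit(u, e)
        np.testing.assert_allclose(fn.predict(u), e, atol=1e-5)

    def test_degenerate_duplicate_rows_fit_consistently(self, rng):
        u = rng.standard_normal((10, 6))
        u = np.concatenate([u, u[:3]])  # identical descriptors, identical targets
        e = np.concatenate([np.arange(10.0), np.arange(3.0)])
        fn = MultistateEnergyFunctional(sigma=1.0, ridge_lambda=1e-8).fit(u, e)
        assert np.all(np.isfinite(fn.predict(u)))

    def test_adding_s1_rows_keeps_s2_functional_usable(self, tiny_training_set):
        """Pooling a third state's densities must not break the S2 map:
        held-out S2 accuracy stays within a small factor of the
        two-state model and far below the inter-state energy scale."""
        from mshk.krr import median_pairwise_distance

        ts = tiny_training_set
        u = ts.coefficients
        e = ts.energies
        train, test = slice(0, 60), slice(60, 80)
        sigma = median_pairwise_distance(u[train].reshape(-1, u.shape[-1]))

        def s2_mae(states):
            rows = np.concatenate([u[train, s, :] for s in states])
            targets = np.concatenate([e[train, s] for s in states])
            fn = MultistateEnergyFunctional(sigma=sigma, ridge_lambda=1e-10).fit(rows, targets)
            return np.abs(fn.predict(u[test, 2, :]) - e[test, 2]).mean()

        mae_02 = s2_mae([0, 2])
        mae_012 = s2_mae([0, 1, 2])
        assert mae_012 <= 2.0 * mae_02
        assert mae_012 < 25.0  # an order of magnitude below the state offsets

    def test_callable_on_density_coefficients(self, scaled_inputs):
        from mshk.basis import DensityCoefficients

        ts, _ = scaled_inputs
        u = ts.coefficients.reshape(-1, ts.coefficients.shape[-1])
        e = ts.energies.reshape(-1)
        fn = MultistateEnergyFunctional(sigma=2.0, ridge_lambda=1e-10).fit(u, e)
        val = fn(DensityCoefficients(u[4]))
        assert val == pytest.approx(fn.predict(u[4:5])[0])


class TestMSHKModel:
    def test_end_to_end_interpolation(self, tiny_training_set):
        model = MSHKModel(sigma_v=0.9, lambda_v=1e-12, sigma_u=0.7, lambda_u=1e-12).fit(
            tiny_training_set
        )
        pred = model.predict(tiny_training_set.geometries)
        assert np.abs(pred - tiny_training_set.energies).max() < 1e-6

    def test_reflection_symmetry_of_symmetrised_model(self, tiny_training_set, template, rng):
        model = MSHKModel(sigma_v=2.0, lambda_v=1e-10, sigma_u=2.0, lambda_u=1e-10).fit(
            tiny_training_set
        )
        for _ in range(5):
            g = template.with_coordinates(
                template.coordinates + 0.05 * rng.standard_normal((9, 3))
            )
            gr = reflect_geometry(g, SIGMA_V_PERMUTATION)
            assert np.abs(model.predict(g) - model.predict(gr)).max() < 1e-3

    def test_density_prediction_feeds_functional(self, tiny_training_set, spec):
        model = MSHKModel(sigma_v=1.5, lambda_v=1e-12, sigma_u=1.5, lambda_u=1e-12).fit(
            tiny_training_set
        )
        g = tiny_training_set.geometries[5]
        details = model.predict(g, return_details=True)
        u_ref = project_density(
            surrogate_density(spec, g, 2, tiny_training_set.grid), tiny_training_set.basis
        )
        assert np.abs(details["coefficients"][2] - u_ref.coefficients).max() < 1e-4

    def test_extrapolation_flag_and_warning(self, tiny_training_set, template):
        model = MSHKModel(sigma_v=1.5, lambda_v=1e-10, sigma_u=1.5, lambda_u=1e-10).fit(
            tiny_training_set
        )
        runaway = template.with_coordinates(template.coordinates * 4.0)
        with pytest.warns(UserWarning, match="extrapolation"):
            details = model.predict(runaway, return_details=True)
        assert details["extrapolated"]

    def test_functional_state_subset_selection(self, tiny_training_set):
        model = MSHKModel(
            sigma_v=1.5, lambda_v=1e-12, sigma_u=1.5, lambda_u=1e-12,
            functional_states=(0, 2),
        ).fit(tiny_training_set)
        pred = model.predict(tiny_training_set.geometries[:10])
        np.testing.assert_allclose(
            pred[:, [0, 2]], tiny_training_set.energies[:10, [0, 2]], atol=1e-5
        )
        with pytest.raises(ValueError, match="absent"):
            MSHKModel(functional_states=(5,)).fit(tiny_training_set)

    def test_save_load_bit_stable(self, tmp_path, tiny_training_set, perturbed_geometries):
        model = MSHKModel(sigma_v=1.8, lambda_v=1e-10, sigma_u=1.2, lambda_u=1e-9).fit(
            tiny_training_set
        )
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = MSHKModel.load(path)
        a = model.predict(perturbed_geometries[:4])
        b = loaded.predict(perturbed_geometries[:4])
        np.testing.assert_array_equal(a, b)

    def test_surface_adapter_matches_predict(self, tiny_training_set, perturbed_geometries):
        model = MSHKModel(sigma_v=1.5, lambda_v=1e-10, sigma_u=1.5, lambda_u=1e-10).fit(
            tiny_training_set
        )
        surf = MSHKSurface(model, state=2)
        g = perturbed_geometries[0]
        assert surf.energy(g) == pytest.approx(model.predict(g)[2])
        batch = surf.energy_batch(perturbed_geometries[:3])
        np.testing.assert_allclose(batch, model.predict(perturbed_geometries[:3])[:, 2])


class TestMSKS:
    def test_interpolation_at_training_points(self, tiny_training_set):
        msks = train_msks(tiny_training_set, sigma=1.5, ridge_lambda=0.0)
        pred = predict_msks(msks, tiny_training_set.geometries)
        np.testing.assert_allclose(pred, tiny_training_set.energies, atol=1e-6)

    def test_far_query_returns_offsets(self, tiny_training_set, template):
        # a blown-up molecule stays far from training even after alignment
        msks = train_msks(tiny_training_set, sigma=0.5, ridge_lambda=1e-10)
        runaway = template.with_coordinates(template.coordinates * 3.0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict_msks(msks, runaway)
        np.testing.assert_allclose(pred, msks.energy_offset_, atol=1e-8)

    def test_state_columns_match_oracle_order(self, tiny_training_set, spec):
        msks = train_msks(tiny_training_set, sigma=1.5, ridge_lambda=1e-12)
        g = tiny_training_set.geometries[3]
        np.testing.assert_allclose(
            predict_msks(msks, g), surrogate_energies(spec, g), atol=1e-4
        )
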