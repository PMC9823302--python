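"""Weight calibration, synthesis and the estimator interface."""

import numpy as np
import pytest
from sklearn.base import clone

from grappa2d.containers import MultiCoilKSpace
from grappa2d.engine import (GrappaReconstructor, build_calibration_system,
                             reconstruct, solve_weights, synthesize)
from grappa2d.kernels import (BlockSpec, KernelGeometry, kernels_for_algorithm)
from grappa2d.sampling import SamplingScheme, apply_mask, lattice_mask_2d, make_mask

ALGOS = ("LK", "EX", "SK", "BK")


# ---------------------------------------------------------------------------
# planted-weight construction: fill the lattice with random samples, then
# compute every missing sample as the exact W_true-combination of its
# sources (periodic indexing), independently of the engine's gather code.


def split_fits(algorithm, block, n_x):
    fits = []
    for geom in kernels_for_algorithm(algorithm, block, n_x):
        if geom.family.startswith(("LK", "EX")):
            fits.extend(geom.per_target())
        else:
            fits.append(geom)
    return fits


def plant_dataset(algorithm, block, n_x, J=3, shape=(10, 20, 20), seed=0):
    rng = np.random.default_rng(seed)
    N_x, N_y, N_z = shape
    scheme = SamplingScheme(block.R_y, block.R_z, 14, 14, shape)
    cy, cz = scheme.dc_index
    data = np.zeros((J,) + shape, dtype=complex)
    lat = lattice_mask_2d(scheme)
    n_lat = int(lat.sum())
    data[:, :, lat] = (rng.standard_normal((J, N_x, n_lat))
                       + 1j * rng.standard_normal((J, N_x, n_lat)))

    fits = split_fits(algorithm, block, n_x)
    weights = [rng.standard_normal((g.n_src * J, g.n_tgt * J))
               + 1j * rng.standard_normal((g.n_src * J, g.n_tgt * J))
               for g in fits]
    ys = [y for y in range(N_y) if (y - cy) % block.R_y == 0]
    zs = [z for z in range(N_z) if (z - cz) % block.R_z == 0]
    for geom, W in zip(fits, weights):
        for x in range(N_x):
            for y0 in ys:
                for z0 in zs:
                    row = []
                    for s, p, q in geom.sources:
                        row.append(data[:, (x + s) % N_x,
                                        (y0 + p * block.R_y) % N_y,
                                        (z0 + q * block.R_z) % N_z])
                    row = np.concatenate(row)
                    est = row @ W
                    for k, (rx, ry, rz) in enumerate(geom.targets):
                        data[:, (x + rx) % N_x, (y0 + ry) % N_y, (z0 + rz) % N_z] = \
                            est[k * J:(k + 1) * J]
    return MultiCoilKSpace(data), scheme, fits, weights


class TestCalibrationSystem:
    def test_one_dimensional_anchor_count(self, rng):
        # 1 channel, 8-sample ACS, R = 2, bracketing kernel: three anchors
        acs = MultiCoilKSpace(rng.standard_normal((1, 1, 8, 1)) + 0j)
        geom = KernelGeometry("LK-ky", ((0, 0, 0), (0, 1, 0)), ((0, 1, 0),),
                              1, None, BlockSpec(2, 1))
        system = build_calibration_system(acs, geom)
        assert system.N_f == 3

    def test_matrix_column_counts(self, rng):
        J = 3
        acs = MultiCoilKSpace(rng.standard_normal((J, 4, 12, 12)) + 0j)
        geom = kernels_for_algorithm("BK", BlockSpec(2, 2))[0]
        system = build_calibration_system(acs, geom)
        assert system.S_src.shape[1] == geom.n_src * J
        assert system.S_tgt.shape[1] == geom.n_tgt * J

    def test_undersized_acs_rejected(self, rng):
        acs = MultiCoilKSpace(rng.standard_normal((1, 1, 3, 3)) + 0j)
        geom = kernels_for_algorithm("BK", BlockSpec(2, 2))[0]
        with pytest.raises(ValueError, match="footprint"):
            build_calibration_system(acs, geom)


class TestSolveWeights:
    def make_system(self, rng, N_f=40, n_src=2, n_tgt=1, J=4):
        geom = kernels_for_algorithm("LK", BlockSpec(2, 2))[0]
        assert geom.n_src == n_src and geom.n_tgt == n_tgt
        A = rng.standard_normal((N_f, n_src * J)) + 1j * rng.standard_normal((N_f, n_src * J))
        return geom, A

    def test_planted_solution_identity(self, rng):
        geom, A = self.make_system(rng)
        W_true = rng.standard_normal((8, 4)) + 1j * rng.standard_normal((8, 4))
        from grappa2d.engine import CalibrationSystem
        system = CalibrationSystem(A, A @ W_true, geom, 4)
        ws = solve_weights(system)
        assert np.linalg.norm(ws.W - W_true) / np.linalg.norm(W_true) < 1e-8

    def test_zero_targets_give_zero_weights(self, rng):
        geom, A = self.make_system(rng)
        from grappa2d.engine import CalibrationSystem
        ws = solve_weights(CalibrationSystem(A, np.zeros((40, 4), dtype=complex), geom, 4))
        np.testing.assert_allclose(ws.W, 0, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        # small well-conditioned system: W = (A^H A)^{-1} A^H B
        geom, A = self.make_system(rng)
        B = rng.standard_normal((40, 4)) + 1j * rng.standard_normal((40, 4))
        from grappa2d.engine import CalibrationSystem
        ws = solve_weights(CalibrationSystem(A, B, geom, 4))
        AH = A.conj().T
        W_ne = np.linalg.solve(AH @ A, AH @ B)
        np.testing.assert_allclose(ws.W, W_ne, atol=1e-10)

    def test_empty_system_rejected(self, rng):
        geom, A = self.make_system(rng)
        from grappa2d.engine import CalibrationSystem
        with pytest.raises(ValueError):
            solve_weights(CalibrationSystem(A[:0], A[:0, :4], geom, 4))


class TestSynthesize:
    def test_zero_weights_leave_missing_samples_zero(self, rng):
        from grappa2d.engine import WeightSet
        geom = kernels_for_algorithm("SK", BlockSpec(2, 2))[0]
        J = 2
        scheme = SamplingScheme(2, 2, 0, 0, (2, 12, 12))
        mask = make_mask(scheme)
        ksp = apply_mask(MultiCoilKSpace(
            rng.standard_normal((J, 2, 12, 12)) + 0j), mask)
        ws = WeightSet(np.zeros((geom.n_src * J, geom.n_tgt * J), dtype=complex), geom, J)
        out = synthesize(ksp, mask, ws)
        assert np.all(out.data[:, ~mask.mask] == 0)

    def test_acquired_samples_never_overwritten(self, rng):
        from grappa2d.engine import WeightSet
        geom = kernels_for_algorithm("BK", BlockSpec(2, 2))[0]
        J = 2
        scheme = SamplingScheme(2, 2, 0, 0, (2, 12, 12))
        mask = make_mask(scheme)
        ksp = apply_mask(MultiCoilKSpace(
            rng.standard_normal((J, 2, 12, 12)) + 0j), mask)
        W = rng.standard_normal((geom.n_src * J, geom.n_tgt * J)) + 0j
        out = synthesize(ksp, mask, WeightSet(W, geom, J))
        np.testing.assert_array_equal(out.data[:, mask.mask], ksp.data[:, mask.mask])


@pytest.mark.parametrize("algorithm", ALGOS)
@pytest.mark.parametrize("n_x", [1, 3])
def test_planted_weight_recovery(algorithm, n_x):
    """Data built as an exact weight-combination of its sources is recovered
    exactly: fitted weights match the planted ones and synthesis reproduces
    the ground truth."""
    block = BlockSpec(2, 2)
    truth, scheme, fits, weights = plant_dataset(algorithm, block, n_x)
    under = apply_mask(truth, make_mask(scheme))
    est = GrappaReconstructor(algorithm=algorithm, n_x=n_x, include_acs=False)
    est.fit(under)
    assert len(est.weights_) == len(weights)
    for ws, W_true in zip(est.weights_, weights):
        rel = np.linalg.norm(ws.W - W_true) / np.linalg.norm(W_true)
        assert rel < 1e-8, f"{ws.geometry.family} weights off by {rel:.2e}"
    recon = est.transform(under)
    scale = np.abs(truth.data).max()
    np.testing.assert_allclose(recon.data, truth.data, atol=1e-8 * scale)


@pytest.mark.parametrize("algorithm", ALGOS)
def test_every_missing_position_covered_exactly_once(algorithm):
    """Coverage audit on a 16x16 PE plane at R = 2x2: the kernel target
    classes partition the missing positions."""
    block = BlockSpec(2, 2)
    N_y = N_z = 16
    scheme = SamplingScheme(2, 2, 0, 0, (1, N_y, N_z))
    cy, cz = scheme.dc_index
    lat = lattice_mask_2d(scheme)
    counts = np.zeros((N_y, N_z), dtype=int)
    ys = range(cy % 2 - 2, N_y + 2, 2)
    zs = range(cz % 2 - 2, N_z + 2, 2)
    for geom in split_fits(algorithm, block, 1):
        for y0 in ys:
            for z0 in zs:
                for _, ry, rz in geom.targets:
                    y, z = y0 + ry, z0 + rz
                    if 0 <= y < N_y and 0 <= z < N_z and not lat[y, z]:
                        counts[y, z] += 1
    assert np.all(counts[~lat] == 1)
    assert np.all(counts[lat] == 0)


class TestReconstruct:
    def test_unaccelerated_input_unchanged(self, rng):
        scheme = SamplingScheme(1, 1, 4, 4, (2, 8, 8))
        ksp = apply_mask(MultiCoilKSpace(
            rng.standard_normal((2, 2, 8, 8)) + 0j), make_mask(scheme))
        out = reconstruct(ksp, "BK")
        np.testing.assert_array_equal(out.data, ksp.data)

    def test_linearity_in_the_data(self, tiny_sim):
        ksp, _, _ = tiny_sim
        scheme = SamplingScheme(2, 2, 10, 10, ksp.grid_shape)
        under = apply_mask(ksp, make_mask(scheme))
        r1 = reconstruct(under, "SK", include_acs=False)
        scaled = MultiCoilKSpace(2.5 * under.data, under.deltas, under.mask)
        r2 = reconstruct(scaled, "SK", include_acs=False)
        np.testing.assert_allclose(r2.data, 2.5 * r1.data,
                                   atol=1e-10 * np.abs(r1.data).max())

    def test_all_missing_samples_estimated(self, tiny_sim):
        ksp, _, _ = tiny_sim
        scheme = SamplingScheme(2, 2, 10, 10, ksp.grid_shape)
        mask = make_mask(scheme)
        under = apply_mask(ksp, mask)
        out = reconstruct(under, "BK")
        assert np.all(np.abs(out.data[:, ~mask.mask]) > 0)

    def test_acquired_data_preserved_exactly(self, tiny_sim):
        ksp, _, _ = tiny_sim
        scheme = SamplingScheme(2, 2, 10, 10, ksp.grid_shape)
        mask = make_mask(scheme)
        under = apply_mask(ksp, mask)
        out = reconstruct(under, "EX", include_acs=True)
        np.testing.assert_array_equal(out.data[:, mask.mask], under.data[:, mask.mask])


class TestEstimatorInterface:
    def test_get_set_params_and_clone(self):
        est = GrappaReconstructor(algorithm="SK", n_x=3, ridge=0.1)
        params = est.get_params()
        assert params["algorithm"] == "SK" and params["n_x"] == 3
        est2 = clone(est).set_params(algorithm="BK")
        assert est2.get_params()["algorithm"] == "BK"
        assert est.get_params()["algorithm"] == "SK"

    def test_transform_before_fit_rejected(self, rng):
        scheme = SamplingScheme(2, 2, 6, 6, (2, 12, 12))
        ksp = apply_mask(MultiCoilKSpace(
            rng.standard_normal((1, 2, 12, 12)) + 0j), make_mask(scheme))
        with pytest.raises(RuntimeError):
            GrappaReconstructor().transform(ksp)

    def test_unknown_algorithm_rejected(self, rng):
        scheme = SamplingScheme(2, 2, 6, 6, (2, 12, 12))
        ksp = apply_mask(MultiCoilKSpace(
            rng.standard_normal((1, 2, 12, 12)) + 0j), make_mask(scheme))
        with pytest.raises(ValueError):
            GrappaReconstructor(algorithm="SENSE").fit(ksp)

    def test_maskless_input_rejected(self, rng):
        ksp = MultiCoilKSpace(rng.standard_normal((1, 2, 12, 12)) + 0j)
        with pytest.raises(ValueError):
            GrappaReconstructor().fit(ksp)
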