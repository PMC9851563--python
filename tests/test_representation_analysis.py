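"""Selectivity classification, RDMs, RSA regression, weight summaries, MDS."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from hebbgate import representation_analysis as ra
from hebbgate.network_core import NetworkParams, TrainConfig, init_network
from hebbgate.learning_motifs import apply_manual_gating

LEV = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])


def _constructed_units():
    """Noise-free units with known selectivity labels."""
    gx, gy = np.meshgrid(LEV, LEV, indexing="ij")
    x = np.concatenate([gx.ravel(), gx.ravel()])
    y = np.concatenate([gy.ravel(), gy.ravel()])
    in1 = np.repeat([1.0, 0.0], 25)
    in2 = 1.0 - in1
    units = {
        ra.TASK1_SELECTIVE: np.maximum(x, 0.0) * in1,          # ReLU of x, task 1 only
        ra.TASK2_SELECTIVE: np.maximum(y + 2.0, 0.0) * in2,    # scales with y, task 2 only
        ra.AGNOSTIC: np.maximum(x + y + 4.0, 0.0),             # congruency unit, both tasks
        ra.SILENT: np.zeros(50),
    }
    labels, cols = zip(*units.items())
    return np.column_stack(cols), list(labels)


class TestSelectivity:
    def test_exact_on_noise_free_constructed_units(self):
        A, truth = _constructed_units()
        res = ra.classify_selectivity(A)
        assert res.labels == truth

    def test_equal_relevant_and_irrelevant_scaling_is_agnostic(self):
        # active only in task 1 but responds to x + y: not axis-aligned,
        # hence not task-selective
        A, _ = _constructed_units()
        gx, gy = np.meshgrid(LEV, LEV, indexing="ij")
        mixed = np.concatenate([(gx + gy).ravel() + 4.0, np.zeros(25)])
        res = ra.classify_selectivity(np.column_stack([A, mixed]))
        assert res.labels[-1] == ra.AGNOSTIC

    def test_fractions_sum_to_one(self, vanilla_interleaved_run):
        res = ra.classify_selectivity(vanilla_interleaved_run.test_traces["post"])
        total = sum(res.fractions[k] for k in
                    (ra.TASK1_SELECTIVE, ra.TASK2_SELECTIVE, ra.AGNOSTIC, ra.SILENT))
        assert total == pytest.approx(1.0)


class TestHiddenRDM:
    def test_identical_patterns_have_zero_distance(self):
        A = np.ones((50, 4))
        assert np.all(ra.hidden_rdm(A) == 0.0)

    def test_orthonormal_patterns_distance_sqrt2(self):
        A = np.zeros((50, 50))
        A[0, 0] = A[1, 1] = 1.0
        assert ra.hidden_rdm(A)[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_invariant_to_hidden_unit_permutation(self, vanilla_interleaved_run, rng):
        A = vanilla_interleaved_run.test_traces["post"]
        perm = rng.permutation(A.shape[1])
        assert np.allclose(ra.hidden_rdm(A), ra.hidden_rdm(A[:, perm]))


class TestModelRDMs:
    def test_symmetry_zero_diagonal_and_determinism(self):
        first = ra.model_rdms()
        second = ra.model_rdms()
        for a, b in zip(first, second):
            assert np.array_equal(a, b)
            assert np.allclose(a, a.T)
            assert np.all(np.diag(a) == 0.0)

    def test_grid_model_task_separation_is_unit_distance(self):
        grid, _, _ = ra.model_rdms()
        # same (x, y), different task: only the t coordinate differs
        for i in range(25):
            assert grid[i, i + 25] == pytest.approx(1.0)

    def test_orthogonal_model_collapses_irrelevant_dimension(self):
        _, orth, _ = ra.model_rdms()
        # two task-1 conditions differing only in y (x = -2 row: indices 0..4)
        assert orth[0, 4] == 0.0
        # two task-2 conditions differing only in x
        assert orth[25, 45] == 0.0
        # but the relevant dimension is preserved
        assert orth[0, 20] == pytest.approx(4.0)

    def test_diagonal_model_collapses_antidiagonals(self):
        _, _, diag = ra.model_rdms()
        # conditions with equal x + y within a task are identical: (x=-2,y=2)
        # is index 4, (x=2,y=-2) is index 20
        assert diag[4, 20] == pytest.approx(0.0)
        assert diag[4, 4 + 25] == pytest.approx(1.0)


class TestRSARegression:
    @pytest.mark.parametrize("which", [0, 1, 2])
    def test_model_identifies_itself(self, which):
        models = ra.model_rdms()
        coef = ra.rsa_regression(models[which], models)
        betas = [coef.beta_grid, coef.beta_orth, coef.beta_diag]
        assert betas[which] == pytest.approx(1.0, abs=1e-8)
        for i, b in enumerate(betas):
            if i != which:
                assert b == pytest.approx(0.0, abs=1e-8)

    def test_rank_deficient_design_flagged(self):
        grid, _, _ = ra.model_rdms()
        with pytest.raises(np.linalg.LinAlgError):
            ra.rsa_regression(grid, (grid, grid, grid))

    def test_group_tests_report_t_and_p(self, rng):
        table = rng.normal(loc=[0.0, 0.5, -0.5], scale=0.1, size=(30, 3))
        out = ra.rsa_group_tests(table)
        assert out["orth"][0] > 0 and out["orth"][1] < 1e-6
        assert out["diag"][0] < 0


class TestWeightSummaries:
    def test_manual_gating_correlation_is_minus_one(self):
        p = apply_manual_gating(init_network(TrainConfig(seed=0)))
        assert ra.task_weight_correlation(p) == pytest.approx(-1.0)

    def test_fresh_networks_uncorrelated_on_average(self):
        rs = [ra.task_weight_correlation(init_network(TrainConfig(seed=s)))
              for s in range(50)]
        assert abs(np.mean(rs)) < 0.05

    def test_degenerate_columns_give_nan(self):
        p = init_network(TrainConfig(seed=0))
        p.task_weights[:, 0] = 1.0
        assert np.isnan(ra.task_weight_correlation(p))

    def test_readout_magnitudes_by_class(self):
        A, labels = _constructed_units()
        p = NetworkParams(np.zeros((4, 27)), np.zeros(4),
                          np.array([0.1, 0.1, 5.0, 0.1]), 0.0)
        out = ra.readout_magnitudes(p, labels)
        assert out[ra.AGNOSTIC] == pytest.approx(5.0)
        assert out[ra.TASK1_SELECTIVE] == pytest.approx(0.1)

    def test_empty_class_is_flagged_nan(self):
        p = init_network(TrainConfig(seed=0))
        out = ra.readout_magnitudes(p, [ra.AGNOSTIC] * 100)
        assert np.isnan(out[ra.SILENT])
        assert not np.isnan(out[ra.AGNOSTIC])

    def test_receptive_fields_of_random_init_are_flat(self):
        p = init_network(TrainConfig(seed=1))
        maps = ra.receptive_field_summary(p, [ra.AGNOSTIC] * 100)
        assert np.abs(maps[ra.AGNOSTIC]).max() < 0.05

    def test_receptive_field_of_constructed_x_selective_bank(self):
        # 100 units whose image weights equal the x level of each pixel:
        # the class-mean map varies along x and is flat along y
        gx, gy = np.meshgrid(LEV, LEV, indexing="ij")
        W = np.zeros((100, 27))
        W[:, :25] = gx.ravel()
        p = NetworkParams(W, np.zeros(100), np.zeros(100), 0.0)
        m = ra.receptive_field_summary(p, [ra.TASK1_SELECTIVE] * 100)[ra.TASK1_SELECTIVE]
        assert np.allclose(m, gx)
        assert np.allclose(m.std(axis=1), 0.0)   # flat along y
        assert m.std(axis=0).sum() > 0           # varies along x


class TestClassicalMDS:
    def test_collinear_points_recovered_exactly_in_one_dimension(self):
        pts = np.array([[0.0], [1.0], [3.0], [6.0]])
        D = squareform(pdist(pts))
        emb = ra.classical_mds(D, dims=1)
        assert np.allclose(squareform(pdist(emb)), D, atol=1e-9)

    def test_embedding_distances_never_exceed_originals(self, vanilla_interleaved_run):
        D = ra.hidden_rdm(vanilla_interleaved_run.test_traces["post"])
        emb = ra.classical_mds(D, dims=3)
        assert np.all(squareform(pdist(emb)) <= D + 1e-8)

    def test_grid_model_rdm_embeds_as_two_separated_grids(self):
        grid, _, _ = ra.model_rdms()
        emb = ra.classical_mds(grid, dims=3)
        # the grid configuration is exactly 3-dimensional
        assert np.allclose(squareform(pdist(emb)), grid, atol=1e-8)
        # one axis separates the tasks, the others span the 5x5 lattice
        gap = np.abs(emb[:25].mean(0) - emb[25:].mean(0))
        axis = np.argmax(gap)
        assert gap[axis] == pytest.approx(1.0, abs=1e-8)

    def test_strongly_non_euclidean_rdm_flagged(self):
        D = 1.0 - np.eye(4)
        D[0, 1] = D[1, 0] = 10.0   # violates triangle inequality badly
        with pytest.raises(ValueError):
            ra.classical_mds(D, dims=2)
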