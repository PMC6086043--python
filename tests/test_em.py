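import numpy as np
import pytest
from sklearn.base import clone

from conftest import make_compendium, random_incidence
from mirem.compendium import build_view
from mirem.em import (
    EMProblem,
    EMRanker,
    build_problem,
    dense_ranks,
    e_step,
    initialize,
    m_step,
    observed_loglik,
    rank_mirnas,
    run_em,
)
from mirem.enrichment import select_candidates
from mirem.errors import ValidationError
from mirem.id_mapping import GeneSet

TOY_Y = np.array([[1, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


def toy_problem():
    return EMProblem(genes=("g1", "g2", "g3", "g4"), mirnas=("A", "B"), Y=TOY_Y)


def gene_set_of(genes):
    return GeneSet(genes=tuple(genes), n_input=len(genes), n_unmapped=0,
                   n_duplicates=0)


class TestBuildProblem:
    def _setup(self, targets, gene_list, threshold=1.0):
        view = build_view(make_compendium({"A": targets}), ["A"])
        gs = gene_set_of(gene_list)
        cand = select_candidates(view, gs, threshold=threshold,
                                 use_adjusted=False)
        return cand, view, gs

    def test_direct_construction(self):
        # Z_mir pads the universe so the toy overlaps stay significant
        cand, view, gs = self._setup(
            {"A_mir": ["g1", "g2", "g3"], "B_mir": ["g3", "g4"],
             "Z_mir": ["x1", "x2", "x3", "x4"]},
            ["g1", "g2", "g3", "g4"],
        )
        problem = build_problem(cand, view, gs)
        idx = {m: j for j, m in enumerate(problem.mirnas)}
        Y = problem.Y[:, [idx["A_mir"], idx["B_mir"]]]
        assert problem.genes == ("g1", "g2", "g3", "g4")
        np.testing.assert_array_equal(Y, TOY_Y)

    def test_uncovered_gene_excluded(self):
        # D_mir pads the universe so overlaps are informative; the
        # threshold keeps weakly-overlapping C_mir (p ~ 0.29) out
        cand, view, gs = self._setup(
            {"A_mir": ["g1", "g2"], "B_mir": ["g2", "g3"], "C_mir": ["g9"],
             "D_mir": [f"h{i}" for i in range(10)]},
            ["g1", "g2", "g3", "g9"],
            threshold=0.1,
        )
        assert "C_mir" not in cand.selected_ids
        problem = build_problem(cand, view, gs)
        assert "g9" in problem.excluded_genes
        assert problem.n_genes == 3

    def test_single_candidate_is_precondition_error(self):
        cand, view, gs = self._setup(
            {"A_mir": ["g1", "g2", "g3"], "B_mir": ["h1", "h2"]},
            ["g1", "g2", "g3"],
        )
        with pytest.raises(ValidationError, match="short-circuit"):
            build_problem(cand, view, gs)


class TestSteps:
    def test_initialize_is_uniform(self):
        state = initialize(toy_problem())
        np.testing.assert_allclose(state.p_hat, [0.5, 0.5])
        assert state.iteration == 0

    @pytest.mark.parametrize("K", [2, 5])
    def test_initialize_uniform_any_k(self, K):
        Y = np.ones((3, K))
        problem = EMProblem(
            genes=tuple(f"g{i}" for i in range(3)),
            mirnas=tuple(f"m{j}" for j in range(K)),
            Y=Y,
        )
        np.testing.assert_allclose(initialize(problem).p_hat, np.full(K, 1 / K))

    def test_e_step_proportional_split(self):
        problem = EMProblem(genes=("g",), mirnas=("A", "B"),
                            Y=np.array([[1.0, 1.0]]))
        state = initialize(problem)
        state = e_step(
            type(state)(p_hat=np.array([0.3, 0.1]), z_hat=state.z_hat,
                        iteration=0, loglik=state.loglik),
            problem,
        )
        np.testing.assert_allclose(state.z_hat, [[0.75, 0.25]])

    def test_e_step_single_support_gets_full_mass(self):
        state = e_step(initialize(toy_problem()), toy_problem())
        np.testing.assert_allclose(state.z_hat[0], [1.0, 0.0])
        np.testing.assert_allclose(state.z_hat[3], [0.0, 1.0])

    def test_e_step_uniform_p_symmetric(self):
        problem = EMProblem(genes=("g",), mirnas=("A", "B", "C"),
                            Y=np.array([[1.0, 1.0, 1.0]]))
        state = e_step(initialize(problem), problem)
        np.testing.assert_allclose(state.z_hat, [[1 / 3, 1 / 3, 1 / 3]])

    def test_m_step_column_averages(self):
        problem = toy_problem()
        state = e_step(initialize(problem), problem)
        z = np.array([[1, 0], [1, 0], [0.5, 0.5], [0, 1]], dtype=float)
        state = type(state)(p_hat=state.p_hat, z_hat=z, iteration=0,
                            loglik=state.loglik)
        new = m_step(state, problem)
        np.testing.assert_allclose(new.p_hat, [0.625, 0.375])
        assert new.iteration == 1

    def test_m_step_requires_row_stochastic_z(self):
        problem = toy_problem()
        state = initialize(problem)  # z_hat still all-zero
        with pytest.raises(ValidationError, match="row-stochastic"):
            m_step(state, problem)


class TestRunEM:
    def test_toy_fixed_point(self):
        result = run_em(toy_problem(), tol=1e-9)
        # shared gene g3 splits so that x = (2 + x)/4  =>  x = 2/3
        assert result.em_scores["A"] == pytest.approx(2 / 3, abs=1e-6)
        assert result.em_scores["B"] == pytest.approx(1 / 3, abs=1e-6)
        assert result.converged

    def test_disjoint_supports_reduce_to_counting(self):
        Y = np.array([[1, 0], [1, 0], [1, 0], [0, 1]], dtype=float)
        problem = EMProblem(genes=("a", "b", "c", "d"), mirnas=("A", "B"), Y=Y)
        result = run_em(problem, tol=1e-12)
        assert result.em_scores["A"] == pytest.approx(0.75)
        assert result.em_scores["B"] == pytest.approx(0.25)

    def test_full_symmetry_is_a_fixed_point(self):
        Y = np.ones((5, 2))
        problem = EMProblem(
            genes=tuple(f"g{i}" for i in range(5)), mirnas=("A", "B"), Y=Y
        )
        result = run_em(problem)
        assert result.em_scores["A"] == pytest.approx(0.5)
        assert result.em_scores["B"] == pytest.approx(0.5)

    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            Y = random_incidence(rng, int(rng.integers(3, 30)),
                                 int(rng.integers(2, 8)))
            problem = EMProblem(
                genes=tuple(f"g{i}" for i in range(Y.shape[0])),
                mirnas=tuple(f"m{j}" for j in range(Y.shape[1])),
                Y=Y,
            )
            result = run_em(problem)
            assert sum(result.em_scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_non_convergence_warns_not_raises(self):
        result = None
        with pytest.warns(RuntimeWarning, match="did not converge"):
            result = run_em(toy_problem(), tol=1e-15, max_iter=3)
        assert not result.converged
        assert result.n_iterations == 3

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        Y = random_incidence(rng, 12, 4)
        genes = tuple(f"g{i}" for i in range(12))
        mirnas = tuple(f"m{j}" for j in range(4))
        base = run_em(EMProblem(genes=genes, mirnas=mirnas, Y=Y), tol=1e-10)
        row_perm = rng.permutation(12)
        col_perm = rng.permutation(4)
        permuted = run_em(
            EMProblem(
                genes=tuple(genes[i] for i in row_perm),
                mirnas=tuple(mirnas[j] for j in col_perm),
                Y=Y[np.ix_(row_perm, col_perm)],
            ),
            tol=1e-10,
        )
        for m in mirnas:
            assert permuted.em_scores[m] == pytest.approx(
                base.em_scores[m], abs=1e-9
            )

    def test_subset_mirna_never_outranks_superset(self):
        # B's targets are a strict subset of A's; identical evidence on the
        # shared genes must not let B overtake A
        Y = np.array(
            [[1, 1], [1, 1], [1, 0], [1, 0], [1, 0]], dtype=float
        )
        problem = EMProblem(
            genes=tuple(f"g{i}" for i in range(5)), mirnas=("A", "B"), Y=Y
        )
        result = run_em(problem, tol=1e-10)
        assert result.em_scores["A"] >= result.em_scores["B"]
        assert result.ranks["A"] <= result.ranks["B"]


class TestEMRankerEstimator:
    def test_sklearn_param_interface(self):
        ranker = EMRanker(tol=1e-6, max_iter=50)
        assert ranker.get_params() == {"tol": 1e-6, "max_iter": 50}
        cloned = clone(ranker)
        assert cloned.get_params() == ranker.get_params()

    def test_fitted_attributes(self):
        ranker = EMRanker(tol=1e-9).fit(TOY_Y)
        assert ranker.p_hat_.shape == (2,)
        assert ranker.z_hat_.shape == TOY_Y.shape
        np.testing.assert_allclose(ranker.z_hat_.sum(axis=1), 1.0, atol=1e-12)
        assert (ranker.z_hat_[TOY_Y == 0] == 0).all()
        assert ranker.converged_
        assert np.all(np.diff(ranker.logliks_) >= -1e-10)

    def test_score_is_observed_loglik(self):
        ranker = EMRanker(tol=1e-9).fit(TOY_Y)
        assert ranker.score(TOY_Y) == pytest.approx(
            observed_loglik(TOY_Y, ranker.p_hat_)
        )

    @pytest.mark.parametrize(
        "Y",
        [
            np.array([[1.0], [1.0]]),                 # K = 1
            np.array([[0.0, 0.0], [1.0, 1.0]]),        # empty gene row
            np.array([[1.0, 0.0], [1.0, 0.0]]),        # empty miRNA column
            np.array([[2.0, 1.0], [1.0, 1.0]]),        # non-binary
        ],
    )
    def test_invalid_incidence_rejected(self, Y):
        with pytest.raises(ValidationError):
            EMRanker().fit(Y)


class TestRanking:
    def test_dense_ranks_share_on_ties(self):
        assert dense_ranks({"A": 0.5, "B": 0.5, "C": 0.2}) == {
            "A": 1, "B": 1, "C": 2,
        }

    def test_rank_report_orders_and_breaks_ties(self):
        view = build_view(
            make_compendium(
                {"A": {"mirA": ["g1", "g2", "g3"], "mirB": ["g3", "g4"],
                       "mirZ": ["x1", "x2", "x3", "x4"]}}
            ),
            ["A"],
        )
        gs = gene_set_of(["g1", "g2", "g3", "g4"])
        cand = select_candidates(view, gs, threshold=1.0, use_adjusted=False)
        result = run_em(build_problem(cand, view, gs), tol=1e-9)
        report = rank_mirnas(result, cand)
        assert list(report["mirna_id"]) == ["mirA", "mirB"]
        assert list(report["em_rank"]) == [1, 2]

    def test_tie_broken_by_adjusted_p_then_id(self):
        from mirem.em import EMResult
        from mirem.enrichment import CandidateSet, EnrichmentResult

        def enr(mid, p):
            return EnrichmentResult(mirna_id=mid, n_universe=100, n_targets=10,
                                    n_set=10, n_overlap=5, p_raw=p, p_adj=p)

        cand = CandidateSet(
            results=(enr("A", 0.01), enr("B", 0.001)),
            selected=(enr("B", 0.001), enr("A", 0.01)),
            threshold=0.05, use_adjusted=True, n_set_in_universe=10,
        )
        result = EMResult(
            em_scores={"A": 0.5, "B": 0.5}, ranks={"A": 1, "B": 1},
            n_iterations=1, converged=True, trace=(),
        )
        report = rank_mirnas(result, cand)
        assert list(report["mirna_id"]) == ["B", "A"]
        assert list(report["em_rank"]) == [1, 1]
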