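"""Expectation-maximization core for miRNA prioritization.

The model: N genes from the input set, K candidate miRNAs, and an
observed binary incidence matrix Y where ``y_ik = 1`` iff miRNA k is
predicted to target gene i.  The latent assignment ``z_ik`` says which
miRNA actually represses gene i; a gene cannot be repressed by a miRNA
that is not predicted to target it (structural zero).  The parameter of
interest is ``p_k``, the fraction of genes repressed by miRNA k, with
``sum_k p_k = 1``.

Starting from the uniform ``p_k = 1/K``, the E-step assigns each gene
softly across its supporting miRNAs in proportion to the current ``p``:

    z_ik = y_ik * p_k / sum_k y_ik * p_k

and the M-step re-estimates each component as the average assignment:

    p_k = sum_i z_ik / N

Iteration stops when the max-norm change in ``p`` falls below ``tol``.
Because shared target genes are split between their miRNAs rather than
counted fully for each, overlapping predictions are down-weighted and the
converged ``p_k`` (the "EM score") ranks the candidates.

The observed-data log-likelihood ``sum_i log(sum_k y_ik p_k)`` is concave
in ``p`` on the simplex, so the deterministic uniform start reaches the
global maximum; no restarts are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .compendium import CompendiumView
from .enrichment import CandidateSet
from .errors import ValidationError
from .id_mapping import GeneSet

__all__ = [
    "EMProblem",
    "EMState",
    "EMResult",
    "EMRanker",
    "build_problem",
    "initialize",
    "e_step",
    "m_step",
    "run_em",
    "rank_mirnas",
    "observed_loglik",
]


def _validate_incidence(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValidationError(f"Y must be 2-D, got shape {Y.shape}")
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValidationError("Y must be binary (0/1)")
    if Y.shape[1] < 2:
        raise ValidationError("EM requires K >= 2 miRNAs (K = 1 short-circuits)")
    if (Y.sum(axis=1) == 0).any():
        raise ValidationError("every gene row of Y must have >= 1 supporting miRNA")
    if (Y.sum(axis=0) == 0).any():
        raise ValidationError("every miRNA column of Y must target >= 1 gene")
    return Y


def observed_loglik(Y: np.ndarray, p: np.ndarray) -> float:
    """Observed-data log-likelihood sum_i log(sum_k y_ik p_k)."""
    mix = np.asarray(Y, dtype=float) @ np.asarray(p, dtype=float)
    # a row's mixture weight can underflow to 0 only in degenerate float
    # situations; floor it so the trace stays finite
    return float(np.log(np.maximum(mix, np.finfo(float).tiny)).sum())


def _e_step_matrix(Y: np.ndarray, p: np.ndarray) -> np.ndarray:
    weighted = Y * p
    denom = weighted.sum(axis=1, keepdims=True)
    zero_rows = denom[:, 0] == 0.0
    if zero_rows.any():
        # all supported p_k collapsed to 0 for these genes: spread the
        # membership uniformly over the row's support
        weighted[zero_rows] = Y[zero_rows]
        denom[zero_rows] = Y[zero_rows].sum(axis=1, keepdims=True)
    return weighted / denom


def _m_step_vector(Z: np.ndarray) -> np.ndarray:
    return Z.sum(axis=0) / Z.shape[0]


class EMRanker(BaseEstimator):
    """EM estimator for the per-miRNA repression fractions ``p_k``.

    scikit-learn style: ``fit(Y)`` takes the binary gene x miRNA incidence
    matrix and exposes the converged estimates as fitted attributes.

    Parameters
    ----------
    tol : float, default 0.001
        Convergence threshold on ``max_k |p_k^(m) - p_k^(m-1)|``.
    max_iter : int, default 1000
        Safety cap on EM iterations; hitting it sets ``converged_ = False``
        and emits a warning rather than raising.

    Attributes
    ----------
    p_hat_ : ndarray of shape (K,)
        Converged repression-fraction estimates (the EM scores); sums to 1.
    z_hat_ : ndarray of shape (N, K)
        Posterior soft assignments at the converged ``p``; each row sums
        to 1 and is zero wherever Y is zero.
    n_iter_ : int
        Number of completed E/M iterations.
    converged_ : bool
    logliks_ : ndarray
        Observed-data log-likelihood after initialization and after each
        M-step (non-decreasing, the EM ascent property).
    deltas_ : ndarray
        Max-norm parameter change per iteration.
    """

    def __init__(self, tol: float = 1e-3, max_iter: int = 1000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, Y, y=None) -> "EMRanker":
        if self.tol <= 0:
            raise ValidationError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValidationError(f"max_iter must be >= 1, got {self.max_iter}")
        Y = _validate_incidence(Y)
        n_genes, n_mirnas = Y.shape
        p = np.full(n_mirnas, 1.0 / n_mirnas)
        logliks = [observed_loglik(Y, p)]
        deltas: list[float] = []
        converged = False
        n_iter = 0
        Z = np.zeros_like(Y)
        for n_iter in range(1, self.max_iter + 1):
            Z = _e_step_matrix(Y, p)
            p_new = _m_step_vector(Z)
            delta = float(np.max(np.abs(p_new - p)))
            p = p_new
            deltas.append(delta)
            logliks.append(observed_loglik(Y, p))
            if delta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_iter} iterations "
                f"(last delta {deltas[-1]:.3e})",
                RuntimeWarning,
                stacklevel=2,
            )
        # refresh the soft assignments so z_hat_ matches the final p_hat_
        self.z_hat_ = _e_step_matrix(Y, p)
        self.p_hat_ = p
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.logliks_ = np.asarray(logliks)
        self.deltas_ = np.asarray(deltas)
        self.n_features_in_ = n_mirnas
        return self

    def score(self, Y, y=None) -> float:
        """Observed-data log-likelihood of Y under the fitted ``p_hat_``."""
        check_is_fitted(self, "p_hat_")
        return observed_loglik(_validate_incidence(Y), self.p_hat_)


# ---------------------------------------------------------------------------
# functional surface over the estimator


@dataclass(frozen=True)
class EMProblem:
    """Incidence matrix Y restricted to covered genes x candidate miRNAs."""

    genes: tuple[str, ...]
    mirnas: tuple[str, ...]
    Y: np.ndarray
    excluded_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        Y = _validate_incidence(self.Y)
        if Y.shape != (len(self.genes), len(self.mirnas)):
            raise ValidationError("Y shape inconsistent with gene/miRNA lists")
        object.__setattr__(self, "Y", Y)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)


@dataclass(frozen=True)
class EMState:
    """One point of the EM trajectory."""

    p_hat: np.ndarray
    z_hat: np.ndarray
    iteration: int
    loglik: float
    converged: bool = False
    delta: float = float("inf")


@dataclass(frozen=True)
class EMResult:
    """Converged estimates: EM scores, dense ranks, diagnostics trace."""

    em_scores: dict[str, float]
    ranks: dict[str, int]
    n_iterations: int
    converged: bool
    trace: tuple[tuple[float, float], ...]  # (delta, loglik) per iteration

    @property
    def score_vector(self) -> np.ndarray:
        return np.array(list(self.em_scores.values()))


def build_problem(
    candidates: CandidateSet, view: CompendiumView, gene_set: GeneSet
) -> EMProblem:
    """Restrict Y to (input genes in the universe) x (selected miRNAs).

    Genes not targeted by any selected candidate are moved to
    ``excluded_genes`` so every row of Y has support; all-zero columns
    cannot occur because every candidate had overlap >= 1 (asserted).
    """
    mirnas = tuple(candidates.selected_ids)
    if len(mirnas) < 2:
        raise ValidationError(
            "EM needs >= 2 selected miRNAs; a single survivor is the "
            "HP-only short-circuit handled by the pipeline"
        )
    target_sets = {m: view.targets_of(m) for m in mirnas}
    universe = view.universe
    covered: list[str] = []
    excluded: list[str] = []
    for gene in gene_set.genes:
        if gene not in universe:
            continue
        if any(gene in target_sets[m] for m in mirnas):
            covered.append(gene)
        else:
            excluded.append(gene)
    if not covered:
        raise ValidationError("no gene in the set is targeted by any candidate")
    Y = np.zeros((len(covered), len(mirnas)))
    for j, mirna in enumerate(mirnas):
        targets = target_sets[mirna]
        for i, gene in enumerate(covered):
            if gene in targets:
                Y[i, j] = 1.0
    assert (Y.sum(axis=0) > 0).all(), "candidate with zero overlap reached EM"
    return EMProblem(
        genes=tuple(covered), mirnas=mirnas, Y=Y, excluded_genes=tuple(excluded)
    )


def initialize(problem: EMProblem) -> EMState:
    """Uniform start p_k = 1/K; memberships not yet evaluated."""
    K = problem.n_mirnas
    p0 = np.full(K, 1.0 / K)
    return EMState(
        p_hat=p0,
        z_hat=np.zeros_like(problem.Y),
        iteration=0,
        loglik=observed_loglik(problem.Y, p0),
    )


def e_step(state: EMState, problem: EMProblem) -> EMState:
    """Soft-assign each gene across its supporting miRNAs."""
    Z = _e_step_matrix(problem.Y, state.p_hat)
    return replace(state, z_hat=Z)


def m_step(state: EMState, problem: EMProblem) -> EMState:
    """Re-estimate p_k as the average membership; advances the iteration."""
    row_sums = state.z_hat.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-9):
        raise ValidationError("m_step requires a row-stochastic z_hat (run e_step)")
    p_new = _m_step_vector(state.z_hat)
    delta = float(np.max(np.abs(p_new - state.p_hat)))
    return EMState(
        p_hat=p_new,
        z_hat=state.z_hat,
        iteration=state.iteration + 1,
        loglik=observed_loglik(problem.Y, p_new),
        delta=delta,
    )


def run_em(
    problem: EMProblem, tol: float = 1e-3, max_iter: int = 1000
) -> EMResult:
    """Run EM to convergence and package scores, ranks and the trace."""
    ranker = EMRanker(tol=tol, max_iter=max_iter).fit(problem.Y)
    scores = {m: float(s) for m, s in zip(problem.mirnas, ranker.p_hat_)}
    ranks = dense_ranks(scores)
    trace = tuple(
        (float(d), float(ll))
        for d, ll in zip(ranker.deltas_, ranker.logliks_[1:])
    )
    return EMResult(
        em_scores=scores,
        ranks=ranks,
        n_iterations=int(ranker.n_iter_),
        converged=bool(ranker.converged_),
        trace=trace,
    )


def dense_ranks(scores: dict[str, float]) -> dict[str, int]:
    """Dense ranks by descending score: equal scores share a rank."""
    distinct = sorted(set(scores.values()), reverse=True)
    level = {s: i + 1 for i, s in enumerate(distinct)}
    return {m: level[s] for m, s in scores.items()}


def rank_mirnas(result: EMResult, candidates: CandidateSet) -> pd.DataFrame:
    """Ranked report rows: EM score, rank and enrichment statistics.

    Rows are ordered by EM score descending, ties broken by adjusted p
    ascending, then miRNA ID; ranks are dense on the score.
    """
    enrichment = {r.mirna_id: r for r in candidates.results}
    missing = set(result.em_scores) - set(enrichment)
    if missing:
        raise ValidationError(f"scored miRNAs without enrichment results: {missing}")
    rows = []
    for mirna_id, score in result.em_scores.items():
        stats = enrichment[mirna_id]
        rows.append(
            {
                "mirna_id": mirna_id,
                "em_score": score,
                "em_rank": result.ranks[mirna_id],
                "p_raw": stats.p_raw,
                "p_adj": stats.p_adj,
                "n_overlap": stats.n_overlap,
                "n_targets": stats.n_targets,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["em_score", "p_adj", "mirna_id"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return df
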