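"""Hypergeometric over-representation filtering of candidate miRNAs.

For every miRNA with at least one predicted target inside the input gene
set, the upper-tail hypergeometric probability asks how surprising the
observed overlap is against the background universe (all genes covered by
the selected database view).  Benjamini-Hochberg correction is applied
across the tested miRNAs and only those below the threshold proceed to
the EM stage; if exactly one survives, the pipeline short-circuits and
reports it without EM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .compendium import CompendiumView
from .errors import ValidationError
from .id_mapping import GeneSet


def hypergeom_pvalue(
    n_universe: int, n_targets: int, n_set: int, n_overlap: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= n_overlap).

    X counts the overlap when ``n_set`` genes are drawn without
    replacement from a universe of ``n_universe`` genes of which
    ``n_targets`` are targets of the miRNA.  Computed through the survival
    function, which is numerically stable and exact for the count ranges
    used here.
    """
    for name, value in (
        ("n_universe", n_universe),
        ("n_targets", n_targets),
        ("n_set", n_set),
        ("n_overlap", n_overlap),
    ):
        if int(value) != value or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {value}")
    if n_targets > n_universe:
        raise ValidationError(f"n_targets ({n_targets}) exceeds n_universe ({n_universe})")
    if n_set > n_universe:
        raise ValidationError(f"n_set ({n_set}) exceeds n_universe ({n_universe})")
    if n_overlap > min(n_targets, n_set):
        raise ValidationError(
            f"n_overlap ({n_overlap}) exceeds min(n_targets, n_set)"
        )
    # sf(k-1) = P(X >= k); includes the whole support, so p is in (0, 1]
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_targets, n_set))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Standard procedure: sort ascending, scale p_(i) by m/i, enforce
    monotonicity from the largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    # p*(m/i) can round one ulp below p itself; adjusted >= raw holds
    # mathematically, so clamp the rounding error away
    adjusted = np.maximum(adjusted, p[order])
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric statistics for one tested miRNA."""

    mirna_id: str
    n_universe: int
    n_targets: int
    n_set: int
    n_overlap: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_overlap <= min(self.n_targets, self.n_set):
            raise ValidationError(f"{self.mirna_id}: inconsistent overlap counts")
        if not (0 < self.p_raw <= 1 and self.p_raw <= self.p_adj <= 1):
            raise ValidationError(f"{self.mirna_id}: inconsistent p-values")


@dataclass(frozen=True)
class CandidateSet:
    """All tested miRNAs plus the subset selected for the EM stage.

    ``single_hit`` flags the workflow short-circuit: exactly one selected
    miRNA means EM is skipped and that miRNA is reported alone.
    """

    results: tuple[EnrichmentResult, ...]  # sorted by p_adj ascending
    selected: tuple[EnrichmentResult, ...]
    threshold: float
    use_adjusted: bool
    n_set_in_universe: int
    dropped_genes: tuple[str, ...] = ()
    warning: str | None = None

    @property
    def single_hit(self) -> bool:
        return len(self.selected) == 1

    @property
    def selected_ids(self) -> tuple[str, ...]:
        return tuple(r.mirna_id for r in self.selected)


def select_candidates(
    view: CompendiumView,
    gene_set: GeneSet,
    threshold: float = 0.01,
    use_adjusted: bool = True,
) -> CandidateSet:
    """Test every overlapping miRNA and select those passing the threshold.

    Input genes absent from the view's universe are dropped from the draw
    count ``n_set`` (and reported); miRNAs with zero overlap are excluded
    from both testing and the BH family.  Selection uses strict
    ``p < threshold`` on the BH-adjusted p by default, or on the raw p
    when ``use_adjusted`` is false.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    universe = view.universe
    in_universe = [g for g in gene_set.genes if g in universe]
    dropped = tuple(g for g in gene_set.genes if g not in universe)
    if not in_universe:
        raise ValidationError(
            "none of the input genes occur in the selected database view"
        )
    gene_pool = set(in_universe)
    n_universe = len(universe)
    n_set = len(in_universe)

    tested: list[tuple[str, int, int]] = []
    for mirna_id in sorted(view.candidate_mirnas):
        targets = view.targets_of(mirna_id)
        n_overlap = len(targets & gene_pool)
        if n_overlap >= 1:
            tested.append((mirna_id, len(targets), n_overlap))

    if not tested:
        return CandidateSet(
            results=(),
            selected=(),
            threshold=threshold,
            use_adjusted=use_adjusted,
            n_set_in_universe=n_set,
            dropped_genes=dropped,
            warning="no miRNA has any predicted target in the gene set",
        )

    n_targets_arr = np.array([t for _, t, _ in tested])
    n_overlap_arr = np.array([o for _, _, o in tested])
    p_raw = hypergeom.sf(n_overlap_arr - 1, n_universe, n_targets_arr, n_set)
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    p_adj = bh_adjust(p_raw)

    results = [
        EnrichmentResult(
            mirna_id=mid,
            n_universe=n_universe,
            n_targets=int(nt),
            n_set=n_set,
            n_overlap=int(no),
            p_raw=float(pr),
            p_adj=float(pa),
        )
        for (mid, nt, no), pr, pa in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.mirna_id))
    selected = tuple(
        r
        for r in results
        if (r.p_adj if use_adjusted else r.p_raw) < threshold
    )
    warning = None if selected else "no miRNA passed the significance threshold"
    return CandidateSet(
        results=tuple(results),
        selected=selected,
        threshold=threshold,
        use_adjusted=use_adjusted,
        n_set_in_universe=n_set,
        dropped_genes=dropped,
        warning=warning,
    )
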