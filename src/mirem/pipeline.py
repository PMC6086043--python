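"""End-to-end orchestration of the five analysis steps.

normalize gene IDs -> build the database view -> hypergeometric + BH
filtering -> EM prioritization (or the single-survivor short-circuit) ->
seed clustering; then write every output artifact (ranked results,
enrichment table, binary interaction heatmap, HP-vs-EM scatter data,
seed dendrogram, cluster table, run metadata).  The pipeline contains no
randomness: reruns on identical inputs produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .compendium import CompendiumView, build_view, load_compendium
from .em import EMResult, build_problem, rank_mirnas, run_em
from .enrichment import CandidateSet, select_candidates
from .errors import ValidationError
from .id_mapping import GeneSet, load_mapping, normalize_gene_list, read_gene_list
from .seeds import SeedCluster, cluster_seeds


@dataclass(frozen=True)
class RunConfig:
    """All analysis parameters; defaults are the benchmark settings
    (p-value threshold 0.01 on BH-adjusted values, EM convergence
    parameter 0.001, interactions common to >= 3 databases, conserved
    interactions only)."""

    gene_list_path: str
    mapping_path: str
    databases: Mapping[str, str]  # name -> path
    selected_dbs: tuple[str, ...] | None = None
    min_db_count: int = 3
    conserved_only: bool = True
    p_threshold: float = 0.01
    use_adjusted: bool = True
    em_tol: float = 1e-3
    em_max_iter: int = 1000
    seed_cluster_cutoff: float = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValidationError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.em_tol <= 0:
            raise ValidationError(f"em_tol must be positive, got {self.em_tol}")
        if self.em_max_iter < 1:
            raise ValidationError("em_max_iter must be >= 1")
        if self.seed_cluster_cutoff < 0:
            raise ValidationError("seed_cluster_cutoff must be >= 0")
        if not self.databases:
            raise ValidationError("at least one database must be configured")
        n_selected = len(self.selected_dbs) if self.selected_dbs else len(self.databases)
        if not 1 <= self.min_db_count <= n_selected:
            raise ValidationError(
                f"min_db_count must be in [1, {n_selected}], got {self.min_db_count}"
            )
        for path in (self.gene_list_path, self.mapping_path, *self.databases.values()):
            if not Path(path).exists():
                raise ValidationError(f"input file not found: {path}")


@dataclass
class RunReport:
    """Everything one run produces, before serialization."""

    results: pd.DataFrame
    enrichment: pd.DataFrame
    heatmap: pd.DataFrame
    scatter: pd.DataFrame
    clusters: tuple[SeedCluster, ...]
    newick: str
    metadata: dict
    warnings: list[str] = field(default_factory=list)
    gene_set: GeneSet | None = None
    em_result: EMResult | None = None
    candidates: CandidateSet | None = None

    @property
    def status(self) -> str:
        if self.results.empty:
            return "no_candidates"
        if (self.results["flag"] == "HP_ONLY").all():
            return "hp_only"
        return "ok"


_RESULT_COLUMNS = [
    "em_rank", "mirna_id", "em_score", "p_raw", "p_adj",
    "n_overlap", "n_targets", "seed", "cluster_id", "flag",
]


def _enrichment_frame(candidates: CandidateSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "n_targets": r.n_targets,
                "n_overlap": r.n_overlap,
                "n_set": r.n_set,
                "n_universe": r.n_universe,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
            }
            for r in candidates.results
        ],
        columns=[
            "mirna_id", "n_targets", "n_overlap", "n_set", "n_universe",
            "p_raw", "p_adj",
        ],
    )


def _heatmap_frame(
    results: pd.DataFrame, view: CompendiumView, gene_set: GeneSet
) -> pd.DataFrame:
    """Binary miRNA x gene incidence over the reported miRNAs.

    Rows follow the report order (by rank); columns are the overlapping
    genes ordered by their first targeting miRNA, then gene ID.
    """
    mirnas = list(results["mirna_id"])
    in_set = [g for g in gene_set.genes if g in view.universe]
    columns: list[str] = []
    seen: set[str] = set()
    for mirna in mirnas:
        targets = view.targets_of(mirna)
        for gene in sorted(g for g in in_set if g in targets and g not in seen):
            seen.add(gene)
            columns.append(gene)
    data = {
        gene: [int(gene in view.targets_of(m)) for m in mirnas] for gene in columns
    }
    return pd.DataFrame(data, index=pd.Index(mirnas, name="mirna_id"), dtype=int)


def _scatter_frame(results: pd.DataFrame) -> pd.DataFrame:
    scatter = results[["mirna_id", "p_adj", "em_score"]].copy()
    scatter["minus_log10_p_adj"] = scatter["p_adj"].map(
        lambda p: -math.log10(p) if p > 0 else float("inf")
    )
    return scatter[["mirna_id", "minus_log10_p_adj", "em_score"]]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow and return the assembled report.

    Raises :class:`NoGenesMappedError` if no input identifier is
    recognized and :class:`ValidationError` for configuration errors; a
    run in which no miRNA passes the filter returns a report with empty
    results and ``status == "no_candidates"`` rather than raising.
    """
    config.validate()
    if config.output_dir is not None:
        _check_writable(Path(config.output_dir))

    mapping = load_mapping(config.mapping_path)
    raw_lines = read_gene_list(config.gene_list_path)
    gene_set = normalize_gene_list(raw_lines, mapping)

    compendium = load_compendium(dict(config.databases))
    view = build_view(
        compendium,
        selected_dbs=config.selected_dbs,
        min_db_count=config.min_db_count,
        conserved_only=config.conserved_only,
    )

    candidates = select_candidates(
        view, gene_set, threshold=config.p_threshold, use_adjusted=config.use_adjusted
    )
    warnings_list: list[str] = []
    if candidates.warning:
        warnings_list.append(candidates.warning)

    em_result: EMResult | None = None
    n_em_genes = 0
    n_em_excluded = 0
    if not candidates.selected:
        results = pd.DataFrame(columns=_RESULT_COLUMNS)
    elif candidates.single_hit:
        lone = candidates.selected[0]
        results = pd.DataFrame(
            [
                {
                    "em_rank": 1,
                    "mirna_id": lone.mirna_id,
                    "em_score": float("nan"),
                    "p_raw": lone.p_raw,
                    "p_adj": lone.p_adj,
                    "n_overlap": lone.n_overlap,
                    "n_targets": lone.n_targets,
                    "flag": "HP_ONLY",
                }
            ]
        )
        warnings_list.append(
            "exactly one significant miRNA: EM skipped, reported HP-only"
        )
    else:
        problem = build_problem(candidates, view, gene_set)
        n_em_genes = problem.n_genes
        n_em_excluded = len(problem.excluded_genes)
        em_result = run_em(problem, tol=config.em_tol, max_iter=config.em_max_iter)
        if not em_result.converged:
            warnings_list.append(
                f"EM did not converge within {config.em_max_iter} iterations"
            )
        results = rank_mirnas(em_result, candidates)
        results["flag"] = "EM"

    if not results.empty:
        records = [view.mirnas[m] for m in results["mirna_id"]]
        clusters, newick = cluster_seeds(records, config.seed_cluster_cutoff)
        cluster_of = {m: c.cluster_id for c in clusters for m in c.members}
        results["seed"] = [view.mirnas[m].seed for m in results["mirna_id"]]
        results["cluster_id"] = [cluster_of[m] for m in results["mirna_id"]]
        results = results[_RESULT_COLUMNS]
        heatmap = _heatmap_frame(results, view, gene_set)
        scatter = _scatter_frame(results)
    else:
        clusters, newick = (), ""
        heatmap = pd.DataFrame()
        scatter = pd.DataFrame(columns=["mirna_id", "minus_log10_p_adj", "em_score"])

    n_in_universe = candidates.n_set_in_universe
    metadata = {
        "mirem_version": __version__,
        "n_input": gene_set.n_input,
        "n_unmapped": gene_set.n_unmapped,
        "n_duplicates": gene_set.n_duplicates,
        "n_mapped": len(gene_set),
        "n_in_universe": n_in_universe,
        "n_universe": len(view.universe),
        "n_view_pairs": view.n_pairs,
        "n_tested_mirnas": len(candidates.results),
        "n_candidates": len(candidates.selected),
        "single_hit": candidates.single_hit,
        "n_em_genes": n_em_genes,
        "n_em_excluded_genes": n_em_excluded,
        "em_iterations": em_result.n_iterations if em_result else 0,
        "em_converged": em_result.converged if em_result else "",
        "config_gene_list": config.gene_list_path,
        "config_mapping": config.mapping_path,
        "config_databases": ",".join(
            f"{k}={v}" for k, v in sorted(config.databases.items())
        ),
        "config_selected_dbs": ",".join(config.selected_dbs or sorted(config.databases)),
        "config_min_db_count": config.min_db_count,
        "config_conserved_only": config.conserved_only,
        "config_p_threshold": config.p_threshold,
        "config_use_adjusted": config.use_adjusted,
        "config_em_tol": config.em_tol,
        "config_em_max_iter": config.em_max_iter,
        "config_seed_cluster_cutoff": config.seed_cluster_cutoff,
    }
    # stage-count bookkeeping must be monotone down the funnel
    assert gene_set.n_input >= len(gene_set) >= n_in_universe >= n_em_genes

    return RunReport(
        results=results,
        enrichment=_enrichment_frame(candidates),
        heatmap=heatmap,
        scatter=scatter,
        clusters=clusters,
        newick=newick,
        metadata=metadata,
        warnings=warnings_list,
        gene_set=gene_set,
        em_result=em_result,
        candidates=candidates,
    )


def _check_writable(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.write_text("")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"output directory not writable: {out_dir}") from exc
    finally:
        if probe.exists():
            probe.unlink()


def _fmt_p(p: float) -> str:
    return f"{p:.5e}"


def _fmt_score(s: float) -> str:
    return "" if pd.isna(s) else f"{s:.6f}"


def write_outputs(report: RunReport, output_dir: str | Path) -> dict[str, Path]:
    """Serialize the report; byte-identical across reruns on same inputs."""
    out = Path(output_dir)
    _check_writable(out)
    paths: dict[str, Path] = {}

    results = report.results.copy()
    if not results.empty:
        results["em_score"] = results["em_score"].map(_fmt_score)
        results["p_raw"] = results["p_raw"].map(_fmt_p)
        results["p_adj"] = results["p_adj"].map(_fmt_p)
    paths["results"] = out / "results.tsv"
    results.to_csv(paths["results"], sep="\t", index=False, lineterminator="\n")

    enrichment = report.enrichment.copy()
    if not enrichment.empty:
        enrichment["p_raw"] = enrichment["p_raw"].map(_fmt_p)
        enrichment["p_adj"] = enrichment["p_adj"].map(_fmt_p)
    paths["enrichment"] = out / "enrichment.tsv"
    enrichment.to_csv(paths["enrichment"], sep="\t", index=False, lineterminator="\n")

    paths["heatmap"] = out / "heatmap.tsv"
    report.heatmap.to_csv(paths["heatmap"], sep="\t", lineterminator="\n")

    scatter = report.scatter.copy()
    if not scatter.empty:
        scatter["minus_log10_p_adj"] = scatter["minus_log10_p_adj"].map(
            lambda v: f"{v:.6f}"
        )
        scatter["em_score"] = scatter["em_score"].map(_fmt_score)
    paths["scatter"] = out / "scatter.tsv"
    scatter.to_csv(paths["scatter"], sep="\t", index=False, lineterminator="\n")

    paths["newick"] = out / "seeds.nwk"
    paths["newick"].write_text(report.newick + ("\n" if report.newick else ""))

    cluster_rows = [
        {
            "cluster_id": c.cluster_id,
            "mirna_id": m,
            "representative_seed": c.representative_seed,
            "is_duplicate_group": int(c.is_duplicate_group),
        }
        for c in report.clusters
        for m in c.members
    ]
    paths["clusters"] = out / "clusters.tsv"
    pd.DataFrame(
        cluster_rows,
        columns=["cluster_id", "mirna_id", "representative_seed", "is_duplicate_group"],
    ).to_csv(paths["clusters"], sep="\t", index=False, lineterminator="\n")

    meta_lines = [f"{k}={v}" for k, v in report.metadata.items()]
    meta_lines += [f"warning={w}" for w in report.warnings]
    paths["metadata"] = out / "run_metadata.txt"
    paths["metadata"].write_text("\n".join(meta_lines) + "\n")
    return paths
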