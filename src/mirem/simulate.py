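"""Synthetic interaction compendia and spiked gene sets.

The generator emulates the study design used to benchmark the method:
several partially-agreeing target-prediction databases over a common gene
universe, plus a "spiked" gene set built mostly from the targets of one
(or two) chosen miRNAs diluted with background genes — the synthetic
analogue of knock-in / knock-out differential-expression lists.  It is
first-class, tested code: every downstream module can be exercised
without downloading any real database.

Defaults are the benchmark conditions: a universe of 2000 genes, 50
miRNAs with 40 targets each and 20% target sharing, three databases each
emitting a true interaction with probability 0.9, and a gene set of 30
spiked targets plus 20 background genes.  All randomness flows from one
seed through named `numpy` child streams (sequences, targets, databases,
gene set), so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .compendium import InteractionCompendium, MiRNARecord, compendium_from_rows
from .errors import ValidationError

_RNA = np.array(list("ACGU"))
MATURE_LENGTH = 22


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic benchmark condition."""

    n_genes_universe: int = 2000
    n_mirnas: int = 50
    targets_per_mirna: tuple[int, int] = (40, 40)  # inclusive range
    overlap_factor: float = 0.2
    n_databases: int = 3
    db_agreement: float = 0.9
    spiked_mirnas: tuple[int, ...] = (0,)
    n_spiked_targets: int = 30
    n_background_genes: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.targets_per_mirna
        if not (0 < lo <= hi):
            raise ValidationError("targets_per_mirna must be a positive range")
        if hi > self.n_genes_universe:
            raise ValidationError("more targets per miRNA than universe genes")
        for prob, name in ((self.overlap_factor, "overlap_factor"),
                           (self.db_agreement, "db_agreement")):
            if not 0 <= prob <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {prob}")
        if self.n_mirnas < 1 or self.n_databases < 1:
            raise ValidationError("counts must be positive")
        if self.overlap_factor == 0 and self.n_mirnas * hi > self.n_genes_universe:
            raise ValidationError(
                "disjoint target sets (overlap_factor=0) do not fit in the universe"
            )
        for idx in self.spiked_mirnas:
            if not 0 <= idx < self.n_mirnas:
                raise ValidationError(f"spiked miRNA index {idx} out of range")
        if self.n_spiked_targets < 0 or self.n_background_genes < 0:
            raise ValidationError("spike counts must be non-negative")
        if self.n_spiked_targets > lo:
            raise ValidationError(
                "n_spiked_targets exceeds the smallest possible target-set size"
            )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulation: who was spiked, with which targets."""

    spiked_mirna_ids: tuple[str, ...]
    target_sets: Mapping[str, tuple[str, ...]]
    gene_set: tuple[str, ...]


@dataclass(frozen=True)
class Simulation:
    """In-memory simulation output plus writers for the on-disk formats."""

    spec: SimSpec
    mirnas: Mapping[str, MiRNARecord]
    db_frames: Mapping[str, pd.DataFrame]  # mirna_id, mature_sequence, gene_id, conserved
    universe: tuple[str, ...]
    truth: SimTruth

    def compendium(self) -> InteractionCompendium:
        rows = [
            (r.mirna_id, r.gene_id, db, True)
            for db, frame in self.db_frames.items()
            for r in frame.itertuples()
        ]
        return InteractionCompendium(
            interactions=compendium_from_rows(
                rows, self.mirnas, tuple(self.db_frames)
            ).interactions,
            mirnas=dict(self.mirnas),
            databases=tuple(self.db_frames),
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write databases/, mapping.tsv, genes.txt and truth.tsv."""
        out = Path(out_dir)
        (out / "databases").mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for db, frame in self.db_frames.items():
            path = out / "databases" / f"{db}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths[db] = path
        mapping = mapping_table(self.universe)
        paths["mapping"] = out / "mapping.tsv"
        mapping.to_csv(paths["mapping"], sep="\t", index=False)
        paths["genes"] = out / "genes.txt"
        paths["genes"].write_text(
            "".join(_alias_line(g, self.universe) for g in self.truth.gene_set)
        )
        truth_rows = [("spiked", m, "") for m in self.truth.spiked_mirna_ids]
        truth_rows += [
            ("target", m, g)
            for m, genes in self.truth.target_sets.items()
            for g in genes
        ]
        truth_rows += [("gene_set", "", g) for g in self.truth.gene_set]
        paths["truth"] = out / "truth.tsv"
        pd.DataFrame(
            truth_rows, columns=["record_type", "mirna_id", "gene_id"]
        ).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _refseq_alias(gene: str) -> str:
    return f"NM_{int(gene[1:]):06d}"


def _alias_line(gene: str, universe: tuple[str, ...]) -> str:
    # alternate namespaces (and a version suffix) so the gene list
    # exercises identifier normalization end to end
    idx = int(gene[1:])
    if idx % 2:
        return f"{_refseq_alias(gene)}.1\n"
    return f"{gene}\n"


def mapping_table(universe: tuple[str, ...]) -> pd.DataFrame:
    """Identity symbol mapping plus a RefSeq-style alias per gene."""
    rows = [(g, "symbol", g) for g in universe]
    rows += [(_refseq_alias(g), "refseq", g) for g in universe]
    return pd.DataFrame(rows, columns=["source_id", "namespace", "canonical_id"])


def simulate_compendium(
    spec: SimSpec, out_dir: str | Path | None = None
) -> Simulation:
    """Generate miRNAs, target sets and per-database tables.

    Target sets are built sequentially: each target is either drawn from
    the pool of genes already used by earlier miRNAs (probability
    ``overlap_factor``) or taken fresh from the unused pool, so
    ``overlap_factor=0`` yields pairwise-disjoint sets.  Each true
    (miRNA, gene) pair is then emitted independently by each database
    with probability ``db_agreement``.
    """
    seq_rng, target_rng, db_rng, set_rng = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(spec.rng_seed).spawn(4)
    )
    universe = tuple(_gene_name(i) for i in range(spec.n_genes_universe))

    mirnas: dict[str, MiRNARecord] = {}
    for j in range(spec.n_mirnas):
        seq = "".join(seq_rng.choice(_RNA, size=MATURE_LENGTH))
        mid = f"sim-miR-{j + 1:03d}"
        mirnas[mid] = MiRNARecord(mirna_id=mid, mature_sequence=seq, conserved=True)

    lo, hi = spec.targets_per_mirna
    unused = list(universe)
    used: list[str] = []
    target_sets: dict[str, tuple[str, ...]] = {}
    for mid in mirnas:
        n_targets = int(target_rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        attempts = 0
        while len(chosen) < n_targets:
            attempts += 1
            take_used = used and target_rng.random() < spec.overlap_factor
            if take_used and attempts < 50 * n_targets:
                gene = used[int(target_rng.integers(len(used)))]
                if gene in chosen:
                    continue
            else:
                if not unused:
                    raise ValidationError("universe exhausted while sampling targets")
                gene = unused.pop(int(target_rng.integers(len(unused))))
            chosen.add(gene)
        ordered = tuple(sorted(chosen))
        target_sets[mid] = ordered
        used.extend(g for g in ordered if g not in used)

    db_frames: dict[str, pd.DataFrame] = {}
    pair_rows = [
        (mid, mirnas[mid].mature_sequence, gene)
        for mid in mirnas
        for gene in target_sets[mid]
    ]
    for d in range(spec.n_databases):
        mask = db_rng.random(len(pair_rows)) < spec.db_agreement
        kept = [row for row, keep in zip(pair_rows, mask) if keep]
        db_frames[f"db{d + 1}"] = pd.DataFrame(
            [(m, s, g, 1) for m, s, g in kept],
            columns=["mirna_id", "mature_sequence", "gene_id", "conserved"],
        )

    spiked_ids = tuple(f"sim-miR-{j + 1:03d}" for j in spec.spiked_mirnas)
    gene_set: list[str] = []
    seen: set[str] = set()
    all_spiked_targets: set[str] = set()
    for mid in spiked_ids:
        all_spiked_targets.update(target_sets[mid])
    for mid in spiked_ids:
        pool = np.array(target_sets[mid])
        picked = set_rng.choice(pool, size=min(spec.n_spiked_targets, len(pool)),
                                replace=False)
        for gene in sorted(picked):
            if gene not in seen:
                seen.add(gene)
                gene_set.append(gene)
    background_pool = np.array(
        [g for g in universe if g not in all_spiked_targets]
    )
    if spec.n_background_genes > len(background_pool):
        raise ValidationError("background request exceeds the non-target pool")
    if spec.n_background_genes:
        background = set_rng.choice(
            background_pool, size=spec.n_background_genes, replace=False
        )
        for gene in sorted(background):
            if gene not in seen:
                seen.add(gene)
                gene_set.append(gene)

    sim = Simulation(
        spec=spec,
        mirnas=mirnas,
        db_frames=db_frames,
        universe=universe,
        truth=SimTruth(
            spiked_mirna_ids=spiked_ids,
            target_sets=target_sets,
            gene_set=tuple(gene_set),
        ),
    )
    if out_dir is not None:
        sim.write(out_dir)
    return sim


def simulate_spiked_gene_set(
    spec: SimSpec, sim: Simulation, out_path: str | Path
) -> Path:
    """Write the spiked gene list (one identifier per line) to a file."""
    out_path = Path(out_path)
    out_path.write_text(
        "".join(_alias_line(g, sim.universe) for g in sim.truth.gene_set)
    )
    return out_path


@dataclass(frozen=True)
class ReplicateOutcome:
    """Ranking outcome of one simulated replicate under a given config."""

    ranks: dict[str, int | None]  # spiked miRNA -> EM rank (None if unranked)
    n_candidates: int
    min_p_adj: float
    single_hit: bool

    def recovered_at(self, top: int) -> bool:
        """True iff every spiked miRNA ranks within the top ``top``."""
        return all(r is not None and r <= top for r in self.ranks.values())


def evaluate_replicate(
    spec: SimSpec,
    min_db_count: int = 3,
    conserved_only: bool = True,
    p_threshold: float = 0.01,
    use_adjusted: bool = True,
    em_tol: float = 1e-3,
    em_max_iter: int = 1000,
) -> ReplicateOutcome:
    """Simulate one compendium + gene set and rank the spiked miRNAs.

    Runs the full analysis in memory (view construction, enrichment
    filtering, EM or the single-survivor short-circuit) under the given
    configuration, which defaults to the benchmark settings.
    """
    from .em import build_problem, run_em
    from .enrichment import select_candidates
    from .compendium import build_view
    from .id_mapping import GeneSet

    sim = simulate_compendium(spec)
    view = build_view(
        sim.compendium(), min_db_count=min_db_count, conserved_only=conserved_only
    )
    genes = sim.truth.gene_set
    gene_set = GeneSet(genes=genes, n_input=len(genes), n_unmapped=0, n_duplicates=0)
    try:
        candidates = select_candidates(
            view, gene_set, threshold=p_threshold, use_adjusted=use_adjusted
        )
    except ValidationError:
        return ReplicateOutcome(
            ranks={m: None for m in sim.truth.spiked_mirna_ids},
            n_candidates=0,
            min_p_adj=float("nan"),
            single_hit=False,
        )
    min_p_adj = (
        min(r.p_adj for r in candidates.results)
        if candidates.results
        else float("nan")
    )
    spiked = sim.truth.spiked_mirna_ids
    if not candidates.selected:
        ranks: dict[str, int | None] = {m: None for m in spiked}
    elif candidates.single_hit:
        lone = candidates.selected_ids[0]
        ranks = {m: (1 if m == lone else None) for m in spiked}
    else:
        problem = build_problem(candidates, view, gene_set)
        result = run_em(problem, tol=em_tol, max_iter=em_max_iter)
        ranks = {m: result.ranks.get(m) for m in spiked}
    return ReplicateOutcome(
        ranks=ranks,
        n_candidates=len(candidates.selected),
        min_p_adj=min_p_adj,
        single_hit=candidates.single_hit,
    )


def recovery_rate(
    base_spec: SimSpec, n_replicates: int, top: int = 1, seed_offset: int = 0, **config
) -> float:
    """Fraction of replicates in which every spiked miRNA ranks in the top."""
    hits = 0
    for r in range(n_replicates):
        spec = replace(base_spec, rng_seed=(base_spec.rng_seed + seed_offset + r) % (2**31))
        if evaluate_replicate(spec, **config).recovered_at(top):
            hits += 1
    return hits / n_replicates
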