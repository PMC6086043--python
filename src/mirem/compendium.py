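"""Multi-database miRNA-target interaction compendium.

Target-prediction databases (TargetScan, miRanda, PITA, ...) disagree
substantially, so the compendium keeps per-database provenance for every
predicted (miRNA, gene) pair and lets the caller choose how much
cross-database support to demand: the plain union (``min_db_count=1``) up
to the intersection of all selected databases.  Databases that annotate
evolutionary conservation can additionally be restricted to conserved
interactions.  The selected view materializes the binary incidence
relation Y (gene x miRNA) consumed by enrichment and by the EM core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

_RNA_ALPHABET = frozenset("ACGU")

#: seed region = nucleotides 2-7 of the mature strand (0-based slice 1:7)
SEED_SLICE = slice(1, 7)
SEED_LENGTH = 6


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA: identifier, sequence, derived seed, conservation.

    The seed region (nucleotides 2-7 of the mature strand) is the primary
    determinant of targeting, hence of prediction overlap between miRNAs.
    """

    mirna_id: str
    mature_sequence: str
    conserved: bool = True

    def __post_init__(self) -> None:
        seq = self.mature_sequence
        if len(seq) < 7:
            raise ValidationError(
                f"{self.mirna_id}: mature sequence must be >= 7 nt, "
                f"got {len(seq)}"
            )
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.mirna_id}: invalid sequence characters "
                f"{''.join(sorted(bad))!r} (alphabet A/C/G/U)"
            )

    @property
    def seed(self) -> str:
        """The 6-nt seed: positions 2-7 (1-based) of the mature sequence."""
        return self.mature_sequence[SEED_SLICE]


def normalize_rna(sequence: str, context: str = "") -> str:
    """Upper-case a sequence and transcribe T to U; reject anything else."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ParseError(
            f"{context}invalid sequence characters {''.join(sorted(bad))!r} "
            "(expected A/C/G/U/T)"
        )
    return seq


_COLUMNS = ("mirna_id", "gene_id", "source_db", "conserved")


@dataclass(frozen=True)
class InteractionCompendium:
    """Deduplicated (miRNA, gene, database) triples plus the miRNA records."""

    interactions: pd.DataFrame  # columns: mirna_id, gene_id, source_db, conserved
    mirnas: Mapping[str, MiRNARecord]
    databases: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = set(self.interactions["mirna_id"]) - set(self.mirnas)
        if missing:
            raise ValidationError(
                f"interactions reference unknown miRNAs: {sorted(missing)[:5]}"
            )

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def merge(self, other: "InteractionCompendium") -> "InteractionCompendium":
        """Combine two compendia; conflicting mature sequences are an error."""
        for mid, rec in other.mirnas.items():
            mine = self.mirnas.get(mid)
            if mine is not None and mine.mature_sequence != rec.mature_sequence:
                raise ValidationError(
                    f"conflicting mature sequences for {mid}: "
                    f"{mine.mature_sequence} vs {rec.mature_sequence}"
                )
        mirnas = dict(self.mirnas)
        mirnas.update(other.mirnas)
        frames = [self.interactions, other.interactions]
        merged = _dedupe(pd.concat(frames, ignore_index=True))
        return InteractionCompendium(
            interactions=merged,
            mirnas=mirnas,
            databases=tuple(dict.fromkeys(self.databases + other.databases)),
        )


def _dedupe(df: pd.DataFrame) -> pd.DataFrame:
    # one (miRNA, gene, db) triple per row; a pair flagged conserved anywhere
    # in a database stays conserved there
    out = (
        df.groupby(["mirna_id", "gene_id", "source_db"], as_index=False)["conserved"]
        .max()
        .sort_values(["source_db", "mirna_id", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )
    return out[list(_COLUMNS)]


def compendium_from_rows(
    rows: Iterable[tuple[str, str, str, bool]],
    mirnas: Mapping[str, MiRNARecord],
    databases: Sequence[str],
) -> InteractionCompendium:
    """Build a compendium from in-memory (mirna, gene, db, conserved) rows."""
    df = pd.DataFrame(list(rows), columns=list(_COLUMNS))
    df["conserved"] = df["conserved"].astype(bool)
    return InteractionCompendium(
        interactions=_dedupe(df), mirnas=dict(mirnas), databases=tuple(databases)
    )


def load_database(path: str | Path, db_name: str) -> InteractionCompendium:
    """Load one database TSV (mirna_id, mature_sequence, gene_id, conserved).

    The header row is optional (detected by a non-0/1 conserved field).
    T is transcribed to U; sequences shorter than 7 nt and conflicting
    sequences for one miRNA ID are rejected.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, bool]] = []
    mirnas: dict[str, MiRNARecord] = {}
    conserved_any: dict[str, bool] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 tab-separated "
                    f"columns, found {len(fields)}"
                )
            mirna_id, seq_raw, gene_id, conserved_raw = (f.strip() for f in fields)
            if conserved_raw not in {"0", "1"}:
                if lineno == 1:
                    continue  # header row
                raise ParseError(
                    f"{path}: line {lineno}: conserved flag must be 0 or 1, "
                    f"got {conserved_raw!r}"
                )
            seq = normalize_rna(seq_raw, context=f"{path}: line {lineno}: ")
            if len(seq) < 7:
                raise ValidationError(
                    f"{path}: line {lineno}: mature sequence must be >= 7 nt, "
                    f"got {len(seq)}"
                )
            conserved = conserved_raw == "1"
            known = mirnas.get(mirna_id)
            if known is not None and known.mature_sequence != seq:
                raise ValidationError(
                    f"{path}: line {lineno}: conflicting mature sequences for "
                    f"{mirna_id}: {known.mature_sequence} vs {seq}"
                )
            if known is None:
                mirnas[mirna_id] = MiRNARecord(mirna_id, seq, conserved)
                conserved_any[mirna_id] = conserved
            elif conserved and not conserved_any[mirna_id]:
                mirnas[mirna_id] = MiRNARecord(mirna_id, seq, True)
                conserved_any[mirna_id] = True
            rows.append((mirna_id, gene_id.upper(), db_name, conserved))
    return compendium_from_rows(rows, mirnas, (db_name,))


def load_compendium(db_paths: Mapping[str, str | Path]) -> InteractionCompendium:
    """Load and merge several database files (name -> path)."""
    if not db_paths:
        raise ValidationError("no databases configured")
    compendium: InteractionCompendium | None = None
    for name, path in db_paths.items():
        part = load_database(path, name)
        compendium = part if compendium is None else compendium.merge(part)
    assert compendium is not None
    return compendium


@dataclass(frozen=True)
class Selection:
    """Echo of the view-building parameters, for metadata/reproducibility."""

    databases: tuple[str, ...]
    min_db_count: int
    conserved_only: bool


@dataclass(frozen=True)
class CompendiumView:
    """The observed prediction relation Y under one database selection.

    ``pairs`` holds the surviving (miRNA, gene) pairs; the gene universe is
    exactly the genes with at least one surviving interaction, which is
    also the enrichment background.
    """

    pairs: pd.DataFrame  # columns: mirna_id, gene_id
    mirnas: Mapping[str, MiRNARecord]
    selection: Selection

    @cached_property
    def targets(self) -> dict[str, frozenset[str]]:
        """Map miRNA ID -> set of surviving target genes."""
        grouped = self.pairs.groupby("mirna_id")["gene_id"]
        return {mid: frozenset(genes) for mid, genes in grouped}

    @cached_property
    def universe(self) -> frozenset[str]:
        return frozenset(self.pairs["gene_id"])

    @cached_property
    def candidate_mirnas(self) -> frozenset[str]:
        return frozenset(self.pairs["mirna_id"])

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def targets_of(self, mirna_id: str) -> frozenset[str]:
        return self.targets.get(mirna_id, frozenset())


def build_view(
    compendium: InteractionCompendium,
    selected_dbs: Sequence[str] | None = None,
    min_db_count: int = 1,
    conserved_only: bool = False,
) -> CompendiumView:
    """Materialize the user-selected view of the compendium.

    A (miRNA, gene) pair survives iff it appears in at least
    ``min_db_count`` distinct selected databases; with ``conserved_only``
    the count only considers interactions flagged conserved (databases
    without conservation annotation load everything as conserved, so they
    are unaffected).  ``min_db_count=1`` is the plain union.
    """
    selected = tuple(selected_dbs) if selected_dbs is not None else compendium.databases
    if not selected:
        raise ValidationError("selected_dbs must be non-empty")
    unknown = set(selected) - set(compendium.databases)
    if unknown:
        raise ValidationError(f"unknown databases selected: {sorted(unknown)}")
    if not 1 <= min_db_count <= len(selected):
        raise ValidationError(
            f"min_db_count must be in [1, {len(selected)}], got {min_db_count}"
        )
    df = compendium.interactions
    df = df[df["source_db"].isin(selected)]
    if conserved_only:
        df = df[df["conserved"]]
    counts = df.groupby(["mirna_id", "gene_id"])["source_db"].nunique()
    survivors = counts[counts >= min_db_count].index
    pairs = (
        pd.DataFrame(survivors.tolist(), columns=["mirna_id", "gene_id"])
        if len(survivors)
        else pd.DataFrame(columns=["mirna_id", "gene_id"])
    )
    pairs = pairs.sort_values(["mirna_id", "gene_id"], kind="stable").reset_index(
        drop=True
    )
    return CompendiumView(
        pairs=pairs,
        mirnas=compendium.mirnas,
        selection=Selection(
            databases=tuple(sorted(selected)),
            min_db_count=min_db_count,
            conserved_only=conserved_only,
        ),
    )
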