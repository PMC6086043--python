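"""Gene identifier unification.

Input gene lists mix RefSeq / Ensembl / UCSC transcript identifiers and
official gene symbols, often with version suffixes (``NM_000546.5``).  All
of them are collapsed onto one canonical gene key through a local lookup
table so that downstream enrichment counts are done at gene level.  The
mapping table is an ordinary three-column TSV (``source_id``,
``namespace``, ``canonical_id``); no network lookup is ever performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import NoGenesMappedError, ParseError, ValidationError

#: Recognized identifier namespaces, in lookup-priority order.  When one
#: raw identifier matches several namespaces the highest-priority hit wins,
#: keeping normalization deterministic.
NAMESPACES: tuple[str, ...] = ("refseq", "ensembl", "ucsc", "symbol")

# Accession prefixes that carry dot-separated version suffixes worth
# stripping before lookup (RefSeq NM_/NR_/XM_/XR_/NP_ and Ensembl ENS*).
_VERSIONED_PREFIX = re.compile(r"^(NM_|NR_|XM_|XR_|NP_|ENS)", re.IGNORECASE)
_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_version(identifier: str) -> str:
    """Drop a trailing ``.N`` version from RefSeq/Ensembl-like accessions.

    Symbols and UCSC names are returned unchanged: a dot there is part of
    the name, not a version.
    """
    if _VERSIONED_PREFIX.match(identifier):
        return _VERSION_SUFFIX.sub("", identifier)
    return identifier


@dataclass(frozen=True)
class IdMappingTable:
    """Immutable lookup from (namespace, source id) to a canonical gene key.

    Canonical identifiers are case-normalized to upper case.  Canonical IDs
    themselves always resolve (to themselves), which makes
    :func:`normalize_gene_list` idempotent.
    """

    lookup: Mapping[tuple[str, str], str]
    canonical_ids: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.lookup)

    def get(self, identifier: str) -> str | None:
        """Resolve one raw identifier to its canonical gene key, or None.

        Tries the identifier verbatim and version-stripped against every
        namespace (priority order of :data:`NAMESPACES`), then falls back
        to direct canonical-ID membership.
        """
        raw = identifier.strip()
        if not raw:
            return None
        candidates = [raw.lower()]
        stripped = strip_version(raw).lower()
        if stripped != candidates[0]:
            candidates.append(stripped)
        for key in candidates:
            for ns in NAMESPACES:
                hit = self.lookup.get((ns, key))
                if hit is not None:
                    return hit
        for key in candidates:
            upper = key.upper()
            if upper in self.canonical_ids:
                return upper
        return None


@dataclass(frozen=True)
class GeneSet:
    """A normalized, de-duplicated gene list with bookkeeping counts.

    ``n_input`` counts every non-blank, non-comment input line and always
    equals ``len(genes) + n_unmapped + n_duplicates``.
    """

    genes: tuple[str, ...]
    n_input: int
    n_unmapped: int
    n_duplicates: int
    unmapped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("GeneSet.genes contains duplicates")
        if self.n_input != len(self.genes) + self.n_unmapped + self.n_duplicates:
            raise ValidationError(
                "GeneSet bookkeeping broken: n_input != |genes| + n_unmapped "
                "+ n_duplicates"
            )

    def __len__(self) -> int:
        return len(self.genes)


def load_mapping(path: str | Path) -> IdMappingTable:
    """Read a three-column mapping TSV into an :class:`IdMappingTable`.

    The header row is optional and auto-detected: a first row whose second
    column is not a known namespace is treated as a header.  Exact
    duplicate rows are dropped; two rows that map the same
    (source_id, namespace) pair to different canonical IDs raise a
    :class:`ValidationError` naming the conflict.
    """
    path = Path(path)
    lookup: dict[tuple[str, str], str] = {}
    canonical: set[str] = set()
    conflicts: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated "
                    f"columns, found {len(fields)}"
                )
            source_id, namespace, canonical_id = (f.strip() for f in fields)
            namespace = namespace.lower()
            if namespace not in NAMESPACES:
                if lineno == 1:
                    continue  # header row
                raise ParseError(
                    f"{path}: line {lineno}: unknown namespace "
                    f"{namespace!r} (expected one of {', '.join(NAMESPACES)})"
                )
            if not canonical_id:
                raise ValidationError(
                    f"{path}: line {lineno}: empty canonical_id"
                )
            key = (namespace, source_id.lower())
            value = canonical_id.upper()
            previous = lookup.get(key)
            if previous is not None and previous != value:
                conflicts.append(
                    f"({source_id}, {namespace}) -> {previous} vs {value}"
                )
                continue
            lookup[key] = value
            canonical.add(value)
    if conflicts:
        raise ValidationError(
            "conflicting duplicate mappings: " + "; ".join(sorted(conflicts))
        )
    return IdMappingTable(lookup=lookup, canonical_ids=frozenset(canonical))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a gene-list file: one identifier per line, ``#`` comments ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]


def normalize_gene_list(
    raw_lines: Sequence[str] | Iterable[str], mapping: IdMappingTable
) -> GeneSet:
    """Map raw identifiers onto canonical gene keys.

    Matching is case-insensitive, version-stripped, and tried against all
    namespaces (fixed priority).  Canonical hits are de-duplicated keeping
    first-seen order; unmapped identifiers are counted and returned, never
    silently dropped.  If *no* identifier maps, a
    :class:`NoGenesMappedError` is raised.
    """
    raw = [ln.strip() for ln in raw_lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not raw:
        raise ValidationError("gene list is empty after removing blanks/comments")
    genes: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    n_duplicates = 0
    for identifier in raw:
        canonical = mapping.get(identifier)
        if canonical is None:
            unmapped.append(identifier)
        elif canonical in seen:
            n_duplicates += 1
        else:
            seen.add(canonical)
            genes.append(canonical)
    if not genes:
        raise NoGenesMappedError("no genes recognized")
    return GeneSet(
        genes=tuple(genes),
        n_input=len(raw),
        n_unmapped=len(unmapped),
        n_duplicates=n_duplicates,
        unmapped=tuple(unmapped),
    )
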