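"""Seed-region clustering of predicted miRNAs.

miRNAs sharing a seed (nucleotides 2-7 of the mature strand) target
near-identical gene sets and are therefore co-predicted; flagging such
duplicated predictions is essential when interpreting a ranked list.
Seeds are fixed-length 6-mers, so no multiple alignment is needed:
pairwise Hamming distance feeds average-linkage (UPGMA) hierarchical
clustering, and cutting the tree at height 0 recovers exactly the groups
of identical seeds.  The dendrogram is serialized as Newick with
ultrametric branch lengths (merge height / 2).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .compendium import SEED_LENGTH, MiRNARecord
from .errors import ValidationError

_RNA_ALPHABET = frozenset("ACGU")


def seed_distance(seed_a: str, seed_b: str) -> int:
    """Hamming distance (number of mismatching positions) between 6-mers."""
    for seed in (seed_a, seed_b):
        if len(seed) != SEED_LENGTH:
            raise ValidationError(
                f"seed must be exactly {SEED_LENGTH} nt, got {seed!r}"
            )
        bad = set(seed) - _RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"seed {seed!r} has characters outside A/C/G/U"
            )
    return sum(a != b for a, b in zip(seed_a, seed_b))


@dataclass(frozen=True)
class SeedDistanceMatrix:
    """Symmetric pairwise seed-distance matrix (units: mismatches, 0-6)."""

    mirna_ids: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D)
        n = len(self.mirna_ids)
        if D.shape != (n, n) or not np.array_equal(D, D.T) or np.diag(D).any():
            raise ValidationError("D must be symmetric with a zero diagonal")


@dataclass(frozen=True)
class SeedCluster:
    cluster_id: int
    members: tuple[str, ...]
    representative_seed: str
    is_duplicate_group: bool


def _consensus_seed(seeds: Sequence[str]) -> str:
    """Per-position majority base; ties resolved lexicographically."""
    out = []
    for position in zip(*seeds):
        counts: dict[str, int] = {}
        for base in position:
            counts[base] = counts.get(base, 0) + 1
        best = min(counts, key=lambda b: (-counts[b], b))
        out.append(best)
    return "".join(out)


def _linkage_to_newick(link: np.ndarray, ids: Sequence[str]) -> str:
    """Serialize a scipy linkage as ultrametric Newick (heights halved)."""
    root = to_tree(link)

    def clade(node, parent_height: float) -> Clade:
        height = 0.0 if node.is_leaf() else node.dist / 2.0
        cl = Clade(branch_length=parent_height - height)
        if node.is_leaf():
            cl.name = ids[node.id]
        else:
            cl.clades = [clade(node.left, height), clade(node.right, height)]
        return cl

    root_height = root.dist / 2.0
    top = Clade(branch_length=0.0)
    if root.is_leaf():
        top.name = ids[root.id]
    else:
        top.clades = [clade(root.left, root_height), clade(root.right, root_height)]
    buf = io.StringIO()
    Phylo.write(Tree(root=top), buf, "newick", format_branch_length="%.4g")
    return buf.getvalue().strip()


class SeedClusterer(BaseEstimator):
    """UPGMA clustering of miRNA seeds at a Hamming-distance cutoff.

    Parameters
    ----------
    cutoff : float, default 0
        Tree-cut height in mismatches.  0 groups only identical seeds
        (duplicate detection); larger values merge similar seeds.

    Attributes
    ----------
    mirna_ids_ : tuple of str (lexicographically sorted, the leaf order)
    seeds_ : dict mapping miRNA ID -> 6-mer seed
    distance_matrix_ : SeedDistanceMatrix
    labels_ : ndarray of cluster labels aligned with ``mirna_ids_``
    clusters_ : tuple of SeedCluster (ordered by smallest member ID)
    newick_ : str, the serialized dendrogram
    """

    def __init__(self, cutoff: float = 0):
        self.cutoff = cutoff

    def fit(self, records: Sequence[MiRNARecord], y=None) -> "SeedClusterer":
        if self.cutoff < 0:
            raise ValidationError(f"cutoff must be >= 0, got {self.cutoff}")
        if not records:
            raise ValidationError("need at least one miRNA record to cluster")
        by_id = {r.mirna_id: r for r in records}
        if len(by_id) != len(records):
            raise ValidationError("duplicate miRNA IDs in prediction list")
        # lexicographic ID order fixes leaf order and hence tie-breaking
        ids = tuple(sorted(by_id))
        seeds = {m: by_id[m].seed for m in ids}
        n = len(ids)
        codes = np.frombuffer(
            "".join(seeds[m] for m in ids).encode(), dtype="S1"
        ).reshape(n, SEED_LENGTH)
        D = (codes[:, None, :] != codes[None, :, :]).sum(axis=2).astype(float)
        self.mirna_ids_ = ids
        self.seeds_ = seeds
        self.distance_matrix_ = SeedDistanceMatrix(mirna_ids=ids, D=D)
        if n == 1:
            labels = np.array([1])
            self.newick_ = f"{ids[0]}:0;"
        else:
            condensed = D[np.triu_indices(n, k=1)]
            link = linkage(condensed, method="average")
            labels = fcluster(link, t=self.cutoff, criterion="distance")
            self.newick_ = _linkage_to_newick(link, ids)
        self.labels_ = labels
        groups: dict[int, list[str]] = {}
        for mirna_id, label in zip(ids, labels):
            groups.setdefault(int(label), []).append(mirna_id)
        ordered = sorted(groups.values(), key=lambda members: members[0])
        clusters = []
        for idx, members in enumerate(ordered, start=1):
            member_seeds = [seeds[m] for m in members]
            clusters.append(
                SeedCluster(
                    cluster_id=idx,
                    members=tuple(members),
                    representative_seed=_consensus_seed(member_seeds),
                    is_duplicate_group=(
                        len(members) >= 2 and len(set(member_seeds)) == 1
                    ),
                )
            )
        self.clusters_ = tuple(clusters)
        return self

    def fit_predict(self, records: Sequence[MiRNARecord], y=None) -> np.ndarray:
        return self.fit(records).labels_

    @property
    def cluster_of_(self) -> dict[str, int]:
        check_is_fitted(self, "clusters_")
        return {m: c.cluster_id for c in self.clusters_ for m in c.members}


def cluster_seeds(
    predictions: Sequence[MiRNARecord], linkage_cutoff: float = 0
) -> tuple[tuple[SeedCluster, ...], str]:
    """Cluster predicted miRNAs by seed; returns (clusters, Newick tree)."""
    clusterer = SeedClusterer(cutoff=linkage_cutoff).fit(predictions)
    return clusterer.clusters_, clusterer.newick_
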