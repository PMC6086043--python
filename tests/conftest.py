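import numpy as np
import pytest

from mirem.compendium import MiRNARecord, compendium_from_rows


def make_compendium(db_targets, sequences=None, conserved=None):
    """Build a compendium from {db: {mirna: [genes]}} with synthetic sequences.

    ``sequences`` optionally maps miRNA ID -> mature sequence; ``conserved``
    optionally maps (mirna, gene, db) -> bool (default True).
    """
    sequences = sequences or {}
    conserved = conserved or {}
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGU"))
    mirnas = {}
    rows = []
    for db, targets in db_targets.items():
        for mirna, genes in targets.items():
            if mirna not in mirnas:
                seq = sequences.get(
                    mirna, "".join(rng.choice(bases, size=22))
                )
                mirnas[mirna] = MiRNARecord(mirna, seq, True)
            for gene in genes:
                rows.append(
                    (mirna, gene, db, conserved.get((mirna, gene, db), True))
                )
    return compendium_from_rows(rows, mirnas, tuple(db_targets))


@pytest.fixture
def mapping_file(tmp_path):
    path = tmp_path / "mapping.tsv"
    path.write_text(
        "source_id\tnamespace\tcanonical_id\n"
        "NM_000546\trefseq\tTP53\n"
        "ENSG00000141510\tensembl\tTP53\n"
        "uc002gig.2\tucsc\tTP53\n"
        "TP53\tsymbol\tTP53\n"
        "NM_005228\trefseq\tEGFR\n"
        "EGFR\tsymbol\tEGFR\n"
    )
    return path


def random_incidence(rng, n_genes, n_mirnas):
    """Random binary Y with no all-zero row or column."""
    while True:
        Y = (rng.random((n_genes, n_mirnas)) < rng.uniform(0.2, 0.7)).astype(float)
        if Y.sum(axis=1).min() > 0 and Y.sum(axis=0).min() > 0:
            return Y
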