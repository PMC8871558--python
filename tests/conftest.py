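import numpy as np
import pytest

from csiscan.alignment_io import AMINO_ACIDS, CladePartition, ProteinAlignment, \
    load_default_partition


@pytest.fixture(scope="session")
def glires_partition() -> CladePartition:
    return load_default_partition()


@pytest.fixture
def toy_partition() -> CladePartition:
    """12 taxa: clades A (4), B (4), nested B1 (2 inside B), 2 free taxa
    (f1, f2) and 2 outgroups."""
    taxa = {f"a{i}" for i in range(4)} | {f"b{i}" for i in range(4)} | \
        {"f1", "f2", "og1", "og2"}
    return CladePartition(
        taxa=set(taxa),
        levels={
            "group": {**{f"a{i}": "A" for i in range(4)},
                      **{f"b{i}": "B" for i in range(4)}},
            "subgroup": {"b0": "B1", "b1": "B1"},
        },
        outgroups={"og1", "og2"},
        candidate_clades=[("group", "A"), ("group", "B"), ("subgroup", "B1")],
    )


def random_alignment(rng: np.random.Generator, n_taxa: int, n_cols: int,
                     gap_prob: float = 0.15, aln_id: str = "rand"
                     ) -> ProteinAlignment:
    """Random gapped alignment; all-gap columns repaired so the container
    invariant holds."""
    aa = np.array(list(AMINO_ACIDS))
    chars = aa[rng.integers(0, 20, size=(n_taxa, n_cols))]
    gaps = rng.random((n_taxa, n_cols)) < gap_prob
    for j in range(n_cols):
        if gaps[:, j].all():
            gaps[rng.integers(0, n_taxa), j] = False
    chars[gaps] = "-"
    taxa = [f"t{i}" for i in range(n_taxa)]
    return ProteinAlignment(id=aln_id, taxa=taxa,
                            rows={t: "".join(chars[i]) for i, t in enumerate(taxa)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220288)
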