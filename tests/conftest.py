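import numpy as np
import pytest

from mirprop.io_formats import (
    EdgeList,
    FamilyRecord,
    GeneScoreEntry,
    GeneScoreList,
    TargetTable,
)


@pytest.fixture
def chain_edges() -> EdgeList:
    """A → B → C regulation chain."""
    return EdgeList(edges=(("A", "B"), ("B", "C")))


@pytest.fixture
def toy_scores() -> GeneScoreList:
    """Two scored genes with log-reliabilities 2 and 1."""
    return GeneScoreList(
        entries=(
            GeneScoreEntry("g1", float(np.e) ** 2, 2.0),
            GeneScoreEntry("g4", float(np.e), 1.0),
        )
    )


@pytest.fixture
def toy_targets() -> TargetTable:
    return TargetTable(
        records=(
            FamilyRecord("famA", ("miR-a1", "miR-a2"), 2.5, frozenset({"A", "B"})),
            FamilyRecord("famB", ("miR-b1",), 3.0, frozenset({"C"})),
        )
    )


def random_digraph(rng: np.random.Generator, n_genes: int, n_edges: int) -> EdgeList:
    """Random directed graph without self-loops, for oracle comparisons."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    edges = set()
    while len(edges) < n_edges:
        s, t = rng.integers(0, n_genes, 2)
        if s != t:
            edges.add((genes[s], genes[t]))
    return EdgeList(edges=tuple(sorted(edges)))


def random_score_list(
    rng: np.random.Generator, universe: list[str], n_scored: int
) -> GeneScoreList:
    hit = rng.choice(len(universe), n_scored, replace=False)
    logs = rng.normal(1.0, 1.0, n_scored)
    return GeneScoreList(
        entries=tuple(
            GeneScoreEntry(universe[j], float(np.exp(w)), float(w))
            for j, w in zip(hit, logs)
        )
    )
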