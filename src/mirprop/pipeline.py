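"""End-to-end screen: propagate → NPES → DE filter → intersect.

`run_screen` wires the stages together for arbitrary inputs; `run_synthetic`
generates a full synthetic study from one config and screens it, returning
the planted truth alongside the results so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diffexpr import DifferentialRecord, de_mirna_set, fold_changes, median_normalize
from .enrichment import EnrichmentResult, screen_families
from .integrate import CandidateRecord, RunSummary, intersect, summarize
from .io_formats import (
    EdgeList,
    ExpressionMatrix,
    GeneScoreList,
    TargetTable,
)
from .netprop import PropagationParams, PropagationResult, propagate_all
from .synthetic_data import SyntheticConfig, generate_all


@dataclass
class ScreenOutput:
    propagation: list[PropagationResult]
    enrichment: list[EnrichmentResult]
    de_records: list[DifferentialRecord]
    candidates: list[CandidateRecord]
    summary: RunSummary


def build_gene_universe(
    targets: TargetTable, edges: EdgeList, scores: GeneScoreList
) -> list[str]:
    """Sorted union of network nodes, family targets and scored genes."""
    universe = edges.node_ids()
    for rec in targets:
        universe |= rec.target_gene_ids
    universe |= {e.gene_id for e in scores.entries}
    return sorted(universe)


def run_screen(
    targets: TargetTable,
    edges: EdgeList,
    scores: GeneScoreList,
    matrix: ExpressionMatrix,
    *,
    gene_universe: list[str] | None = None,
    params: PropagationParams = PropagationParams(),
    n_permutations: int = 1000,
    fdr_threshold: float = 0.05,
    up_threshold: float = 1.25,
    down_threshold: float = 0.75,
    rng_seed: int = 0,
) -> ScreenOutput:
    """The full computational screen on already-loaded inputs."""
    if gene_universe is None:
        gene_universe = build_gene_universe(targets, edges, scores)
    propagation = propagate_all(targets, edges, gene_universe, params)
    enrichment = screen_families(
        propagation,
        scores,
        gene_universe,
        n_permutations=n_permutations,
        fdr_threshold=fdr_threshold,
        rng_seed=rng_seed,
    )
    normalized = median_normalize(matrix)
    de_records = fold_changes(
        normalized, up_threshold=up_threshold, down_threshold=down_threshold
    )
    candidates = intersect(enrichment, de_records, targets.family_map())
    return ScreenOutput(
        propagation=propagation,
        enrichment=enrichment,
        de_records=de_records,
        candidates=candidates,
        summary=summarize(enrichment, de_records, candidates),
    )


@dataclass
class SyntheticScreenOutput:
    screen: ScreenOutput
    planted_families: list[str]
    planted_mirnas: dict[str, float]

    def planted_family_significant(self) -> bool:
        flagged = {r.family_id for r in self.screen.enrichment if r.significant}
        return all(f in flagged for f in self.planted_families)

    def planted_mirnas_in_candidates(self) -> bool:
        """Did every planted member of a planted family reach the final
        candidate table?  (Planted miRNAs of background families are decoys
        and are not required to appear.)"""
        cand = {c.mirna_id for c in self.screen.candidates}
        expected = {
            m
            for rec in self._planted_records()
            for m in rec
            if m in self.planted_mirnas
        }
        return bool(expected) and expected <= cand

    def _planted_records(self):
        # member lists of the planted families, via the naming convention
        for fam in self.planted_families:
            idx = int(fam.replace("fam", ""))
            members = [f"miR-{idx:03d}a"]
            if idx % 5 == 0:
                members.append(f"miR-{idx:03d}b")
            yield members


def run_synthetic(
    config: SyntheticConfig,
    *,
    params: PropagationParams = PropagationParams(),
    n_permutations: int = 1000,
    fdr_threshold: float = 0.05,
    rng_seed: int | None = None,
) -> SyntheticScreenOutput:
    """Generate a synthetic study and run the screen over it.

    The permutation seed defaults to the config's own rng_seed so one
    integer reproduces the whole run.
    """
    data = generate_all(config)
    screen = run_screen(
        data["targets"],
        data["network"],
        data["scores"],
        data["matrix"],
        gene_universe=config.gene_ids(),
        params=params,
        n_permutations=n_permutations,
        fdr_threshold=fdr_threshold,
        rng_seed=config.rng_seed if rng_seed is None else rng_seed,
    )
    return SyntheticScreenOutput(
        screen=screen,
        planted_families=data["planted_families"],
        planted_mirnas=data["planted_mirnas"],
    )
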