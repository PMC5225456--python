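"""Synthetic inputs with planted ground truth for the whole screen.

The generators emulate the statistical structure the screen assumes,
without any external database:

* a sparse directed TF→gene network grown by preferential attachment on
  in-degree, so a few hub genes collect many regulators (propagation has
  structure to exploit);
* an addiction-gene list whose membership and reliability scores are
  biased toward high in-degree genes (heavy-tailed, log-normal scores);
* miRNA family target sets, with *planted* families drawing a fixed
  fraction of their targets from the addiction genes and their upstream
  TFs — the signal the propagation + enrichment screen should recover;
* a two-group expression matrix with log-normal signals, planted fold
  changes in the treated (CH) group, and a per-array multiplicative scale
  factor that makes median normalization load-bearing.

Everything is deterministic given ``rng_seed``; each generator derives its
own child stream from the seed so outputs do not share randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_formats import (
    EdgeList,
    ExpressionMatrix,
    FamilyRecord,
    GeneScoreEntry,
    GeneScoreList,
    TargetTable,
    write_edge_list,
    write_expression_matrix,
    write_gene_scores,
    write_target_table,
)


class ConfigError(ValueError):
    """A SyntheticConfig field is outside its valid range."""


def _default_planted_down() -> list[tuple[str, float]]:
    # the planted family's member, halved — mirrors the miR-218 phenotype
    return [("miR-001a", 0.5)]


def _default_planted_up() -> list[tuple[str, float]]:
    # a background family's member, doubled
    return [("miR-005b", 2.0)]


@dataclass
class SyntheticConfig:
    n_genes: int = 500
    n_tfs: int = 50
    edges_per_tf: int = 10
    n_families: int = 50
    targets_per_family: int = 30
    n_addiction_genes: int = 100
    planted_family_count: int = 1
    planted_overlap_fraction: float = 0.6
    n_mirnas_on_array: int = 300
    samples_per_group: int = 4
    planted_up: list[tuple[str, float]] = field(default_factory=_default_planted_up)
    planted_down: list[tuple[str, float]] = field(default_factory=_default_planted_down)
    signal_log_sd: float = 0.25
    array_scale_sd: float = 0.3
    score_log_mean: float = 1.0
    score_log_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_tfs",
            "edges_per_tf",
            "n_families",
            "targets_per_family",
            "n_addiction_genes",
            "n_mirnas_on_array",
            "samples_per_group",
        ):
            if getattr(self, name) < 0 or (
                name not in ("n_tfs",) and getattr(self, name) == 0
            ):
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.planted_overlap_fraction <= 1:
            raise ConfigError("planted_overlap_fraction must lie in [0, 1]")
        if self.planted_family_count < 0:
            raise ConfigError("planted_family_count must be non-negative")
        if self.planted_family_count > self.n_families:
            raise ConfigError("planted_family_count exceeds n_families")
        if self.edges_per_tf >= self.n_genes:
            raise ConfigError("edges_per_tf must be < n_genes")
        if self.n_addiction_genes > self.n_genes:
            raise ConfigError("n_addiction_genes exceeds n_genes")
        if self.targets_per_family > self.n_genes:
            raise ConfigError("targets_per_family exceeds n_genes")
        for mirna, fc in self.planted_up + self.planted_down:
            if fc <= 0:
                raise ConfigError(f"planted fold change for {mirna} must be > 0")
        if self.signal_log_sd < 0 or self.array_scale_sd < 0:
            raise ConfigError("log-scale standard deviations must be >= 0")

    # -- deterministic naming -------------------------------------------------

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def tf_ids(self) -> list[str]:
        return self.gene_ids()[: self.n_tfs]

    def family_ids(self) -> list[str]:
        return [f"fam{i:03d}" for i in range(1, self.n_families + 1)]

    def family_members(self, family_index: int) -> list[str]:
        """Members of the 1-based family *family_index*; every fifth family
        has two array members, so miRNA counts can exceed family counts."""
        members = [f"miR-{family_index:03d}a"]
        if family_index % 5 == 0:
            members.append(f"miR-{family_index:03d}b")
        return members

    def array_mirna_ids(self) -> list[str]:
        """Family members first, then anonymous filler probes (no family)."""
        ids: list[str] = []
        for i in range(1, self.n_families + 1):
            ids.extend(self.family_members(i))
        if len(ids) > self.n_mirnas_on_array:
            raise ConfigError("n_mirnas_on_array too small for the family members")
        ids.extend(
            f"probe-{j:03d}" for j in range(1, self.n_mirnas_on_array - len(ids) + 1)
        )
        return ids

    def planted_family_ids(self) -> list[str]:
        return self.family_ids()[: self.planted_family_count]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream])


# ---------------------------------------------------------------------------


def generate_regulatory_network(config: SyntheticConfig) -> EdgeList:
    """Directed TF→gene edges grown by preferential attachment on in-degree.

    Each TF emits ``edges_per_tf`` edges to distinct non-self genes drawn
    with probability proportional to (current in-degree + 1), giving hub
    targets; exactly ``n_tfs × edges_per_tf`` edges result.
    """
    rng = config._rng(1)
    genes = config.gene_ids()
    indeg = np.zeros(config.n_genes)
    edges: list[tuple[str, str]] = []
    for tf_idx in range(config.n_tfs):
        weights = indeg + 1.0
        weights[tf_idx] = 0.0  # no self-loop
        targets = rng.choice(
            config.n_genes,
            size=config.edges_per_tf,
            replace=False,
            p=weights / weights.sum(),
        )
        for t in targets:
            edges.append((genes[tf_idx], genes[t]))
            indeg[t] += 1
    return EdgeList(edges=tuple(edges))


def generate_gene_scores(
    config: SyntheticConfig, network: EdgeList | None = None
) -> GeneScoreList:
    """Addiction genes with log-normal reliability scores.

    When a network is supplied, both membership and score magnitude are
    biased toward genes with many regulators: selection probability is
    proportional to in-degree + 1, and the largest scores are assigned to
    the most-regulated selected genes.  This is the signal propagation is
    meant to find — perturbing an upstream TF floods high-reliability
    addiction genes.
    """
    rng = config._rng(2)
    genes = config.gene_ids()
    indeg = np.zeros(config.n_genes)
    if network is not None:
        index = {g: i for i, g in enumerate(genes)}
        for _, t in network.edges:
            indeg[index[t]] += 1
    weights = indeg + 1.0
    chosen = rng.choice(
        config.n_genes,
        size=config.n_addiction_genes,
        replace=False,
        p=weights / weights.sum(),
    )
    reliabilities = np.sort(
        rng.lognormal(config.score_log_mean, config.score_log_sd, len(chosen))
    )[::-1]
    # highest scores on the most-regulated genes (ties by gene id)
    chosen_sorted = sorted(chosen, key=lambda i: (-indeg[i], genes[i]))
    entries = tuple(
        GeneScoreEntry(genes[i], float(r), math.log(float(r)))
        for i, r in zip(chosen_sorted, reliabilities)
    )
    return GeneScoreList(entries=tuple(sorted(entries, key=lambda e: e.gene_id)))


def generate_target_map(
    config: SyntheticConfig, network: EdgeList, scores: GeneScoreList
) -> tuple[TargetTable, list[str]]:
    """Family→target table with planted addiction-regulating families.

    Planted families (the first ``planted_family_count`` family ids) draw
    ``planted_overlap_fraction`` of their targets from the enriched pool —
    addiction genes plus TFs regulating an addiction gene — and the rest
    uniformly; background families draw uniformly.  Returns the table and
    the planted family ids as ground truth.
    """
    rng = config._rng(3)
    genes = config.gene_ids()
    addiction = {e.gene_id for e in scores.entries}
    upstream_tfs = {s for s, t in network.edges if t in addiction}
    pool = sorted(addiction | upstream_tfs)
    planted_ids = set(config.planted_family_ids())
    records = []
    for i, family_id in enumerate(config.family_ids(), start=1):
        conservation = float(rng.uniform(2.0, 6.0))
        if family_id in planted_ids:
            k_pool = min(
                round(config.planted_overlap_fraction * config.targets_per_family),
                len(pool),
            )
            from_pool = rng.choice(len(pool), size=k_pool, replace=False)
            targets = {pool[j] for j in from_pool}
            rest = [g for g in genes if g not in targets]
            fill = rng.choice(
                len(rest), size=config.targets_per_family - k_pool, replace=False
            )
            targets |= {rest[j] for j in fill}
        else:
            idx = rng.choice(
                config.n_genes, size=config.targets_per_family, replace=False
            )
            targets = {genes[j] for j in idx}
        records.append(
            FamilyRecord(
                family_id=family_id,
                mirna_ids=tuple(config.family_members(i)),
                conservation_score=conservation,
                target_gene_ids=frozenset(targets),
            )
        )
    return TargetTable(records=tuple(records)), sorted(planted_ids)


def generate_expression_matrix(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Two-group miRNA array with planted fold changes and array scaling.

    Signals are log-normal around a per-miRNA baseline; planted miRNAs'
    CH samples are multiplied by their fold change; every array is then
    multiplied by its own log-normal scale factor (sd ``array_scale_sd``),
    which median normalization must undo.  Returns the matrix and the
    planted truth {mirna_id: fold_change}.
    """
    rng = config._rng(4)
    mirna_ids = config.array_mirna_ids()
    planted = dict(config.planted_up) | dict(config.planted_down)
    unknown = sorted(set(planted) - set(mirna_ids))
    if unknown:
        raise ConfigError(f"planted miRNA(s) not on the array: {unknown}")
    n = len(mirna_ids)
    n_samples = 2 * config.samples_per_group
    sample_ids = [f"CS{j + 1}" for j in range(config.samples_per_group)] + [
        f"CH{j + 1}" for j in range(config.samples_per_group)
    ]
    group_of = {s: ("CS" if s.startswith("CS") else "CH") for s in sample_ids}
    baseline = rng.lognormal(math.log(200.0), 1.0, n)
    noise = (
        np.exp(rng.normal(0.0, config.signal_log_sd, (n, n_samples)))
        if config.signal_log_sd > 0
        else np.ones((n, n_samples))
    )
    signals = baseline[:, None] * noise
    ch_cols = np.arange(config.samples_per_group, n_samples)
    for i, mirna in enumerate(mirna_ids):
        if mirna in planted:
            signals[i, ch_cols] *= planted[mirna]
    array_scale = (
        np.exp(rng.normal(0.0, config.array_scale_sd, n_samples))
        if config.array_scale_sd > 0
        else np.ones(n_samples)
    )
    signals = signals * array_scale[None, :]
    matrix = ExpressionMatrix(
        mirna_ids=mirna_ids,
        sample_ids=sample_ids,
        signals=signals,
        group_of_sample=group_of,
        normalized=False,
    )
    return matrix, planted


# ---------------------------------------------------------------------------


def generate_all(config: SyntheticConfig) -> dict:
    """Run every generator; returns a dict of all inputs plus ground truth."""
    network = generate_regulatory_network(config)
    scores = generate_gene_scores(config, network)
    targets, planted_families = generate_target_map(config, network, scores)
    matrix, planted_mirnas = generate_expression_matrix(config)
    return {
        "network": network,
        "scores": scores,
        "targets": targets,
        "matrix": matrix,
        "planted_families": planted_families,
        "planted_mirnas": planted_mirnas,
    }


def write_all(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Write every generated input in its pipeline dialect, plus a truth
    table (entity_id, truth_label) and the config echoed to YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_all(config)
    write_edge_list(data["network"], outdir / "edges.tsv")
    write_gene_scores(data["scores"], outdir / "gene_scores.tsv")
    write_target_table(data["targets"], outdir / "targets.tsv")
    write_expression_matrix(
        data["matrix"], outdir / "expression.tsv", outdir / "groups.tsv"
    )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("entity_id\ttruth_label\n")
        for fam in data["planted_families"]:
            fh.write(f"{fam}\tplanted_family\n")
        for mirna, fc in sorted(data["planted_mirnas"].items()):
            label = "planted_up" if fc > 1 else "planted_down"
            fh.write(f"{mirna}\t{label}:{fc}\n")
    cfg = {
        k: (list(map(list, v)) if isinstance(v, list) else v)
        for k, v in vars(config).items()
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return data
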