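"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are tab-separated with a header row.  The dialects are minimal
stand-ins for the public resources the screen draws on: a TargetScan-style
family→target table with a family conservation score, an HTRIdb-style
directed TF→gene edge list, a KARG-style addiction-gene reliability list,
and a two-group miRNA expression matrix.  Sequences are plain FASTA.

Every reader validates its input and raises :class:`FormatError` (layout
problems, with a line number where possible) or :class:`ValueError`
(domain violations) rather than silently truncating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: base of the reliability-score log transform; natural log by default,
#: override module-wide for base-2/10 dialects.
LOG_BASE: float = math.e

_DNA = frozenset("ACGT")
_RNA = frozenset("ACGU")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FamilyRecord:
    """One conserved miRNA family with its predicted target set."""

    family_id: str
    mirna_ids: tuple[str, ...]
    conservation_score: float
    target_gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not math.isfinite(self.conservation_score):
            raise ValueError(f"non-finite conservation score for {self.family_id}")
        if not self.target_gene_ids:
            raise ValueError(f"empty target set for family {self.family_id}")


@dataclass(frozen=True)
class TargetTable:
    records: tuple[FamilyRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.family_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate family_id in target table")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def family_map(self) -> dict[str, str]:
        """miRNA id → family id over every family in the table."""
        fmap: dict[str, str] = {}
        for rec in self.records:
            for m in rec.mirna_ids:
                fmap[m] = rec.family_id
        return fmap


@dataclass(frozen=True)
class EdgeList:
    """Deduplicated directed regulation edges (source TF → regulated gene)."""

    edges: tuple[tuple[str, str], ...]
    directed: bool = True
    n_self_loops_dropped: int = 0

    def __len__(self) -> int:
        return len(self.edges)

    def node_ids(self) -> set[str]:
        nodes: set[str] = set()
        for s, t in self.edges:
            nodes.add(s)
            nodes.add(t)
        return nodes


@dataclass(frozen=True)
class GeneScoreEntry:
    gene_id: str
    reliability: float
    log_reliability: float


@dataclass(frozen=True)
class GeneScoreList:
    """Addiction genes with raw and log-transformed reliability scores."""

    entries: tuple[GeneScoreEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.gene_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_id in score list")
        for e in self.entries:
            if not e.reliability > 0:
                raise ValueError(f"non-positive reliability for {e.gene_id}")

    def __len__(self) -> int:
        return len(self.entries)

    def log_weight_of(self) -> dict[str, float]:
        return {e.gene_id: e.log_reliability for e in self.entries}


@dataclass
class ExpressionMatrix:
    """miRNA × sample signal matrix with two-group labels (CS vs CH)."""

    mirna_ids: list[str]
    sample_ids: list[str]
    signals: np.ndarray  # shape (n_mirnas, n_samples), non-negative
    group_of_sample: dict[str, str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValueError(
                f"signal matrix shape {self.signals.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs × {len(self.sample_ids)} samples"
            )
        if np.any(self.signals < 0) or not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite and non-negative")
        missing = [s for s in self.sample_ids if s not in self.group_of_sample]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        groups = {self.group_of_sample[s] for s in self.sample_ids}
        if len(groups) < 2:
            raise ValueError("both sample groups must be non-empty")

    def columns_for(self, group: str) -> list[int]:
        return [
            j for j, s in enumerate(self.sample_ids) if self.group_of_sample[s] == group
        ]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.mirna_ids),
            list(self.sample_ids),
            self.signals.copy(),
            dict(self.group_of_sample),
            self.normalized,
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A validated nucleotide sequence, stored uppercase."""

    id: str
    sequence: str
    alphabet: str  # "DNA" | "RNA"

    def __post_init__(self) -> None:
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        allowed = _DNA if self.alphabet == "DNA" else _RNA
        for pos, ch in enumerate(self.sequence):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} character {ch!r} in record "
                    f"{self.id!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def make_sequence_record(id: str, sequence: str, alphabet: str) -> SequenceRecord:
    """Uppercase and validate a raw sequence string."""
    return SequenceRecord(id=id, sequence=sequence.upper(), alphabet=alphabet)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (no header)") from None
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_target_table(path: str | Path, min_conservation: float = 2.0) -> TargetTable:
    """Load a family→target table, keeping families at or above *min_conservation*.

    Expected columns: ``family_id``, ``mirna_ids`` (comma-joined),
    ``conservation_score``, ``gene_id`` — one row per family–gene pair.
    """
    df = _read_tsv(path, ["family_id", "mirna_ids", "conservation_score", "gene_id"])
    if df.empty:
        return TargetTable(records=())
    scores = pd.to_numeric(df["conservation_score"], errors="coerce")
    bad = scores.isna()
    if bad.any():
        # +2: header line plus 1-based line numbering
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: non-numeric conservation_score at line {line}")
    records = []
    for fam, grp in df.groupby("family_id", sort=False):
        score = float(scores[grp.index[0]])
        if score < min_conservation:
            continue
        mirnas = tuple(m.strip() for m in str(grp["mirna_ids"].iloc[0]).split(","))
        records.append(
            FamilyRecord(
                family_id=str(fam),
                mirna_ids=mirnas,
                conservation_score=score,
                target_gene_ids=frozenset(grp["gene_id"].astype(str)),
            )
        )
    return TargetTable(records=tuple(records))


def read_edge_list(path: str | Path) -> EdgeList:
    """Load a two-column directed edge list; drops self-loops, deduplicates."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_loops = 0
    with open(path) as fh:
        header_skipped = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: expected 2 tab-separated fields at line {lineno}, "
                    f"got {len(fields)}"
                )
            if not header_skipped:
                header_skipped = True
                if fields == ["source", "target"]:
                    continue
            s, t = fields
            if s == t:
                n_loops += 1
                continue
            if (s, t) not in seen:
                seen.add((s, t))
                edges.append((s, t))
    if n_loops:
        logger.info("dropped %d self-loop(s) from %s", n_loops, path)
    return EdgeList(edges=tuple(edges), n_self_loops_dropped=n_loops)


def read_gene_scores(path: str | Path) -> GeneScoreList:
    """Load a gene reliability list; duplicates collapse to the max score."""
    df = _read_tsv(path, ["gene_id", "reliability"])
    entries: dict[str, float] = {}
    n_dup = 0
    for _, row in df.iterrows():
        gene = str(row["gene_id"])
        rel = float(row["reliability"])
        if rel <= 0:
            raise ValueError(f"non-positive reliability for gene {gene}")
        if gene in entries:
            n_dup += 1
            entries[gene] = max(entries[gene], rel)
        else:
            entries[gene] = rel
    if n_dup:
        logger.info("collapsed %d duplicate gene row(s) in %s by max", n_dup, path)
    return GeneScoreList(
        entries=tuple(
            GeneScoreEntry(g, r, math.log(r, LOG_BASE)) for g, r in entries.items()
        )
    )


def read_expression_matrix(
    path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    """Load a signal matrix (row ids in column 1) plus a sample→group table."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    grp = _read_tsv(groups_path, ["sample_id", "group"])
    group_of = dict(zip(grp["sample_id"].astype(str), grp["group"].astype(str)))
    missing = [s for s in mat.columns if s not in group_of]
    if missing:
        raise ValueError(f"{groups_path}: no group for sample(s) {missing}")
    return ExpressionMatrix(
        mirna_ids=[str(i) for i in mat.index],
        sample_ids=[str(c) for c in mat.columns],
        signals=mat.to_numpy(dtype=float),
        group_of_sample=group_of,
        normalized=False,
    )


def read_fasta(path: str | Path, alphabet: str = "DNA") -> list[SequenceRecord]:
    """Read FASTA records, uppercased and validated against *alphabet*.

    U↔T is not auto-converted: an RNA base in a DNA file is an error.
    """
    return [
        make_sequence_record(rec.id, str(rec.seq), alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)


def write_target_table(table: TargetTable, path: str | Path) -> None:
    rows = [
        {
            "family_id": rec.family_id,
            "mirna_ids": ",".join(rec.mirna_ids),
            "conservation_score": rec.conservation_score,
            "gene_id": gene,
        }
        for rec in table.records
        for gene in sorted(rec.target_gene_ids)
    ]
    pd.DataFrame(
        rows, columns=["family_id", "mirna_ids", "conservation_score", "gene_id"]
    ).to_csv(path, sep="\t", index=False)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in edges.edges:
            fh.write(f"{s}\t{t}\n")


def write_gene_scores(scores: GeneScoreList, path: str | Path) -> None:
    pd.DataFrame(
        [{"gene_id": e.gene_id, "reliability": e.reliability} for e in scores.entries]
    ).to_csv(path, sep="\t", index=False)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, groups_path: str | Path
) -> None:
    df = pd.DataFrame(
        matrix.signals, index=matrix.mirna_ids, columns=matrix.sample_ids
    )
    df.index.name = "mirna_id"
    df.to_csv(path, sep="\t")
    pd.DataFrame(
        [
            {"sample_id": s, "group": matrix.group_of_sample[s]}
            for s in matrix.sample_ids
        ]
    ).to_csv(groups_path, sep="\t", index=False)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")
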