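"""Intersection of the NPES screen with the differential-expression filter.

A candidate is a differentially expressed miRNA whose family was flagged
significant by the enrichment screen.  Because a family can have several
members on the array, the candidate miRNA count can exceed the candidate
family count.  Candidates are ranked significance-first: family q
ascending, then NPES descending, then miRNA id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .diffexpr import DifferentialRecord
from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

FamilyMap = dict[str, str]  # miRNA id -> family id (many-to-one)


@dataclass(frozen=True)
class CandidateRecord:
    mirna_id: str
    family_id: str
    npes: float
    q_value: float
    fold_change: float
    direction: str
    rank: int  # 1-based, dense


@dataclass(frozen=True)
class RunSummary:
    n_families_tested: int
    n_families_significant: int
    n_de_mirnas: int
    n_candidate_mirnas: int
    n_candidate_families: int


def intersect(
    enrichment: list[EnrichmentResult],
    de_records: list[DifferentialRecord],
    family_map: FamilyMap,
) -> list[CandidateRecord]:
    """DE miRNAs whose family is significant, ranked by (q asc, NPES desc).

    DE miRNAs with no family in the map (no conserved family passed the
    upstream filter) are excluded and logged, mirroring the conservation
    filter.
    """
    by_family = {r.family_id: r for r in enrichment}
    de_by_id = {r.mirna_id: r for r in de_records if r.passes}
    candidates = []
    n_unmapped = 0
    for mirna_id, de in de_by_id.items():
        family_id = family_map.get(mirna_id)
        if family_id is None:
            n_unmapped += 1
            continue
        enr = by_family.get(family_id)
        if enr is None or not enr.significant:
            continue
        candidates.append((mirna_id, family_id, enr, de))
    if n_unmapped:
        logger.info("%d DE miRNA(s) had no family mapping and were excluded", n_unmapped)
    candidates.sort(key=lambda c: (c[2].q_value, -c[2].npes, c[0]))
    return [
        CandidateRecord(
            mirna_id=m,
            family_id=f,
            npes=enr.npes,
            q_value=enr.q_value,
            fold_change=de.fold_change,
            direction=de.direction,
            rank=i + 1,
        )
        for i, (m, f, enr, de) in enumerate(candidates)
    ]


def summarize(
    enrichment: list[EnrichmentResult],
    de_records: list[DifferentialRecord],
    candidates: list[CandidateRecord],
) -> RunSummary:
    return RunSummary(
        n_families_tested=len(enrichment),
        n_families_significant=sum(1 for r in enrichment if r.significant),
        n_de_mirnas=sum(1 for r in de_records if r.passes),
        n_candidate_mirnas=len(candidates),
        n_candidate_families=len({c.family_id for c in candidates}),
    )


def report(
    candidates: list[CandidateRecord],
    summary: RunSummary,
    out_path: str | Path,
) -> None:
    """Write the candidate table (TSV) and a stage-count summary next to it."""
    out_path = Path(out_path)
    pd.DataFrame(
        [
            {
                "rank": c.rank,
                "mirna_id": c.mirna_id,
                "family_id": c.family_id,
                "npes": c.npes,
                "q_value": c.q_value,
                "fold_change": c.fold_change,
                "direction": c.direction,
            }
            for c in candidates
        ],
        columns=[
            "rank",
            "mirna_id",
            "family_id",
            "npes",
            "q_value",
            "fold_change",
            "direction",
        ],
    ).to_csv(out_path, sep="\t", index=False)
    summary_path = out_path.with_suffix(".summary.txt")
    summary_path.write_text(
        "families_tested\t{0.n_families_tested}\n"
        "families_significant\t{0.n_families_significant}\n"
        "de_mirnas\t{0.n_de_mirnas}\n"
        "candidate_mirnas\t{0.n_candidate_mirnas}\n"
        "candidate_families\t{0.n_candidate_families}\n".format(summary)
    )
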