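"""Canonical miRNA seed-site scanning and the small validation-assay math.

The seed is nucleotides 2–8 of the mature miRNA (5′→3′).  Canonical target
sites on a 3′UTR are reverse-complement matches of (sub)regions of the
seed, in decreasing strength:

    8mer      reverse complement of positions 2–8, followed by A
    7mer-m8   reverse complement of positions 2–8
    7mer-A1   reverse complement of positions 2–7, followed by A
    6mer      reverse complement of positions 2–7

The trailing A in A1/8mer sites is the target adenosine opposite miRNA
position 1; it is a literal A regardless of the miRNA's first base.  A
locus is reported once, as its longest matching type (a flag exposes all
overlapping matches for audit).  Coordinates are 0-based half-open on the
given insert, + strand.

Also here: seed-region mutant design for luciferase constructs,
Renilla/Firefly normalization, and 2^−ΔΔCt relative quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord, make_sequence_record

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT_DNA = str.maketrans("ACGT", "TGCA")
_COMPLEMENT_RNA = str.maketrans("ACGU", "UGCA")


def _complement(seq: str, alphabet: str) -> str:
    table = _COMPLEMENT_DNA if alphabet == "DNA" else _COMPLEMENT_RNA
    return seq.translate(table)


def _revcomp(seq: str, alphabet: str) -> str:
    return _complement(seq, alphabet)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA; the seed is positions 2–8 of its 5′→3′ sequence."""

    id: str
    sequence: SequenceRecord

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(
                f"mature miRNA {self.id!r} shorter than 8 nt; no seed"
            )

    @property
    def seed(self) -> str:
        return seed_of(self.sequence.sequence)


@dataclass(frozen=True)
class SeedSite:
    """A canonical seed-match interval on a 3′UTR (0-based half-open)."""

    utr_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[self.site_type]
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, "
                f"got [{self.start}, {self.end})"
            )


def seed_of(mature_sequence: str) -> str:
    """Seed heptamer: characters at positions 2–8 (1-based) of the mature
    5′→3′ sequence."""
    if len(mature_sequence) < 8:
        raise ValueError("mature sequence shorter than 8 nt has no 2–8 seed")
    return mature_sequence[1:8].upper()


def site_motifs(seed: str, alphabet: str = "DNA") -> dict[str, str]:
    """Target-strand motif for each canonical site type, in *alphabet*.

    The seed may be given in RNA or DNA; motifs are emitted in the UTR's
    alphabet (U↔T converted as needed).
    """
    if len(seed) != 7:
        raise ValueError("seed must be exactly 7 nt (miRNA positions 2–8)")
    seed_dna = seed.upper().replace("U", "T")
    seed_local = seed_dna if alphabet == "DNA" else seed_dna.replace("T", "U")
    a = "A"
    m8 = _revcomp(seed_local, alphabet)  # pairs positions 2–8
    six = _revcomp(seed_local[:6], alphabet)  # pairs positions 2–7
    return {
        "8mer": m8 + a,
        "7mer-m8": m8,
        "7mer-A1": six + a,
        "6mer": six,
    }


def scan_sites(
    utr: SequenceRecord, mirna: MatureMiRNA, *, report_all: bool = False
) -> list[SeedSite]:
    """All canonical sites of *mirna* on *utr*, sorted by start.

    Each locus is reported once as its longest matching type; matches whose
    interval lies inside a longer match are subsumed unless *report_all*.
    """
    motifs = site_motifs(mirna.seed, utr.alphabet)
    matches: list[SeedSite] = []
    for site_type, motif in motifs.items():
        start = utr.sequence.find(motif)
        while start != -1:
            matches.append(SeedSite(utr.id, start, start + len(motif), site_type))
            start = utr.sequence.find(motif, start + 1)
    if not report_all:
        matches = [
            m
            for m in matches
            if not any(
                o.end - o.start > m.end - m.start
                and o.start <= m.start
                and m.end <= o.end
                for o in matches
            )
        ]
    matches.sort(key=lambda m: (m.start, m.end))
    return matches


class MutationError(RuntimeError):
    """Seed-site mutation could not abolish canonical pairing."""


def mutate_seed_site(
    utr: SequenceRecord, site: SeedSite, mirna: MatureMiRNA
) -> SequenceRecord:
    """Replace the seed-match sequence with its complement (not reverse
    complement), abolishing Watson–Crick pairing with the seed while
    preserving length.

    The mutant is re-scanned; if the substitution happens to create a new
    canonical site elsewhere, the reverse complement is tried as a fallback
    before giving up.
    """
    if not (0 <= site.start < site.end <= len(utr)):
        raise ValueError(f"site [{site.start}, {site.end}) outside UTR {utr.id!r}")
    segment = utr.sequence[site.start : site.end]
    for replacement in (
        _complement(segment, utr.alphabet),
        _revcomp(segment, utr.alphabet),
    ):
        mutant_seq = utr.sequence[: site.start] + replacement + utr.sequence[site.end :]
        mutant = make_sequence_record(f"{utr.id}_seedmut", mutant_seq, utr.alphabet)
        if not scan_sites(mutant, mirna):
            return mutant
    raise MutationError(
        f"could not abolish canonical {mirna.id} sites on {utr.id} "
        f"at [{site.start}, {site.end})"
    )


# ---------------------------------------------------------------------------
# luciferase reporter normalization


@dataclass(frozen=True)
class LuciferaseWell:
    """One well of a dual-luciferase assay."""

    renilla: float
    firefly: float
    treatment: str  # "scramble" | "mimic"
    construct: str  # e.g. "Mecp2-wt", "Mecp2-mut"

    def __post_init__(self) -> None:
        if self.firefly <= 0:
            raise ValueError("Firefly activity must be positive")
        if self.renilla <= 0:
            raise ValueError("Renilla activity must be positive")
        if self.treatment not in ("scramble", "mimic"):
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def ratio(self) -> float:
        return self.renilla / self.firefly


def luciferase_normalize(
    wells: list[LuciferaseWell],
) -> dict[tuple[str, str], tuple[float, float]]:
    """Per-condition normalized means ± s.e.m.

    Each well's Renilla/Firefly ratio is divided by the mean ratio of the
    scramble wells of the same UTR construct, so every construct's scramble
    group has mean 1 by construction.  Returns
    {(construct, treatment): (mean, sem)}; sem is NaN for singleton groups.
    """
    if not wells:
        raise ValueError("no wells")
    constructs = {w.construct for w in wells}
    reference: dict[str, float] = {}
    for construct in constructs:
        ref = [w.ratio for w in wells if w.construct == construct and w.treatment == "scramble"]
        if not ref:
            raise ValueError(f"no scramble reference wells for construct {construct!r}")
        reference[construct] = float(np.mean(ref))
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for construct in sorted(constructs):
        for treatment in ("scramble", "mimic"):
            vals = np.array(
                [
                    w.ratio / reference[construct]
                    for w in wells
                    if w.construct == construct and w.treatment == treatment
                ]
            )
            if vals.size == 0:
                continue
            sem = (
                float(vals.std(ddof=1) / math.sqrt(vals.size))
                if vals.size > 1
                else float("nan")
            )
            out[(construct, treatment)] = (float(vals.mean()), sem)
    return out


# ---------------------------------------------------------------------------
# qPCR relative quantification


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control;
    one extra cycle of the target in the treated group halves the result.
    """
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-delta_delta)


@dataclass(frozen=True)
class QpcrSample:
    """Target and reference Ct for one sample."""

    ct_target: float
    ct_reference: float
    group: str  # "control" | "treated"


def relative_expression(samples: list[QpcrSample]) -> float:
    """2^−ΔΔCt from per-sample Cts, using group-mean ΔCt values."""
    controls = [s for s in samples if s.group == "control"]
    treated = [s for s in samples if s.group == "treated"]
    if not controls or not treated:
        raise ValueError("need at least one control and one treated sample")
    dct_control = float(np.mean([s.ct_target - s.ct_reference for s in controls]))
    dct_treated = float(np.mean([s.ct_target - s.ct_reference for s in treated]))
    return 2.0 ** (-(dct_treated - dct_control))
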