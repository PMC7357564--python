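"""Half-spot expression counting and splice-isoform partitioning.

Expression of a gene in a short-read archive is measured by counting how
many mates ("half spots": each mate of a spot counts separately) contain
coding sequence of the gene, then normalizing per million *spots* in the
archive.  Note the deliberate asymmetry: the numerator is half spots,
the denominator is spots, so a paired-end archive can yield up to twice
the per-million value a per-read normalization would give.  Matching is
an exact shared substring of at least ``min_match`` nucleotides with the
coding sequence (either strand), and only the coding sequence is used as
query so that shared untranslated stretches between paralogous
transcripts cannot inflate counts.

Alternative splice isoforms are partitioned on identifier sets: the
mates matching each isoform are identified separately, the intersection
is the shared count, and subtracting it from each isoform's initial
count gives the isoform-specific counts — which makes the arithmetic
exact (a_only + b_only + shared == union_total always).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq

from .records import ReadSpot, SequenceRecord

#: Returned by fold_change for x/0 with x > 0.
INF_FOLD = math.inf
#: Returned by fold_change for 0/0.
UNDEFINED_FOLD = math.nan

DEFAULT_MIN_MATCH = 32


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene, per-archive expression with per-million normalization."""

    gene_id: str
    archive_id: str
    half_spot_count: int
    total_spots: int

    def __post_init__(self) -> None:
        if self.total_spots <= 0:
            raise ValueError("total_spots must be positive")
        if self.half_spot_count < 0:
            raise ValueError("half_spot_count must be non-negative")

    @property
    def rpm(self) -> float:
        return rpm(self.half_spot_count, self.total_spots)


@dataclass(frozen=True)
class IsoformCounts:
    """Identifier-set partition of reads between two splice isoforms."""

    a_only: int
    b_only: int
    shared: int

    @property
    def union_total(self) -> int:
        return self.a_only + self.b_only + self.shared


def _kmer_set(seq: str, k: int) -> set[str]:
    kmers: set[str] = set()
    for s in (seq.upper(), str(Seq(seq.upper()).reverse_complement())):
        kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return kmers


def matching_half_spots(
    cds: SequenceRecord, spots: list[ReadSpot], min_match: int = DEFAULT_MIN_MATCH
) -> set[tuple[str, int]]:
    """Identifiers of mates sharing >= min_match exact nt with the CDS.

    A mate shares an exact substring of length >= min_match with the CDS
    (on either strand) iff one of its min_match-mers occurs in the CDS,
    so membership reduces to a k-mer set lookup.
    """
    if not cds.residues:
        raise ValueError("empty coding sequence")
    if cds.alphabet != "dna":
        raise ValueError("coding sequence must be nucleotide")
    k = min_match
    ref = _kmer_set(cds.residues, k)
    hits: set[tuple[str, int]] = set()
    for spot in spots:
        for mi, mate in enumerate(spot.mates):
            m = mate.upper()
            if len(m) < k:
                continue
            if any(m[i : i + k] in ref for i in range(len(m) - k + 1)):
                hits.add((spot.spot_id, mi))
    return hits


def count_coding_reads(
    cds: SequenceRecord, spots: list[ReadSpot], min_match: int = DEFAULT_MIN_MATCH
) -> int:
    """Number of half spots containing coding sequence of ``cds``."""
    return len(matching_half_spots(cds, spots, min_match))


def rpm(half_spot_count: int, total_spots: int) -> float:
    """Half-spot count per million spots in the archive."""
    if total_spots <= 0:
        raise ValueError("total_spots must be positive")
    if half_spot_count < 0:
        raise ValueError("half_spot_count must be non-negative")
    return half_spot_count * 1_000_000 / total_spots


def isoform_specific_counts(
    cds_a: SequenceRecord,
    cds_b: SequenceRecord,
    spots: list[ReadSpot],
    min_match: int = DEFAULT_MIN_MATCH,
) -> IsoformCounts:
    """Partition matching mates between two isoforms by identifier sets."""
    if cds_a.residues == cds_b.residues:
        raise ValueError("isoforms must differ")
    a = matching_half_spots(cds_a, spots, min_match)
    b = matching_half_spots(cds_b, spots, min_match)
    shared = len(a & b)
    return IsoformCounts(a_only=len(a) - shared, b_only=len(b) - shared, shared=shared)


def fold_change(rpm_high: float, rpm_low: float) -> float:
    """Expression contrast between two archives, as a ratio of RPM values.

    Zero denominators are real in expression tables (tissues with no
    detectable reads), so x/0 with x > 0 returns ``INF_FOLD`` and 0/0
    returns ``UNDEFINED_FOLD`` rather than raising.
    """
    if rpm_high < 0 or rpm_low < 0:
        raise ValueError("rpm values must be non-negative")
    if rpm_low == 0:
        return INF_FOLD if rpm_high > 0 else UNDEFINED_FOLD
    return rpm_high / rpm_low


def truth_isoform_counts(
    truth_rows: list[dict],
    cds_a: SequenceRecord,
    cds_b: SequenceRecord,
    read_length: int,
    min_match: int = DEFAULT_MIN_MATCH,
) -> IsoformCounts:
    """Isoform partition derived from a simulator truth table.

    Independent of the k-mer matching path: each read's origin window is
    located by coordinates, and the read is assigned to an isoform iff at
    least ``min_match`` contiguous nucleotides of its window occur
    verbatim in that isoform.  For reads originating from one isoform
    this reduces to coordinate arithmetic against the common
    prefix/suffix shared with the other isoform; when the window lies
    entirely in the common region the read is shared by construction.
    """
    seqs = {cds_a.id: cds_a.residues, cds_b.id: cds_b.residues}
    other = {cds_a.id: cds_b.residues, cds_b.id: cds_a.residues}
    a_ids: set[str] = set()
    b_ids: set[str] = set()
    for row in truth_rows:
        tid = row["transcript_id"]
        if tid not in seqs:
            continue
        window = seqs[tid][row["offset"] - 1 : row["offset"] - 1 + read_length]
        own = cds_a if tid == cds_a.id else cds_b
        (a_ids if own is cds_a else b_ids).add(row["read_id"])
        if _shares_block(window, other[tid], min_match):
            (b_ids if own is cds_a else a_ids).add(row["read_id"])
    shared = len(a_ids & b_ids)
    return IsoformCounts(
        a_only=len(a_ids) - shared, b_only=len(b_ids) - shared, shared=shared
    )


def _shares_block(window: str, other: str, k: int) -> bool:
    if len(window) < k:
        return False
    return any(window[i : i + k] in other for i in range(len(window) - k + 1))


def expression_table(
    genes: dict[str, SequenceRecord],
    archives: dict[str, list[ReadSpot]],
    min_match: int = DEFAULT_MIN_MATCH,
) -> list[ExpressionRecord]:
    """Count every gene in every archive; archives are sized in spots."""
    out = []
    for aid, spots in archives.items():
        total = len(spots)
        for gid, cds in genes.items():
            out.append(
                ExpressionRecord(
                    gene_id=gid,
                    archive_id=aid,
                    half_spot_count=count_coding_reads(cds, spots, min_match),
                    total_spots=total,
                )
            )
    return out
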