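"""Iterative targeted read recruitment and mini-assembly.

Mirrors the mining strategy used against transcriptome short-read
archives: recruit reads resembling a query (a protein in the first
round, nucleotide contigs thereafter), assemble just those reads into
contigs, use the contigs as the next round's query, and repeat until the
recruited set stops growing.  BLAST-style permissive E-value search is
re-expressed as exact short-seed matching (amino-acid seeds against all
six mate translations for protein queries, nucleotide seeds on both
strands for DNA queries), and the assembler is a deterministic greedy
overlap-layout merger — mini-transcriptomes recruited this way are tiny,
so neither a scoring matrix nor a graph assembler is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .records import ReadSpot, SequenceRecord


@dataclass(frozen=True)
class RecruitParams:
    """Seed and overlap settings for the mining loop."""

    aa_seed_length: int = 4
    nt_seed_length: int = 21
    min_overlap: int = 25
    min_overlap_identity: float = 1.0
    max_rounds: int = 10

    def __post_init__(self) -> None:
        if self.aa_seed_length < 3:
            raise ValueError("aa seeds must be >= 3 residues")
        if self.nt_seed_length < 11:
            raise ValueError("nt seeds must be >= 11 bases")
        if not 0 < self.min_overlap_identity <= 1:
            raise ValueError("overlap identity must be in (0, 1]")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _six_frame_translations(seq: str) -> list[str]:
    out = []
    for s in (seq, _revcomp(seq)):
        for f in range(3):
            sub = s[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                out.append(str(Seq(sub).translate()))
    return out


def recruit_reads(
    query: SequenceRecord, spots: list[ReadSpot], params: RecruitParams
) -> set[tuple[str, int]]:
    """Mates sharing at least one exact seed with the query.

    Protein queries are compared against all six translation frames of
    each mate with ``aa_seed_length`` seeds; DNA queries use
    ``nt_seed_length`` seeds on both strands.  Returns (spot id, mate
    index) pairs, duplicate-free.
    """
    if query.alphabet == "protein":
        k = params.aa_seed_length
        if len(query.residues) < k:
            raise ValueError("query shorter than seed length")
        seeds = _kmers(query.residues.upper(), k)
        recruited = set()
        for spot in spots:
            for mi, mate in enumerate(spot.mates):
                if any(
                    _kmers(t, k) & seeds for t in _six_frame_translations(mate.upper())
                ):
                    recruited.add((spot.spot_id, mi))
        return recruited
    k = params.nt_seed_length
    if len(query.residues) < k:
        raise ValueError("query shorter than seed length")
    q = query.residues.upper()
    seeds = _kmers(q, k) | _kmers(_revcomp(q), k)
    recruited = set()
    for spot in spots:
        for mi, mate in enumerate(spot.mates):
            if _kmers(mate.upper(), k) & seeds:
                recruited.add((spot.spot_id, mi))
    return recruited


# ---------------------------------------------------------------------------
# Greedy overlap assembly


@dataclass
class Contig:
    """An assembled contig with read provenance and per-base coverage."""

    id: str
    sequence: str
    read_ids: list[str]
    # (read_id, 0-based start in contig, read strand relative to contig)
    placements: list[tuple[str, int, str]] = field(default_factory=list)
    _lengths: dict = field(default_factory=dict, repr=False)

    @property
    def coverage(self) -> np.ndarray:
        cov = np.zeros(len(self.sequence), dtype=int)
        for rid, start, _strand in self.placements:
            cov[start : start + self._lengths[rid]] += 1
        return cov


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Longest suffix(a)/prefix(b) overlap >= min_overlap at >= identity."""
    limit = min(len(a), len(b))
    if min_identity >= 1.0:
        for k in range(limit, min_overlap - 1, -1):
            if a.endswith(b[:k]):
                return k
        return 0
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for k in range(limit, min_overlap - 1, -1):
        if (aa[-k:] == bb[:k]).mean() >= min_identity:
            return k
    return 0


def assemble_reads(
    mates: dict[str, str], min_overlap: int = 25, min_identity: float = 1.0
) -> list[Contig]:
    """Greedy best-overlap-first assembly of a small read set.

    Reads contained in another read (either orientation) are absorbed;
    then the pair with the longest qualifying suffix/prefix overlap is
    merged — in any relative orientation — until no pair overlaps by
    >= ``min_overlap`` at >= ``min_identity``.  Ties are broken by
    lexicographic contig-id pair, so assembly is deterministic.
    """
    contigs: dict[str, Contig] = {}
    for rid in sorted(mates):
        seq = mates[rid].upper()
        if len(seq) < min_overlap:
            raise ValueError(f"read {rid!r} shorter than min_overlap")
        c = Contig(id=rid, sequence=seq, read_ids=[rid], placements=[(rid, 0, "+")])
        c._lengths[rid] = len(seq)
        contigs[rid] = c

    def absorb(host: Contig, c: Contig) -> None:
        orient = "+" if c.sequence in host.sequence else "-"
        seq = c.sequence if orient == "+" else _revcomp(c.sequence)
        at = host.sequence.index(seq)
        for rid, start, strand in c.placements:
            s = strand if orient == "+" else ("-" if strand == "+" else "+")
            pos = (
                at + start
                if orient == "+"
                else at + len(c.sequence) - start - c._lengths[rid]
            )
            host.placements.append((rid, pos, s))
            host._lengths[rid] = c._lengths[rid]
        host.read_ids.extend(c.read_ids)

    alive: dict[str, Contig] = {}
    for cid in sorted(contigs, key=lambda i: (-len(contigs[i].sequence), i)):
        c = contigs[cid]
        host = next(
            (
                h
                for h in alive.values()
                if c.sequence in h.sequence or _revcomp(c.sequence) in h.sequence
            ),
            None,
        )
        if host is None:
            alive[cid] = c
        else:
            absorb(host, c)

    def oriented(c: Contig, flip: bool) -> Contig:
        if not flip:
            return c
        seq = _revcomp(c.sequence)
        flipped = Contig(id=c.id, sequence=seq, read_ids=list(c.read_ids))
        flipped.placements = [
            (rid, len(seq) - start - c._lengths[rid], "-" if s == "+" else "+")
            for rid, start, s in c.placements
        ]
        flipped._lengths = dict(c._lengths)
        return flipped

    def merge(a: Contig, b: Contig, k: int, new_id: str) -> Contig:
        seq = a.sequence + b.sequence[k:]
        c = Contig(id=new_id, sequence=seq, read_ids=a.read_ids + b.read_ids)
        c.placements = list(a.placements)
        shift = len(a.sequence) - k
        c.placements += [(rid, start + shift, s) for rid, start, s in b.placements]
        c._lengths = {**a._lengths, **b._lengths}
        return c

    # the four join classes per unordered pair, keyed as
    # (first_id, second_id, flip_first, flip_second); flips beyond these
    # four are reverse-complement duplicates
    def pair_joins(ia: str, ib: str) -> list[tuple]:
        a, b = alive[ia].sequence, alive[ib].sequence
        joins = []
        for key, first, second in (
            ((ia, ib, False, False), a, b),
            ((ib, ia, False, False), b, a),
            ((ia, ib, False, True), a, _revcomp(b)),
            ((ia, ib, True, False), _revcomp(a), b),
        ):
            k = _best_overlap(first, second, min_overlap, min_identity)
            if k:
                joins.append((key, k))
        return joins

    overlaps: dict[tuple, int] = {}
    ids = sorted(alive)
    for i, ia in enumerate(ids):
        for ib in ids[i + 1 :]:
            overlaps.update(pair_joins(ia, ib))

    counter = 0
    while True:
        best = None
        for (ia, ib, fa, fb), k in overlaps.items():
            cand = (-k, ia, ib, fa, fb)
            if best is None or cand < best:
                best = cand
        if best is None:
            break
        neg_k, ia, ib, fa, fb = best
        counter += 1
        new = merge(
            oriented(alive[ia], fa), oriented(alive[ib], fb), -neg_k, f"ctg{counter:04d}"
        )
        del alive[ia], alive[ib]
        overlaps = {
            key: k for key, k in overlaps.items() if ia not in key[:2] and ib not in key[:2]
        }
        for cid in sorted(list(alive)):
            c = alive[cid]
            if c.sequence in new.sequence or _revcomp(c.sequence) in new.sequence:
                absorb(new, c)
                del alive[cid]
                overlaps = {
                    key: k for key, k in overlaps.items() if cid not in key[:2]
                }
        alive[new.id] = new
        for cid in sorted(alive):
            if cid != new.id:
                overlaps.update(pair_joins(new.id, cid))
    return [alive[cid] for cid in sorted(alive)]


# ---------------------------------------------------------------------------
# Iterative loop


@dataclass
class RecruitmentState:
    """Per-round recruited identifier sets and contigs of the miner."""

    rounds: list[set[tuple[str, int]]] = field(default_factory=list)
    contigs_per_round: list[list[Contig]] = field(default_factory=list)

    @property
    def round_index(self) -> int:
        return len(self.rounds)

    @property
    def recruited(self) -> set[tuple[str, int]]:
        return self.rounds[-1] if self.rounds else set()

    @property
    def contigs(self) -> list[Contig]:
        return self.contigs_per_round[-1] if self.contigs_per_round else []


def iterate_recruitment(
    query: SequenceRecord, spots: list[ReadSpot], params: RecruitParams
) -> RecruitmentState:
    """Run recruit/assemble rounds until the recruited set converges.

    Round 1 recruits with the original query; later rounds recruit with
    the previous round's contigs (nucleotide seeds).  Recruited sets are
    cumulative, hence monotone non-decreasing, and the loop stops as
    soon as a round adds no new identifier or ``max_rounds`` is reached.
    """
    state = RecruitmentState()
    by_id = {s.spot_id: s for s in spots}
    recruited: set[tuple[str, int]] = set()
    queries: list[SequenceRecord] = [query]
    for _ in range(params.max_rounds):
        new = set()
        for q in queries:
            try:
                new |= recruit_reads(q, spots, params)
            except ValueError:
                continue  # contig shorter than the seed: skip as a query
        grew = not new <= recruited
        recruited = recruited | new
        state.rounds.append(set(recruited))
        if not recruited:
            state.contigs_per_round.append([])
            break
        mates = {
            f"{sid}/{mi + 1}": by_id[sid].mates[mi] for sid, mi in sorted(recruited)
        }
        contigs = assemble_reads(
            mates, params.min_overlap, params.min_overlap_identity
        )
        state.contigs_per_round.append(contigs)
        if not grew:
            break
        queries = [
            SequenceRecord(id=c.id, residues=c.sequence, alphabet="dna")
            for c in contigs
        ]
    return state
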