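"""Synthetic genomes, transcripts and reads with planted truth.

The generator emulates the sequence structure the mining and detection
pipeline assumes: multi-exon ilp genes with the six-cysteine insulin
framework, the four-coding-exon aIGF archetype with a mid-exon-3
alternative splice site producing two isoforms (the included segment is
arginine-rich with two extra cysteines, the last exon carries the
GTVx1Px2(F/Y) motif), clustered gonadulin-aIGF-relaxin gene arrangements
with configurable intergenic distances, and uniform-coverage reads with
a configurable substitution error rate.

Every output is a pure function of (spec, seed).  Family "archetypes"
are synthetic: each family has a deterministic template in which a
family-specific fraction of positions is conserved between members;
gonadulins are the most divergent, relaxins the most conserved,
mirroring the relative conservation the families show in real data.
Non-conserved positions never introduce cysteines, so the framework is a
sharp truth signal, and decoy/intergenic background is an i.i.d. 40% GC
model rejection-sampled to contain no framework-matching ORF.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .detect import DEFAULT_PATTERN, FrameworkPattern, find_orfs, match_framework
from .records import FeatureRecord, ReadSpot, SequenceRecord

FAMILIES = ("insulin", "aIGF", "gonadulin", "relaxin")

# residues used for non-conserved fill; no cysteine by design
_FILLER = "ADEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "LVIF"
_SIGNAL_LEN = 15  # MK + 10 hydrophobic + AGA

# fraction of template positions conserved between members of a family
_CONSERVED = {"insulin": 0.65, "aIGF": 0.70, "gonadulin": 0.45, "relaxin": 0.80}

# mature-region segment lengths (aa): filler before C1, C1..C2 gap,
# C-peptide (C2..C3 gap), C5..C6 gap, post-C6 extension
_BASE_LAYOUT = {
    "insulin": dict(b0=4, gap1=10, gap2=14, gap5=8, ext=3),
    "gonadulin": dict(b0=5, gap1=14, gap2=30, gap5=10, ext=4),
    "relaxin": dict(b0=4, gap1=9, gap2=20, gap5=8, ext=2),
    "aIGF": dict(b0=4, gap1=10, gap2=16, gap5=8, ext1=20, alt=24, ext2=30),
}

# stop codons in all three frames (and, being a revcomp palindrome, on
# the minus strand too): blocks reading frames from running through introns
_INTRON_STOPPER = "ATTAATTAATTAAT"

_STOP_FREE = {"TAA", "TAG", "TGA"}


def _stable_rng(*parts) -> np.random.Generator:
    key = ":".join(str(p) for p in parts)
    return np.random.default_rng(zlib.crc32(key.encode()) & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Gene model specification


@dataclass(frozen=True)
class GeneModelSpec:
    """Structure of one planted ilp gene.

    ``exon_lengths`` are coding-exon lengths in nucleotides (the stop
    codon is included in the last exon); all exon boundaries are
    codon-aligned (phase 0), a deliberate simplification.  For aIGF the
    archetype has exactly four coding exons and ``alt_splice_offset``
    marks, in nucleotides from the start of exon 3, where the
    alternatively spliced (arginine-rich) last part of that exon begins.
    """

    family: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    alt_splice_offset: int | None = None
    strand: str = "+"
    seven_cysteines: bool = False  # decapod-relaxin-like extra interior cysteine

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        if any(e <= 0 for e in self.exon_lengths) or any(i <= 0 for i in self.intron_lengths):
            raise ValueError("exon and intron lengths must be positive")
        if any(e % 3 for e in self.exon_lengths):
            raise ValueError(
                "exon lengths not multiple-consistent with reading frame "
                f"(got {self.exon_lengths}; phase-0 splicing requires multiples of 3)"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.family == "aIGF":
            if len(self.exon_lengths) != 4:
                raise ValueError("archetype aIGF gene has exactly 4 coding exons")
            if self.alt_splice_offset is None:
                raise ValueError("aIGF requires an alt_splice_offset")
            off = self.alt_splice_offset
            if not 0 < off < self.exon_lengths[2]:
                raise ValueError("alt_splice_offset must lie strictly inside exon 3")
            if off % 3:
                raise ValueError("alt_splice_offset must be codon-aligned")
        elif self.alt_splice_offset is not None:
            raise ValueError(f"{self.family} genes have no alternative splice site")
        if self.seven_cysteines and self.family != "relaxin":
            raise ValueError("the seventh-cysteine variant is a relaxin feature")


def gene_model_spec(
    family: str,
    strand: str = "+",
    intron_length: int = 180,
    seven_cysteines: bool = False,
) -> GeneModelSpec:
    """Default archetype spec for a family (see _BASE_LAYOUT)."""
    lay = _BASE_LAYOUT[family]
    if family == "aIGF":
        core2 = lay["gap2"] - lay["gap2"] // 2  # C-peptide part in exon 2
        exon1 = 3 * (_SIGNAL_LEN + lay["b0"] + 1 + lay["gap1"] + 1 + lay["gap2"] // 2)
        exon2 = 3 * (core2 + 2 + 3 + 1 + lay["gap5"] + 1)
        exon3 = 3 * (lay["ext1"] + lay["alt"])
        exon4 = 3 * lay["ext2"] + 3
        exons = (exon1, exon2, exon3, exon4)
        alt = 3 * lay["ext1"]
        introns = (intron_length,) * 3
    else:
        core2 = lay["gap2"] - lay["gap2"] // 2
        exon1 = 3 * (_SIGNAL_LEN + lay["b0"] + 1 + lay["gap1"] + 1 + lay["gap2"] // 2)
        exon2 = 3 * (core2 + 2 + 3 + 1 + lay["gap5"] + 1 + lay["ext"]) + 3
        exons = (exon1, exon2)
        alt = None
        introns = (intron_length,)
    return GeneModelSpec(
        family=family,
        exon_lengths=exons,
        intron_lengths=introns,
        alt_splice_offset=alt,
        strand=strand,
        seven_cysteines=seven_cysteines,
    )


# ---------------------------------------------------------------------------
# Protein and codon construction


def _segment_template(family: str, name: str, length: int) -> list[str | None]:
    """Deterministic per-family template for one variable segment.

    Entries are conserved residues or None (member-specific fill).  The
    template depends only on (family, segment name, length), so two
    members built from the same spec share exactly the conserved
    positions.
    """
    rng = _stable_rng("template", family, name, length)
    p = _CONSERVED[family]
    return [
        rng.choice(list(_FILLER)) if rng.random() < p else None for _ in range(length)
    ]


def _fill(template: list[str | None], rng: np.random.Generator) -> str:
    return "".join(
        a if a is not None else _FILLER[rng.integers(len(_FILLER))] for a in template
    )


def _signal_peptide(rng: np.random.Generator) -> str:
    core = "".join(_HYDROPHOBIC[rng.integers(len(_HYDROPHOBIC))] for _ in range(10))
    return "MK" + core + "AGA"


def _arginine_rich_segment(length: int) -> str:
    """Dibasic segment with two cysteines; every 10-window is >=60% R/K."""
    if length < 12:
        raise ValueError("arginine-rich segment needs >= 12 residues")
    base = "RRKRRSRRRK"
    seg = list((base * (length // len(base) + 1))[:length])
    seg[length // 3] = "C"
    seg[2 * length // 3] = "C"
    return "".join(seg)


def _gtv_exon_template(family: str, length: int) -> list[str | None]:
    """Last-coding-exon template carrying the GTVx1Px2(F/Y) consensus."""
    tmpl = _segment_template(family, "ext2", length)
    motif = "GTVAPSF"
    at = min(4, length - len(motif))
    for i, a in enumerate(motif):
        tmpl[at + i] = a if a not in "x" else None
    # x1/x2 positions of the consensus vary between members
    tmpl[at + 3] = None
    tmpl[at + 5] = None
    return tmpl


def _precursor_segments(spec: GeneModelSpec, rng: np.random.Generator) -> list[str]:
    """Per-exon amino-acid sequences of the (long-isoform) precursor."""
    fam = spec.family
    lay = _BASE_LAYOUT[fam]
    exon_aa = [e // 3 for e in spec.exon_lengths]
    exon_aa[-1] -= 1  # stop codon
    b0, gap1, gap5 = lay["b0"], lay["gap1"], lay["gap5"]
    head = _SIGNAL_LEN + b0 + 1 + gap1 + 1  # through C2
    cpep1 = exon_aa[0] - head
    cpep2 = exon_aa[1] - (2 + 3 + 1 + gap5 + 1 + (0 if fam == "aIGF" else lay["ext"]))
    gap2 = cpep1 + cpep2
    if cpep1 < 1 or cpep2 < 0 or not 5 <= gap2 <= 200:
        raise ValueError(
            f"{fam}: exon lengths leave an invalid C-peptide (gap {gap2})"
        )
    seven_at = gap2 // 2 if spec.seven_cysteines else None

    def cpep(n: int, offset: int) -> str:
        tmpl = _segment_template(fam, "cpep", gap2)[offset : offset + n]
        s = list(_fill(tmpl, rng))
        if seven_at is not None and offset <= seven_at < offset + n:
            s[seven_at - offset] = "C"
        return "".join(s)

    exon1 = (
        _signal_peptide(rng)
        + _fill(_segment_template(fam, "b0", b0), rng)
        + "C"
        + _fill(_segment_template(fam, "gap1", gap1), rng)
        + "C"
        + cpep(cpep1, 0)
    )
    exon2 = (
        cpep(cpep2, cpep1)
        + "CC"
        + _fill(_segment_template(fam, "a1", 3), rng)
        + "C"
        + _fill(_segment_template(fam, "gap5", gap5), rng)
        + "C"
    )
    if fam == "aIGF":
        ext1_aa = spec.alt_splice_offset // 3
        alt_aa = exon_aa[2] - ext1_aa
        exon3 = _fill(_segment_template(fam, "ext1", ext1_aa), rng) + _arginine_rich_segment(alt_aa)
        exon4 = _fill(_gtv_exon_template(fam, exon_aa[3]), rng)
        return [exon1, exon2, exon3, exon4]
    exon2 += _fill(_segment_template(fam, "ext", lay["ext"]), rng)
    return [exon1, exon2]


_CODONS: dict[str, list[str]] = {}
for _c in ("".join((a, b, c)) for a in "TCAG" for b in "TCAG" for c in "TCAG"):
    _aa = str(Seq(_c).translate())
    _CODONS.setdefault(_aa, []).append(_c)


def _encode(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[a][rng.integers(len(_CODONS[a]))] if a != "M" or i > 0 else "ATG"
        for i, a in enumerate(aa)
    )


def _random_dna(length: int, rng: np.random.Generator, gc: float = 0.40) -> str:
    if length == 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    letters = np.frombuffer(b"ATGC", dtype=np.uint8)
    return letters[rng.choice(4, size=length, p=p)].tobytes().decode()


def reference_panel() -> dict[str, str]:
    """Synthetic family reference proteins for classification.

    One representative member per family with a well-defined archetype;
    gonadulin is deliberately absent — in the classification rules its
    hallmark is uniform dissimilarity to every reference, so divergent
    short-extension precursors fall through to the gonadulin-candidate
    label rather than matching a gonadulin profile.
    """
    panel = {}
    for fam in ("insulin", "aIGF", "relaxin"):
        rng = _stable_rng("reference", fam)
        segs = _precursor_segments(gene_model_spec(fam), rng)
        panel[fam] = "".join(segs)
    return panel


# ---------------------------------------------------------------------------
# Gene construction


@dataclass
class GeneBuild:
    """One planted gene: genomic fragment, local features, isoforms."""

    gene_id: str
    family: str
    spec: GeneModelSpec
    genomic: str
    features: list[FeatureRecord]
    transcripts: list[SequenceRecord]  # spliced CDS (ATG..stop), mRNA sense
    proteins: dict[str, str]  # transcript id -> precursor protein


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def make_ilp_gene(spec: GeneModelSpec, seed: int, gene_id: str = "gene1") -> GeneBuild:
    """Build one gene: genomic sequence, exon features and isoforms.

    The encoded precursor satisfies the default framework pattern; aIGF
    genes yield two isoforms that differ only by the alternatively
    spliced last part of exon 3.
    """
    rng = _stable_rng("gene", seed, gene_id)
    exon_aa = _precursor_segments(spec, rng)
    exon_nt = [_encode(aa, rng) for aa in exon_aa]
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    exon_nt[-1] += stop
    for nt, want in zip(exon_nt, spec.exon_lengths):
        assert len(nt) == want, (len(nt), want)

    introns = []
    for ilen in spec.intron_lengths:
        fill = ilen - 4 - len(_INTRON_STOPPER)
        if fill < 0:
            raise ValueError(f"intron length {ilen} too short (< {4 + len(_INTRON_STOPPER)})")
        introns.append("GT" + _INTRON_STOPPER + _random_dna(fill, rng) + "AG")

    genomic_parts, exon_spans, pos = [], [], 0
    for i, nt in enumerate(exon_nt):
        genomic_parts.append(nt)
        exon_spans.append((pos + 1, pos + len(nt)))
        pos += len(nt)
        if i < len(introns):
            genomic_parts.append(introns[i])
            pos += len(introns[i])
    genomic = "".join(genomic_parts)
    glen = len(genomic)

    if spec.strand == "-":
        genomic = _revcomp(genomic)
        exon_spans = [(glen - e + 1, glen - s + 1) for s, e in reversed(exon_spans)]
        exon_order = list(reversed(range(len(exon_nt))))
    else:
        exon_order = list(range(len(exon_nt)))

    # isoforms
    cds_long = "".join(exon_nt)
    isoforms = {f"{gene_id}.t1": cds_long}
    if spec.family == "aIGF":
        off = spec.alt_splice_offset
        isoforms[f"{gene_id}.t2"] = (
            exon_nt[0] + exon_nt[1] + exon_nt[2][:off] + exon_nt[3]
        )

    features = [
        FeatureRecord(
            seqid=gene_id,
            type="gene",
            start=1,
            end=glen,
            strand=spec.strand,
            attributes={"ID": gene_id, "family": spec.family},
        )
    ]
    for tid in isoforms:
        features.append(
            FeatureRecord(
                seqid=gene_id,
                type="mRNA",
                start=1,
                end=glen,
                strand=spec.strand,
                attributes={"ID": tid, "Parent": gene_id, "family": spec.family},
            )
        )
        for k in range(len(exon_spans)):
            s, e = exon_spans[k]
            orig = exon_order[k]
            if tid.endswith(".t2") and orig == 2:
                # exon 3 of the short isoform stops at the alternative site
                off = spec.alt_splice_offset
                if spec.strand == "+":
                    e = s + off - 1
                else:
                    s = e - off + 1
            for ftype in ("exon", "CDS"):
                features.append(
                    FeatureRecord(
                        seqid=gene_id,
                        type=ftype,
                        start=s,
                        end=e,
                        strand=spec.strand,
                        attributes={
                            "ID": f"{tid}.{ftype.lower()}{orig + 1}",
                            "Parent": tid,
                        },
                    )
                )

    transcripts = [
        SequenceRecord(id=tid, residues=cds, alphabet="dna")
        for tid, cds in isoforms.items()
    ]
    proteins = {
        tid: str(Seq(cds).translate()).rstrip("*") for tid, cds in isoforms.items()
    }
    for tid, prot in proteins.items():
        pattern = (
            FrameworkPattern(allow_extra_cysteines=True)
            if spec.seven_cysteines
            else DEFAULT_PATTERN
        )
        if match_framework(prot, pattern) is None:
            raise AssertionError(f"generator invariant violated: {tid} lacks framework")
    return GeneBuild(
        gene_id=gene_id,
        family=spec.family,
        spec=spec,
        genomic=genomic,
        features=features,
        transcripts=transcripts,
        proteins=proteins,
    )


# ---------------------------------------------------------------------------
# Genome construction


@dataclass
class GenomeBuild:
    """A synthetic scaffold with planted gene clusters and full truth."""

    genome: SequenceRecord
    features: list[FeatureRecord]  # absolute 1-based coordinates
    genes: list[GeneBuild]
    gene_spans: list[tuple[int, int]]  # absolute coding-region spans, by gene
    intergenic_truth: list[list[int]]  # per cluster, planted distances


def make_genome(
    n_clusters: int,
    cluster_composition: tuple[str, ...] = ("gonadulin", "aIGF", "relaxin"),
    intergenic_distances: tuple[int, ...] = (15000, 30000),
    decoy_length: int = 1_000_000,
    seed: int = 0,
    min_orf_aa: int = 60,
    pattern: FrameworkPattern = DEFAULT_PATTERN,
    scaffold_id: str = "scaffold1",
) -> GenomeBuild:
    """Assemble a scaffold of decoy background with planted gene clusters.

    Cluster genes are separated by exactly ``intergenic_distances`` (gap
    between neighboring coding regions); decoy and intergenic background
    is 40% GC i.i.d. sequence, post-processed so that no ORF outside the
    planted genes matches the detector's framework pattern at
    ``min_orf_aa``.
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    if n_clusters and len(intergenic_distances) != len(cluster_composition) - 1:
        raise ValueError("need one intergenic distance per adjacent gene pair")
    rng = _stable_rng("genome", seed)

    genes: list[GeneBuild] = []
    cluster_parts: list[str] = []
    gene_offsets_in_cluster: list[list[tuple[int, int]]] = []
    for ci in range(n_clusters):
        parts, offsets, pos = [], [], 0
        for gi, fam in enumerate(cluster_composition):
            strand = "+" if rng.random() < 0.5 else "-"
            spec = gene_model_spec(fam, strand=strand)
            gene = make_ilp_gene(spec, seed=seed, gene_id=f"c{ci + 1}_{fam}{gi + 1}")
            genes.append(gene)
            offsets.append((pos, len(gene.genomic)))
            parts.append(gene.genomic)
            pos += len(gene.genomic)
            if gi < len(cluster_composition) - 1:
                d = intergenic_distances[gi]
                min_d = 50
                if d < min_d:
                    raise ValueError(f"intergenic distance {d} too short (< {min_d})")
                parts.append(_random_dna(d, rng))
                pos += d
        cluster_parts.append("".join(parts))
        gene_offsets_in_cluster.append(offsets)

    # split the decoy budget evenly around the clusters so neighboring
    # clusters stay far apart relative to intra-cluster distances
    n_chunks = n_clusters + 1
    base = decoy_length // n_chunks
    chunk_sizes = [base] * n_chunks
    chunk_sizes[-1] += decoy_length - base * n_chunks
    decoys = [_random_dna(s, rng) for s in chunk_sizes]

    genome_parts, gene_spans, pos = [], [], 0
    for ci in range(n_clusters):
        genome_parts.append(decoys[ci])
        pos += len(decoys[ci])
        for off, glen in gene_offsets_in_cluster[ci]:
            gene_spans.append((pos + off + 1, pos + off + glen))
        genome_parts.append(cluster_parts[ci])
        pos += len(cluster_parts[ci])
    genome_parts.append(decoys[-1])
    genome = "".join(genome_parts)

    genome = _scrub_decoy(genome, gene_spans, min_orf_aa, pattern)

    features: list[FeatureRecord] = []
    for gene, (gs, _ge) in zip(genes, gene_spans):
        for f in gene.features:
            features.append(
                FeatureRecord(
                    seqid=scaffold_id,
                    type=f.type,
                    start=gs + f.start - 1,
                    end=gs + f.end - 1,
                    strand=f.strand,
                    attributes=dict(f.attributes),
                )
            )
    record = SequenceRecord(id=scaffold_id, residues=genome, alphabet="dna")
    for gene, (gs, ge) in zip(genes, gene_spans):
        assert genome[gs - 1 : ge] == gene.genomic
    return GenomeBuild(
        genome=record,
        features=features,
        genes=genes,
        gene_spans=gene_spans,
        intergenic_truth=[list(intergenic_distances)] * n_clusters,
    )


def _scrub_decoy(
    genome: str,
    gene_spans: list[tuple[int, int]],
    min_orf_aa: int,
    pattern: FrameworkPattern,
    max_iter: int = 25,
) -> str:
    """Mutate background cysteines until no non-planted ORF matches.

    Framework hits whose ORF overlaps a planted gene are left alone (the
    genes themselves are spliced, so their full precursors never appear
    as genomic ORFs); for any other hit one framework cysteine outside
    the planted spans is changed to serine and the scan repeats.
    """
    seq = list(genome)
    for _ in range(max_iter):
        rec = SequenceRecord(id="g", residues="".join(seq), alphabet="dna")
        offending = []
        for orf in find_orfs(rec, min_aa=min_orf_aa):
            if any(s <= orf.end and orf.start <= e for s, e in gene_spans):
                continue
            m = match_framework(orf.aa_sequence, pattern)
            if m is not None:
                offending.append((orf, m))
        if not offending:
            return "".join(seq)
        for orf, m in offending:
            for aa_pos in m.positions:
                if orf.strand == "+":
                    nt = orf.start + 3 * (aa_pos - 1)
                else:
                    nt = orf.end - 3 * (aa_pos - 1) - 2
                if any(s <= nt + 2 and nt <= e for s, e in gene_spans):
                    continue  # codon touches a planted gene; try another cysteine
                # TGT/TGC -> AGT/AGC (Cys -> Ser) regardless of strand
                idx = nt - 1 if orf.strand == "+" else nt + 1
                seq[idx] = "A" if orf.strand == "+" else "T"
                break
            else:  # pragma: no cover - cannot happen: genes are spliced
                raise RuntimeError("framework hit entirely within planted exons")
    raise RuntimeError("decoy scrubbing did not converge")


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class PlantedTruth:
    """Per-read origin table for a simulated archive."""

    rows: list[dict] = field(default_factory=list)
    abundances: dict[str, float] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows, columns=["read_id", "transcript_id", "offset", "mate", "strand"]
        )


def tile_reads(
    transcript: SequenceRecord,
    read_length: int = 100,
    step: int = 3,
    id_prefix: str = "tile",
) -> tuple[list[ReadSpot], PlantedTruth]:
    """Deterministic single-end reads tiling a transcript end to end.

    Starts every ``step`` nt plus one final window flush with the 3' end,
    giving ~read_length/step-fold coverage with both termini covered —
    the regime in which a greedy assembler must reconstruct the full
    sequence exactly.
    """
    seq = transcript.residues
    if read_length > len(seq):
        raise ValueError("read_length exceeds transcript length")
    starts = list(range(0, len(seq) - read_length + 1, step))
    if starts[-1] != len(seq) - read_length:
        starts.append(len(seq) - read_length)
    spots, truth = [], PlantedTruth(abundances={transcript.id: 1.0})
    for i, s in enumerate(starts):
        sid = f"{id_prefix}{i + 1:06d}"
        spots.append(ReadSpot(sid, (seq[s : s + read_length],)))
        truth.rows.append(
            dict(read_id=sid, transcript_id=transcript.id, offset=s + 1, mate=1, strand="+")
        )
    return spots, truth


def simulate_reads(
    transcripts: list[SequenceRecord],
    abundances: list[float],
    n_spots: int,
    read_length: int = 100,
    paired: bool = False,
    error_rate: float = 0.0,
    insert_length: int = 250,
    seed: int = 0,
    id_prefix: str = "spot",
) -> tuple[list[ReadSpot], PlantedTruth]:
    """Simulate an archive of ``n_spots`` spots from a transcript mixture.

    Transcript choice is multinomial with the given weights; fragment
    start positions are uniform along each transcript.  Paired spots are
    forward/reverse with a fixed insert length (clamped to the
    transcript); with ``error_rate`` 0 every mate is an exact substring
    of its origin (reverse-complemented for minus-strand mates).
    """
    if len(transcripts) != len(abundances):
        raise ValueError("one abundance per transcript")
    if any(w <= 0 for w in abundances):
        raise ValueError("abundance weights must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be a probability")
    short = min(len(t.residues) for t in transcripts)
    if read_length > short:
        raise ValueError(
            f"read_length {read_length} exceeds shortest transcript ({short} nt)"
        )
    rng = _stable_rng("reads", seed, id_prefix)
    weights = np.asarray(abundances, dtype=float)
    weights = weights / weights.sum()
    choices = rng.choice(len(transcripts), size=n_spots, p=weights)

    spots: list[ReadSpot] = []
    truth = PlantedTruth(
        abundances={t.id: float(w) for t, w in zip(transcripts, weights)}
    )

    def mutate(read: str) -> str:
        if error_rate == 0:
            return read
        arr = list(read)
        for i in range(len(arr)):
            if rng.random() < error_rate:
                arr[i] = "ACGT"[(("ACGT".index(arr[i]) + 1 + rng.integers(3)) % 4)]
        return "".join(arr)

    for i, ti in enumerate(choices):
        t = transcripts[int(ti)]
        seq = t.residues
        spot_id = f"{id_prefix}{i + 1:06d}"
        if paired:
            ins = min(insert_length, len(seq))
            ins = max(ins, read_length)
            start = int(rng.integers(len(seq) - ins + 1))
            frag = seq[start : start + ins]
            m1 = mutate(frag[:read_length])
            m2 = mutate(_revcomp(frag[-read_length:]))
            spots.append(ReadSpot(spot_id, (m1, m2)))
            truth.rows.append(
                dict(read_id=f"{spot_id}/1", transcript_id=t.id, offset=start + 1,
                     mate=1, strand="+")
            )
            truth.rows.append(
                dict(read_id=f"{spot_id}/2", transcript_id=t.id,
                     offset=start + ins - read_length + 1, mate=2, strand="-")
            )
        else:
            start = int(rng.integers(len(seq) - read_length + 1))
            window = seq[start : start + read_length]
            strand = "+" if rng.random() < 0.5 else "-"
            read = mutate(window if strand == "+" else _revcomp(window))
            spots.append(ReadSpot(spot_id, (read,)))
            truth.rows.append(
                dict(read_id=spot_id, transcript_id=t.id, offset=start + 1,
                     mate=1, strand=strand)
            )
    return spots, truth
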