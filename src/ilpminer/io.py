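"""Readers and writers for FASTA, FASTQ, GFF3 and Newick.

All parsing of the standard dialects is delegated to Biopython
(FASTA/FASTQ), gffutils (GFF3 lines) and scikit-bio (Newick); this module
only adapts them to the pipeline's record types and enforces the
round-trip and referential-integrity guarantees the pipeline relies on.
"""

from __future__ import annotations

import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line
from skbio import TreeNode

from .records import FeatureRecord, ReadSpot, SequenceRecord

_MATE_SUFFIX = re.compile(r"/([12])$")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ParseError(f"{path}: not FASTA or FASTQ (first record line {line!r})")
    raise ParseError(f"{path}: empty file")


def parse_sequences(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Parse a FASTA or FASTQ file into SequenceRecords.

    Duplicate ids raise; malformed records raise naming the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq),
                    alphabet=alphabet,
                    description=desc,
                )
            )
    except ValueError as exc:  # biopython parse failures surface as ValueError
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_fastq(spots: Iterable[ReadSpot], path: str | Path) -> None:
    """Write spots as FASTQ; paired mates get /1 and /2 identifier suffixes."""
    with open(path, "w") as fh:
        for spot in spots:
            paired = len(spot.mates) == 2
            for i, mate in enumerate(spot.mates):
                rid = f"{spot.spot_id}/{i + 1}" if paired else spot.spot_id
                qual = spot.quality[i] if spot.quality else "I" * len(mate)
                fh.write(f"@{rid}\n{mate}\n+\n{qual}\n")


def parse_read_spots(path: str | Path) -> list[ReadSpot]:
    """Parse a FASTQ file, collapsing /1 and /2 mates into single spots.

    Mates of a pair must be adjacent in the file (as write_fastq emits
    them); an unpaired /1 or /2 read becomes a 1-mate spot.
    """
    path = Path(path)
    raw: list[tuple[str, int | None, str, str]] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        m = _MATE_SUFFIX.search(rec.id)
        base = _MATE_SUFFIX.sub("", rec.id) if m else rec.id
        mate_no = int(m.group(1)) if m else None
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        raw.append((base, mate_no, str(rec.seq), qual))

    spots: list[ReadSpot] = []
    i = 0
    while i < len(raw):
        base, mate_no, seq, qual = raw[i]
        if (
            mate_no == 1
            and i + 1 < len(raw)
            and raw[i + 1][0] == base
            and raw[i + 1][1] == 2
        ):
            _, _, seq2, qual2 = raw[i + 1]
            spots.append(ReadSpot(base, (seq, seq2), (qual, qual2)))
            i += 2
        else:
            spots.append(ReadSpot(base, (seq,), (qual,)))
            i += 1
    ids = Counter(s.spot_id for s in spots)
    dups = [k for k, v in ids.items() if v > 1]
    if dups:
        raise ParseError(f"{path}: duplicate spot id {dups[0]!r}")
    return spots


# ---------------------------------------------------------------------------
# GFF3


def parse_features(path: str | Path, sort: bool = False) -> list[FeatureRecord]:
    """Parse a GFF3 file; validates coordinates, strand and Parent links."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: malformed GFF3 line: {exc}") from exc
            if feat.start > feat.end:
                raise ParseError(f"{path}:{lineno}: start > end ({feat.start} > {feat.end})")
            attrs = {k: ",".join(v) for k, v in feat.attributes.items()}
            try:
                records.append(
                    FeatureRecord(
                        seqid=feat.seqid,
                        type=feat.featuretype,
                        start=feat.start,
                        end=feat.end,
                        strand=feat.strand or ".",
                        attributes=attrs,
                        source=feat.source or ".",
                        score=str(feat.score) if feat.score not in (None, "") else ".",
                        phase=str(feat.frame) if feat.frame not in (None, "") else ".",
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    ids = {r.id for r in records if r.id}
    for r in records:
        if r.parent is not None:
            for p in r.parent.split(","):
                if p not in ids:
                    raise ParseError(
                        f"{path}: feature {r.id or r.type!r} references missing Parent {p!r}"
                    )
    if sort:
        records.sort(key=lambda r: (r.seqid, r.start, r.end))
    return records


def _fmt_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_features(records: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.seqid,
                        r.source,
                        r.type,
                        str(r.start),
                        str(r.end),
                        r.score,
                        r.strand,
                        r.phase,
                        _fmt_attributes(r.attributes),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick

_NEWICK_UNSAFE = re.compile(r"[\s;,():\[\]']")


def serialize_tree(tree: TreeNode) -> str:
    """Serialize a (support-annotated) tree to a Newick string.

    Leaf labels must be unique and free of Newick metacharacters; internal
    node names carry bootstrap supports, following the common convention.
    """
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 leaves")
    dup = [k for k, v in Counter(tips).items() if v > 1]
    if dup:
        raise ValueError(f"duplicate leaf label {dup[0]!r}")
    for name in tips:
        if name is None or _NEWICK_UNSAFE.search(name):
            raise ValueError(f"leaf label {name!r} contains Newick metacharacters")
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length")
    import io as _io

    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def parse_tree(newick: str) -> TreeNode:
    import io as _io

    return TreeNode.read(_io.StringIO(newick))


def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str]) -> None:
    """Write a list of dict rows as a TSV with a fixed column order."""
    import pandas as pd

    pd.DataFrame(list(rows), columns=list(columns)).to_csv(path, sep="\t", index=False)
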