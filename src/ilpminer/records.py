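"""Core record types shared across the pipeline.

Coordinates are 1-based inclusive everywhere records cross a module
boundary, matching the GFF3 convention; any half-open arithmetic is kept
internal to the functions that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DNA_ALPHABET = set("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a file.
    residues : str
        Non-empty sequence over the declared alphabet (ambiguity codes
        allowed).
    alphabet : {"dna", "protein"}
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReadSpot:
    """One sequencing unit: a read pair or a single read.

    A spot with k mates contributes k countable *half spots*; the mate is
    the unit in which coding-sequence matches are counted, while archives
    are sized in spots.  ``quality`` optionally carries per-base Phred
    scores, one list per mate.
    """

    spot_id: str
    mates: tuple[str, ...]
    quality: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.spot_id:
            raise ValueError("spot_id must be non-empty")
        if not 1 <= len(self.mates) <= 2:
            raise ValueError(
                f"spot {self.spot_id!r}: expected 1 or 2 mates, got {len(self.mates)}"
            )
        if any(not m for m in self.mates):
            raise ValueError(f"spot {self.spot_id!r}: empty mate")
        if self.quality is not None and len(self.quality) != len(self.mates):
            raise ValueError(f"spot {self.spot_id!r}: quality/mate count mismatch")

    @property
    def n_half_spots(self) -> int:
        return len(self.mates)


@dataclass
class FeatureRecord:
    """One GFF3 feature line (1-based inclusive coordinates)."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = "ilpminer"
    score: str = "."
    phase: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"feature {self.attributes.get('ID', '?')}: invalid span "
                f"{self.start}..{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.type in ("gene", "mRNA", "CDS") and self.strand == ".":
            raise ValueError(f"{self.type} feature requires a defined strand")

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")

    def __len__(self) -> int:
        return self.end - self.start + 1
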