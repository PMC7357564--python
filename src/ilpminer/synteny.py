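"""Detection of clustered ilp-family genes on a scaffold.

The gonadulin, aIGF and relaxin genes sit next to one another in several
insect genomes (and gonadulin next to aIGF in spiders) — the signature
of an ancient local gene triplication.  This module chains neighboring
ilp-family loci into clusters by the gap between their coding regions
and labels the arrangement found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import FeatureRecord

logger = logging.getLogger(__name__)

ILP_FAMILIES = {"insulin", "aIGF", "gonadulin", "relaxin"}


@dataclass(frozen=True)
class GeneLocus:
    """A gene's coding-region extent (min/max over its CDS) on a scaffold."""

    gene_id: str
    family: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"locus {self.gene_id}: invalid span")
        if self.family not in ILP_FAMILIES | {"other"}:
            raise ValueError(f"locus {self.gene_id}: unknown family {self.family!r}")


@dataclass
class SyntenyCluster:
    """Consecutive ilp-family loci closer than max_gap, with distances."""

    loci: list[GeneLocus]
    distances: list[int]  # gap between consecutive coding regions
    label: str = ""

    @property
    def scaffold(self) -> str:
        return self.loci[0].scaffold

    @property
    def families(self) -> list[str]:
        return [l.family for l in self.loci]


def loci_from_features(features: list[FeatureRecord]) -> list[GeneLocus]:
    """Collapse GFF3 gene/CDS records into per-gene coding extents.

    The family label comes from the gene's ``family`` attribute (as the
    detector's annotated GFF3 output provides); genes without one are
    labelled "other" and never join an ilp cluster.
    """
    genes = {
        f.id: f for f in features if f.type == "gene" and f.id is not None
    }
    mrna_parent = {
        f.id: f.parent for f in features if f.type == "mRNA" and f.id is not None
    }
    cds_spans: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if f.type != "CDS" or f.parent is None:
            continue
        gene_id = mrna_parent.get(f.parent, f.parent)
        if gene_id in genes:
            cds_spans.setdefault(gene_id, []).append((f.start, f.end))
    loci = []
    for gid, g in genes.items():
        spans = cds_spans.get(gid, [(g.start, g.end)])
        loci.append(
            GeneLocus(
                gene_id=gid,
                family=g.attributes.get("family", "other"),
                scaffold=g.seqid,
                start=min(s for s, _ in spans),
                end=max(e for _, e in spans),
                strand=g.strand,
            )
        )
    return loci


def cluster_genes(loci: list[GeneLocus], max_gap: int = 1_000_000) -> list[SyntenyCluster]:
    """Single-linkage chaining of ilp loci along each scaffold.

    Consecutive ilp-family loci whose coding-region gap
    (start(i+1) - end(i) - 1) is <= ``max_gap`` join one cluster.
    Overlapping loci get distance 0 with a warning.
    """
    ilp = sorted(
        (l for l in loci if l.family in ILP_FAMILIES),
        key=lambda l: (l.scaffold, l.start, l.end, l.gene_id),
    )
    clusters: list[SyntenyCluster] = []
    current: list[GeneLocus] = []
    distances: list[int] = []
    for locus in ilp:
        if current and locus.scaffold == current[-1].scaffold:
            gap = locus.start - current[-1].end - 1
            if gap < 0:
                logger.warning(
                    "overlapping loci %s and %s; distance set to 0",
                    current[-1].gene_id,
                    locus.gene_id,
                )
                gap = 0
            if gap <= max_gap:
                current.append(locus)
                distances.append(gap)
                continue
        if current:
            clusters.append(_finish(current, distances))
        current, distances = [locus], []
    if current:
        clusters.append(_finish(current, distances))
    return clusters


def _finish(loci: list[GeneLocus], distances: list[int]) -> SyntenyCluster:
    c = SyntenyCluster(loci=list(loci), distances=list(distances))
    c.label = classify_cluster(c)
    return c


def classify_cluster(cluster: SyntenyCluster) -> str:
    """Label a cluster's family arrangement.

    A cluster holding gonadulin, aIGF and relaxin together is
    "triplication-like" (the ancestral triplication signature); a
    gonadulin/aIGF pair is "pair" (the arrangement seen in spiders);
    repeated copies of a single family are a "tandem-duplication"; one
    gene is a "singleton"; anything else is "other".
    """
    fams = set(cluster.families)
    if {"gonadulin", "aIGF", "relaxin"} <= fams:
        return "triplication-like"
    if fams == {"gonadulin", "aIGF"}:
        return "pair"
    if len(cluster.loci) >= 2 and len(fams) == 1:
        return "tandem-duplication"
    if len(cluster.loci) == 1:
        return "singleton"
    return "other"


def cluster_report(clusters: list[SyntenyCluster]) -> list[dict]:
    """TSV-ready rows: scaffold, ordered families, strands, distances, label."""
    return [
        {
            "scaffold": c.scaffold,
            "families": ",".join(c.families),
            "strands": ",".join(l.strand for l in c.loci),
            "distances": ",".join(str(d) for d in c.distances),
            "label": c.label,
        }
        for c in clusters
    ]
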