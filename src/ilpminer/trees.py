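"""Sequence similarity trees: alignment, distances, NJ and bootstrap.

Arthropod ilp precursors are too divergent for a defensible phylogeny —
outside the framework cysteines homologous positions cannot be
identified — so the pipeline builds *similarity* trees instead: align
the full, uncurated precursors, convert to p-distances, build a
neighbor-joining tree, and attach column-bootstrap supports to read how
reliably groups of precursors cluster.  Receptor trees use the same
machinery on filtered positions (well-aligned columns, or transmembrane
segments only for GPCRs).

All steps are deterministic given their inputs (and the bootstrap
seed): the guide tree, profile alignment, NJ tie-breaking and negative
branch handling follow fixed, documented rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from skbio import TreeNode

from .records import SequenceRecord

GAP = "-"

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_BLOSUM_ARR = np.zeros((len(_AA), len(_AA)))
for _i, _a in enumerate(_AA):
    for _j, _b in enumerate(_AA):
        _BLOSUM_ARR[_i, _j] = _BLOSUM[_a, _b]


@dataclass
class Alignment:
    """A multiple alignment: unique labels, equal-length gapped rows."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("one label per row")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate row labels")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.matrix, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.isfinite(d).all() or (d < 0).any():
            raise ValueError("distances must be finite and non-negative")
        self.matrix = d


# ---------------------------------------------------------------------------
# Progressive alignment


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, _AA_INDEX["X"]) for a in seq.upper()], dtype=int)


def _profile(rows: list[str]) -> np.ndarray:
    """Columns x (residues + gap) frequency profile."""
    n_sym = len(_AA) + 1
    ncol = len(rows[0])
    prof = np.zeros((ncol, n_sym))
    for row in rows:
        for j, a in enumerate(row):
            prof[j, len(_AA) if a == GAP else _AA_INDEX.get(a, _AA_INDEX["X"])] += 1
    return prof / len(rows)


def _profile_scores(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Expected BLOSUM62 score for every column pair (gaps score 0)."""
    ra, rb = pa[:, : len(_AA)], pb[:, : len(_AA)]
    return ra @ _BLOSUM_ARR @ rb.T


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    """Profile-profile global alignment with affine gaps (Gotoh)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = _profile_scores(pa, pb)
    n, m = S.shape
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in B (consume A column)
    Y = np.full((n + 1, m + 1), neg)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        X[i, 1:] = np.maximum(Mi1[1:] - gap_open, X[i - 1, 1:] - gap_extend)
        diag = np.maximum(np.maximum(Mi1[:-1], Xi1[:-1]), Yi1[:-1]) + S[i - 1]
        M[i, 1:] = diag
        # Y needs a left-to-right scan (depends on same-row values)
        row_best = np.maximum(M[i], X[i])
        y = neg
        for j in range(1, m + 1):
            y = max(row_best[j - 1] - gap_open, y - gap_extend)
            Y[i, j] = y
    # traceback mirroring the forward recurrences exactly
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    tol = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            out_a.append("col")
            out_b.append("col")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            out_a.append("col")
            out_b.append("gap")
            stay = abs(X[i, j] - (X[i - 1, j] - gap_extend)) < tol
            opened = abs(X[i, j] - (M[i - 1, j] - gap_open)) < tol
            state = 1 if stay and not opened else 0
            i -= 1
        else:
            out_a.append("gap")
            out_b.append("col")
            stay = abs(Y[i, j] - (Y[i, j - 1] - gap_extend)) < tol
            if stay and not (
                abs(Y[i, j] - (max(M[i, j - 1], X[i, j - 1]) - gap_open)) < tol
            ):
                state = 2
            else:
                state = 0 if M[i, j - 1] >= X[i, j - 1] else 1
            j -= 1
    out_a.reverse()
    out_b.reverse()

    def expand(rows: list[str], ops: list[str]) -> list[str]:
        res = [""] * len(rows)
        pos = 0
        for op in ops:
            if op == "col":
                for r in range(len(rows)):
                    res[r] += rows[r][pos]
                pos += 1
            else:
                for r in range(len(rows)):
                    res[r] += GAP
        return res

    return expand(rows_a, out_a), expand(rows_b, out_b)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_align(
    seqs: list[SequenceRecord], gap_open: float = 10.0, gap_extend: float = 0.5
) -> Alignment:
    """Guide-tree progressive multiple alignment (k-mer UPGMA guide,
    profile-profile Gotoh steps, BLOSUM62 expected scores).

    The similarity-tree protocol aligns the full precursors and performs
    no manual curation of the result.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for s in seqs:
        if not s.residues:
            raise ValueError(f"empty sequence {s.id!r}")
    if len({s.id for s in seqs}) != len(seqs):
        raise ValueError("duplicate sequence ids")
    n = len(seqs)
    # UPGMA guide tree on k-mer distances, deterministic tie-breaks
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i].residues, seqs[j].residues)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i].residues.upper()]) for i in range(n)
    }
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    nxt = n
    while len(clusters) > 1:
        (i, j), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        mi, mj = clusters.pop(i), clusters.pop(j)
        rows_i, rows_j = mi[1], mj[1]
        new_rows = _align_profiles(rows_i, rows_j, gap_open, gap_extend)
        merged = (mi[0] + mj[0], new_rows[0] + new_rows[1])
        for key in list(dist):
            if i in key or j in key:
                dist.pop(key)
        # average-linkage distances to the new cluster
        for k_ in clusters:
            members_k = clusters[k_][0]
            val = float(
                np.mean([d[x, y] for x in merged[0] for y in members_k])
            )
            dist[(min(k_, nxt), max(k_, nxt))] = val
        clusters[nxt] = merged
        sizes[nxt] = len(merged[0])
        nxt += 1
    order, rows = next(iter(clusters.values()))
    labels = [seqs[i].id for i in order]
    return Alignment(labels=labels, rows=rows)


def drop_gappy_rows(aln: Alignment, max_row_gap_fraction: float) -> Alignment:
    """Drop whole sequences whose gap fraction exceeds the threshold.

    The alternative reading of "only well aligned sequences were
    retained": filter sequences rather than columns.  Offered as an
    explicit choice with no default anywhere in the pipeline; the
    shipped analyses filter columns.
    """
    if not 0 <= max_row_gap_fraction <= 1:
        raise ValueError("threshold must be in [0, 1]")
    keep = [
        i
        for i, r in enumerate(aln.rows)
        if r.count(GAP) / len(r) <= max_row_gap_fraction
    ]
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 rows have gap fraction <= {max_row_gap_fraction}"
        )
    return Alignment(
        labels=[aln.labels[i] for i in keep], rows=[aln.rows[i] for i in keep]
    )


def filter_columns(aln: Alignment, max_gap_fraction: float) -> Alignment:
    """Keep only columns whose gap fraction <= threshold, order preserved."""
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("threshold must be in [0, 1]")
    nrow = len(aln.rows)
    keep = [
        j
        for j in range(aln.n_columns)
        if sum(r[j] == GAP for r in aln.rows) / nrow <= max_gap_fraction
    ]
    if not keep:
        raise ValueError(
            f"no column has gap fraction <= {max_gap_fraction}; nothing retained"
        )
    return Alignment(
        labels=list(aln.labels),
        rows=["".join(r[j] for j in keep) for r in aln.rows],
    )


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def pairwise_distance(aln: Alignment) -> DistanceMatrix:
    """p-distances: mismatches over positions ungapped in both rows."""
    n = len(aln.rows)
    arr = np.array([list(r) for r in aln.rows])
    gap = arr == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"rows {aln.labels[i]!r} and {aln.labels[j]!r} share no "
                    "comparable positions"
                )
            d[i, j] = d[j, i] = float((arr[i][ok] != arr[j][ok]).sum()) / total
    return DistanceMatrix(labels=list(aln.labels), matrix=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining with deterministic tie-breaking.

    The Q criterion picks the pair to join; ties are broken by the
    lexicographically smallest label pair.  Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch, the
    usual NJ correction.  Returns an unrooted tree (trifurcating root
    for > 2 taxa) as a scikit-bio TreeNode.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    if n == 2:
        root = TreeNode()
        a, b = (nodes[lab] for lab in labels)
        a.length = float(dm.matrix[0, 1])
        b.length = 0.0
        root.extend([a, b])
        return root
    active = list(labels)
    d = {
        (a, b): float(dm.matrix[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
    }
    joined = 0
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                q = (r - 2) * d[(a, b)] - totals[a] - totals[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d[(a, b)] + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = d[(a, b)] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        joined += 1
        parent = TreeNode(name=f"_nj{joined}")
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = float(la), float(lb)
        parent.extend([na, nb])
        new = f"_nj{joined}"
        nodes[new] = parent
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = max(
                0.0, 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            )
        active = [c for c in active if c not in (a, b)] + [new]
    a, b, c = sorted(active)
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    root = TreeNode()
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(lab)
        node.length = float(max(ln, 0.0))
        root.append(node)
    for node in root.traverse(include_self=False):
        if node.name and node.name.startswith("_nj"):
            node.name = None
    return root


# ---------------------------------------------------------------------------
# Bootstrap


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            parts.add(min(side, tips - side, key=sorted))
    return parts


def bootstrap_support(
    aln: Alignment, replicates: int = 100, seed: int = 0
) -> TreeNode:
    """NJ tree with column-bootstrap supports on internal branches.

    Columns are resampled with replacement ``replicates`` times; the
    support of an internal branch is the fraction of replicate trees
    containing the same bipartition of the leaf set.  Supports are
    stored as internal node names (the usual Newick convention),
    formatted with 3 decimals.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(pairwise_distance(aln))
    if len(aln.labels) <= 3:
        return tree  # no internal branches to support
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    counts: dict[frozenset, int] = {p: 0 for p in _bipartitions(tree)}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r[j] for j in cols) for r in aln.rows]
        rep = Alignment(labels=list(aln.labels), rows=rows)
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep))
        except ValueError:
            continue  # a replicate can lose all comparable positions
        parts = _bipartitions(rep_tree)
        for p in counts:
            if p in parts:
                counts[p] += 1
    tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            part = min(side, tips - side, key=sorted)
            node.name = f"{counts.get(part, 0) / replicates:.3f}"
    return tree


def support_of_clade(tree: TreeNode, members: set[str]) -> float | None:
    """Bootstrap support of the branch separating ``members``, if present."""
    tips = frozenset(t.name for t in tree.tips())
    want = frozenset(members)
    want = min(want, tips - want, key=sorted)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if min(side, tips - side, key=sorted) == want and node.name:
            return float(node.name)
    return None


# ---------------------------------------------------------------------------
# Transmembrane regions


def extract_tm_regions(
    protein: str, window: int = 19, hydropathy_min: float = 1.6
) -> tuple[str, list[tuple[int, int]]]:
    """Transmembrane-like segments by Kyte-Doolittle window hydropathy.

    Positions whose centered ``window``-wide mean hydropathy is
    >= ``hydropathy_min`` are grouped into maximal runs; each run is one
    segment (1-based inclusive spans over window centers), and segments
    are concatenated in sequence order — the position set GPCR trees are
    built from.
    """
    protein = protein.upper()
    n = len(protein)
    if n < window:
        raise ValueError("protein shorter than the hydropathy window")
    half = window // 2
    vals = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    centers = np.arange(half + 1, half + 1 + len(means))  # 1-based
    qualify = means >= hydropathy_min
    spans: list[tuple[int, int]] = []
    i = 0
    while i < len(qualify):
        if not qualify[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(qualify) and qualify[j + 1]:
            j += 1
        spans.append((int(centers[i]), int(centers[j])))
        i = j + 1
    concat = "".join(protein[s - 1 : e] for s, e in spans)
    return concat, spans


def similarity_tree(
    seqs: list[SequenceRecord],
    replicates: int = 100,
    seed: int = 0,
    max_gap_fraction: float | None = None,
    max_row_gap_fraction: float | None = None,
) -> TreeNode:
    """Full precursor similarity-tree pipeline: align, NJ, bootstrap.

    Both filters default to off (the uncurated similarity-tree
    protocol); ``max_gap_fraction`` filters columns,
    ``max_row_gap_fraction`` drops whole sequences.
    """
    aln = progressive_align(seqs)
    if max_row_gap_fraction is not None:
        aln = drop_gappy_rows(aln, max_row_gap_fraction)
    if max_gap_fraction is not None:
        aln = filter_columns(aln, max_gap_fraction)
    return bootstrap_support(aln, replicates=replicates, seed=seed)
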