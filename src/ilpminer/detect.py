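"""Insulin-framework precursor detection and family classification.

Insulin-like peptide (ilp) precursors are recognized by the conserved
arrangement of six cysteines that form the three disulfide bridges of the
insulin fold: two cysteines in the B chain, then — after the connecting
C peptide — an adjacent CC pair, a cysteine three residues later, and a
final cysteine in the A chain.  Families are told apart by what follows
the sixth cysteine: neuroendocrine insulins, gonadulins and relaxins end
almost immediately, while arthropod insulin-like growth factors (aIGFs)
carry a long C-terminal extension with an alternatively spliced
arginine-rich segment (two extra cysteines) and a GTVx1Px2(F/Y) consensus
motif in the last coding exon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .records import SequenceRecord

_ORF_RE = re.compile(r"M[^*]*\*")
_GTV_RE = re.compile(r"GTV.P.[FY]")
_SMALL_POLAR = set("AGSCT")


# ---------------------------------------------------------------------------
# ORF scanning


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a nucleotide source sequence.

    ``start``/``end`` are 1-based inclusive positions on the forward
    strand of the source, covering the ATG through the stop codon.
    """

    source_id: str
    frame: int  # 1..3 within the strand
    strand: str  # '+' or '-'
    aa_sequence: str
    start: int
    end: int


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_orfs(
    record: SequenceRecord, min_aa: int, all_starts: bool = False
) -> list[Orf]:
    """Scan all six frames for ORFs (ATG..stop) of >= min_aa residues.

    By default each stop codon yields one ORF starting at the first ATG
    after the previous in-frame stop; ``all_starts`` additionally reports
    nested ORFs from internal ATGs.  The stop codon is required and not
    part of ``aa_sequence``.
    """
    if record.alphabet != "dna":
        raise ValueError("find_orfs requires a nucleotide sequence")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(record.residues)
    orfs: list[Orf] = []
    for strand in "+-":
        seq = record.residues.upper() if strand == "+" else _revcomp(record.residues.upper())
        for frame in (1, 2, 3):
            sub = seq[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            protein = str(Seq(sub).translate())
            spans: list[tuple[int, int]] = []  # aa index of M, aa index of stop
            for m in _ORF_RE.finditer(protein):
                spans.append((m.start(), m.end() - 1))
                if all_starts:
                    inner = protein[m.start() + 1 : m.end() - 1]
                    off = m.start() + 1
                    j = inner.find("M")
                    while j != -1:
                        spans.append((off + j, m.end() - 1))
                        j = inner.find("M", j + 1)
            for aa_start, aa_stop in spans:
                aa_seq = protein[aa_start:aa_stop]
                if len(aa_seq) < min_aa:
                    continue
                # nucleotide span incl. stop codon, on the scanned strand
                s = (frame - 1) + 3 * aa_start
                e = (frame - 1) + 3 * (aa_stop + 1) - 1
                if strand == "+":
                    start, end = s + 1, e + 1
                else:
                    start, end = n - e, n - s
                orfs.append(Orf(record.id, frame, strand, aa_seq, start, end))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


# ---------------------------------------------------------------------------
# Cysteine framework


@dataclass(frozen=True)
class FrameworkPattern:
    """Spacing bounds between the six framework cysteines.

    ``gaps[i]`` bounds the number of residues strictly between framework
    cysteine i+1 and i+2; the adjacent CC pair is gap 0.  With
    ``allow_extra_cysteines`` additional cysteines between the first and
    sixth framework cysteine are recorded rather than disqualifying
    (a decapod relaxin variant carries such a seventh cysteine).
    """

    gaps: tuple[tuple[int, int], ...] = ((5, 40), (5, 200), (0, 0), (3, 3), (6, 30))
    allow_extra_cysteines: bool = False

    def __post_init__(self) -> None:
        if len(self.gaps) != 5:
            raise ValueError("a six-cysteine framework has exactly 5 spacing intervals")
        for lo, hi in self.gaps:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid gap interval ({lo}, {hi})")


DEFAULT_PATTERN = FrameworkPattern()
RELAXED_PATTERN = FrameworkPattern(allow_extra_cysteines=True)


@dataclass(frozen=True)
class FrameworkMatch:
    """Positions (1-based) of the six framework cysteines in a protein."""

    positions: tuple[int, int, int, int, int, int]
    extra_cysteines: tuple[int, ...]
    extension_length: int


def match_framework(protein: str, pattern: FrameworkPattern = DEFAULT_PATTERN) -> FrameworkMatch | None:
    """Find the leftmost six-cysteine framework match, or None.

    Leftmost means the lexicographically smallest tuple of framework
    cysteine positions among all satisfying assignments.
    """
    protein = protein.upper()
    cys = [i + 1 for i, a in enumerate(protein) if a == "C"]
    if len(cys) < 6:
        return None

    def search(chosen: list[int], next_idx: int) -> tuple[int, ...] | None:
        # depth-first in ascending position order: the first complete
        # assignment is the lexicographically smallest one
        if len(chosen) == 6:
            combo = tuple(chosen)
            extra = tuple(p for p in cys if combo[0] < p < combo[5] and p not in chosen)
            if extra and not pattern.allow_extra_cysteines:
                return None
            return combo
        lo, hi = pattern.gaps[len(chosen) - 1]
        for k in range(next_idx, len(cys)):
            gap = cys[k] - chosen[-1] - 1
            if gap > hi:
                break
            if gap < lo:
                continue
            chosen.append(cys[k])
            hit = search(chosen, k + 1)
            chosen.pop()
            if hit is not None:
                return hit
        return None

    for first in range(len(cys) - 5):
        combo = search([cys[first]], first + 1)
        if combo is not None:
            return FrameworkMatch(
                positions=combo,
                extra_cysteines=tuple(
                    p
                    for p in cys
                    if combo[0] < p < combo[5] and p not in set(combo)
                ),
                extension_length=len(protein) - combo[5],
            )
    return None


# ---------------------------------------------------------------------------
# Diagnostic motifs


def detect_gtv_motif(protein: str) -> tuple[int, int] | None:
    """Leftmost GTVx1Px2(F/Y) consensus occurrence, 1-based inclusive span."""
    m = _GTV_RE.search(protein.upper())
    if m is None:
        return None
    return (m.start() + 1, m.end())


def detect_arginine_rich(
    protein: str,
    window: int = 10,
    basic_fraction: float = 0.5,
    required_cys: int = 2,
) -> tuple[int, int] | None:
    """Find the dibasic (R/K-rich) alternatively spliced aIGF segment.

    Returns the maximal span in which every length-``window`` sub-window
    has an R+K fraction >= ``basic_fraction`` and which contains at least
    ``required_cys`` cysteines; None if no such span exists.  Reported
    spans are always at least ``window`` long.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    protein = protein.upper()
    n = len(protein)
    if n < window:
        return None
    basic = [1 if a in "RK" else 0 for a in protein]
    prefix = [0]
    for b in basic:
        prefix.append(prefix[-1] + b)
    need = basic_fraction * window
    ok = [
        (prefix[i + window] - prefix[i]) >= need - 1e-9 for i in range(n - window + 1)
    ]
    # maximal runs of qualifying window starts; span = union of their windows
    best: tuple[int, int] | None = None
    i = 0
    while i < len(ok):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(ok) and ok[j + 1]:
            j += 1
        span = (i + 1, j + window)  # 1-based inclusive
        n_cys = protein[span[0] - 1 : span[1]].count("C")
        if n_cys >= required_cys and (best is None or (span[1] - span[0]) > (best[1] - best[0])):
            best = span
        i = j + 1
    return best


# ---------------------------------------------------------------------------
# Signal peptide heuristic


def _window_hydropathy(protein: str, start: int, width: int) -> float:
    seg = protein[start : start + width]
    return sum(KYTE_DOOLITTLE.get(a, 0.0) for a in seg) / len(seg)


def predict_signal_peptide(
    protein: str,
    core_window: int = 7,
    core_hydropathy: float = 1.5,
    max_core_start: int = 30,
    max_cleavage: int = 40,
) -> int | None:
    """Heuristic signal-peptide call; returns the signal length or None.

    Looks for a hydrophobic core — a run of ``core_window``-wide windows
    with mean Kyte-Doolittle hydropathy >= ``core_hydropathy`` starting
    within the first ``max_core_start`` residues — then places the
    cleavage site at the first downstream position whose -1 and -3
    residues are small/polar ({A,G,S,C,T}), the classic (-3,-1) rule.
    The returned value is the 1-based position of the last signal
    residue.  Deliberately cruder than a trained predictor: it is a
    deterministic, local rule.
    """
    protein = protein.upper()
    if len(protein) < 20:
        return None
    n_windows = len(protein) - core_window + 1
    run_start = run_end = None
    for i in range(min(n_windows, max_core_start)):
        if _window_hydropathy(protein, i, core_window) >= core_hydropathy:
            if run_start is None:
                run_start = i
            run_end = i
        elif run_start is not None:
            break
    if run_start is None:
        return None
    core_end = run_end + 1  # 1-based window-start position of last qualifying window
    for p in range(core_end + 1, min(len(protein), max_cleavage) + 1):
        # mature peptide would start at position p+1; -1 is p, -3 is p-2
        if p - 2 >= 1 and protein[p - 1] in _SMALL_POLAR and protein[p - 3] in _SMALL_POLAR:
            return p
    return None


# ---------------------------------------------------------------------------
# Classification


@dataclass
class PrecursorAnnotation:
    """A candidate ilp precursor with its diagnostic evidence."""

    sequence_id: str
    framework: FrameworkMatch
    signal_cleavage: int | None = None
    arginine_rich_span: tuple[int, int] | None = None
    gtv_span: tuple[int, int] | None = None
    family: str = "unknown"
    scores: dict[str, float] = field(default_factory=dict)


def alignment_identity(
    a: str, b: str, match: int = 2, mismatch: int = -1, gap: int = -2
) -> float:
    """Normalized global-alignment identity between two proteins.

    Needleman-Wunsch with linear gap penalties; the returned value is the
    number of identically aligned residue pairs in the optimal alignment
    divided by the longer input length, giving a value in [0, 1] that is
    1.0 only for identical sequences.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    import numpy as np

    a, b = a.upper(), b.upper()
    la, lb = len(a), len(b)
    score = np.zeros((la + 1, lb + 1), dtype=np.int32)
    score[0, :] = gap * np.arange(lb + 1)
    score[:, 0] = gap * np.arange(la + 1)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, la + 1):
        sub = np.where(bb == ord(a[i - 1]), match, mismatch)
        diag = score[i - 1, :-1] + sub
        up = score[i - 1, 1:] + gap
        cand = np.maximum(diag, up)
        # left-gap dependency: score[i,j] = max_{k<=j}(u_k) + gap*j with
        # u_k = best score entering column k, resolved by a prefix max
        js = np.arange(1, lb + 1)
        t = np.maximum.accumulate(np.concatenate(([score[i, 0]], cand - gap * js)))
        score[i, 1:] = t[1:] + gap * js
    # traceback counting identities
    i, j, ident = la, lb, 0
    while i > 0 and j > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if score[i, j] == score[i - 1, j - 1] + s:
            ident += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif score[i, j] == score[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return ident / max(la, lb)


def classify_precursor(
    annotation: PrecursorAnnotation,
    reference_panel: dict[str, str],
    min_ext: int = 40,
    s_min: float = 0.5,
    protein: str | None = None,
) -> PrecursorAnnotation:
    """Assign an ilp family label from framework, motifs and similarity.

    Rules, in order: (1) a C-terminal extension of >= ``min_ext`` residues
    plus a GTV motif or arginine-rich segment is an aIGF; (2) otherwise
    the best reference-panel identity >= ``s_min`` assigns that family
    (ties broken by lexicographic family name); (3) otherwise a short
    extension with uniformly low similarity is a gonadulin candidate —
    divergence itself being the gonadulin signature — and anything else
    is left unknown.
    """
    if annotation.framework is None:
        raise ValueError("classification requires a framework match")
    if protein is not None and not annotation.scores:
        annotation.scores = {
            fam: alignment_identity(protein, ref)
            for fam, ref in sorted(reference_panel.items())
        }
    scores = annotation.scores
    ext = annotation.framework.extension_length
    if ext >= min_ext and (annotation.gtv_span or annotation.arginine_rich_span):
        annotation.family = "aIGF"
        return annotation
    best = max(scores.values(), default=0.0)
    if best >= s_min:
        annotation.family = min(f for f, s in scores.items() if s == best)
        return annotation
    if ext < min_ext and all(s < s_min for s in scores.values()):
        annotation.family = "gonadulin-candidate"
    else:
        annotation.family = "unknown"
    return annotation


def annotate_protein(
    seq_id: str,
    protein: str,
    pattern: FrameworkPattern = DEFAULT_PATTERN,
    reference_panel: dict[str, str] | None = None,
    min_ext: int = 40,
    s_min: float = 0.5,
) -> PrecursorAnnotation | None:
    """Full per-protein annotation: framework, motifs, signal, family."""
    fw = match_framework(protein, pattern)
    if fw is None:
        return None
    ext_seq = protein[fw.positions[5] :]
    gtv = detect_gtv_motif(ext_seq)
    if gtv is not None:
        gtv = (gtv[0] + fw.positions[5], gtv[1] + fw.positions[5])
    arg = detect_arginine_rich(ext_seq)
    if arg is not None:
        arg = (arg[0] + fw.positions[5], arg[1] + fw.positions[5])
    ann = PrecursorAnnotation(
        sequence_id=seq_id,
        framework=fw,
        signal_cleavage=predict_signal_peptide(protein),
        arginine_rich_span=arg,
        gtv_span=gtv,
    )
    if reference_panel is not None:
        classify_precursor(ann, reference_panel, min_ext=min_ext, s_min=s_min, protein=protein)
    return ann


def scan_sequences(
    records: list[SequenceRecord],
    min_aa: int = 60,
    pattern: FrameworkPattern = DEFAULT_PATTERN,
    reference_panel: dict[str, str] | None = None,
    min_ext: int = 40,
    s_min: float = 0.5,
) -> list[tuple[Orf | None, PrecursorAnnotation]]:
    """Detect precursors in protein records or in all ORFs of DNA records."""
    hits: list[tuple[Orf | None, PrecursorAnnotation]] = []
    for rec in records:
        if rec.alphabet == "protein":
            ann = annotate_protein(
                rec.id, rec.residues, pattern, reference_panel, min_ext, s_min
            )
            if ann is not None:
                hits.append((None, ann))
        else:
            for orf in find_orfs(rec, min_aa=min_aa):
                ann = annotate_protein(
                    f"{rec.id}:{orf.start}-{orf.end}({orf.strand})",
                    orf.aa_sequence,
                    pattern,
                    reference_panel,
                    min_ext,
                    s_min,
                )
                if ann is not None:
                    hits.append((orf, ann))
    return hits
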