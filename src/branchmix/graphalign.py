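"""Fragment-to-graph alignment.

Each FASTQ fragment is aligned in both orientations against every reference
path with affine-gap local (Smith-Waterman-Gotoh) alignment and the best
hit is projected back onto graph nodes and offsets, classifying every base
as match, mismatch, insertion, deletion, softclip or unresolved (N).
Mitogenome graphs are small enough that best-per-path alignment is exact
for path-realizable hits. Scores for all path/strand pairs come from a
compiled scan; the traceback for the single winning pair is delegated to
Biopython's PairwiseAligner with identical scoring.

Event coordinates follow the original fragment strand: `pos5`/`pos3` are
distances from the fragment's own 5' and 3' ends, which is the frame the
deamination model is indexed in.
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from Bio import Align, SeqIO
from numba import njit

from .refdb import PangenomeGraph

READ_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = np.full(256, 4, dtype=np.int8)  # N and anything else -> 4
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

EVENTS = ("match", "mismatch", "insertion", "deletion", "softclip", "unresolved")


class AlignmentError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _affine_local_score_int(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Best local alignment score and its target end position, integer
    scoring. A gap of length g costs gap_open + (g-1)*gap_extend."""
    m = t.size
    NEG = np.int64(-(10 ** 9))
    H = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, NEG, dtype=np.int64)
    best = np.int64(0)
    bj = 0
    for i in range(q.size):
        diag = np.int64(0)
        E = NEG
        qi = q[i]
        for j in range(1, m + 1):
            e2 = H[j - 1] + gap_open
            E = E + gap_extend
            if e2 > E:
                E = e2
            f2 = H[j] + gap_open
            fj = F[j] + gap_extend
            if f2 > fj:
                fj = f2
            F[j] = fj
            h = diag + (match if qi == t[j - 1] else mismatch)
            if E > h:
                h = E
            if fj > h:
                h = fj
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
                bj = j
    return best, bj


@njit(cache=True)
def _affine_local_score_float(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = t.size
    H = np.zeros(m + 1)
    F = np.full(m + 1, -1e18)
    best = 0.0
    bj = 0
    for i in range(q.size):
        diag = 0.0
        E = -1e18
        qi = q[i]
        for j in range(1, m + 1):
            E = max(H[j - 1] + gap_open, E + gap_extend)
            F[j] = max(H[j] + gap_open, F[j] + gap_extend)
            h = max(0.0, diag + (match if qi == t[j - 1] else mismatch), E, F[j])
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
                bj = j
    return best, bj


def affine_local_score(q, t, match, mismatch, gap_open, gap_extend):
    """Best local alignment score of query q vs target t (integer codes)
    with affine gaps; returns (score, target end position)."""
    if all(float(x).is_integer() for x in (match, mismatch, gap_open, gap_extend)):
        s, j = _affine_local_score_int(q, t, int(match), int(mismatch),
                                       int(gap_open), int(gap_extend))
        return float(s), j
    s, j = _affine_local_score_float(q, t, float(match), float(mismatch),
                                     float(gap_open), float(gap_extend))
    return s, j


@dataclass
class ReadRecord:
    """A sequenced fragment with per-base Phred+33 qualities."""

    id: str
    seq: str
    qual: str

    def __post_init__(self):
        self.seq = self.seq.upper()
        if len(self.seq) != len(self.qual):
            raise AlignmentError(f"read {self.id}: sequence/quality length mismatch")
        bad = set(self.seq) - READ_ALPHABET
        if bad:
            raise AlignmentError(f"read {self.id}: invalid characters {sorted(bad)}")

    @property
    def eps(self) -> np.ndarray:
        """Per-base error probability 10^(-Q/10), in (0, 1]."""
        q = np.frombuffer(self.qual.encode(), dtype=np.uint8).astype(float) - 33.0
        return np.power(10.0, -q / 10.0)


@dataclass
class AlignedBase:
    b: str               # fragment-strand base ('-' for deletions)
    eps: float
    event: str
    node: Optional[int]  # graph node id (match/mismatch/deletion only)
    offset: int          # 0-based offset within the node
    pos5: int            # distance from the fragment 5' end
    pos3: int            # distance from the fragment 3' end


@dataclass
class FragmentAlignment:
    read_id: str
    orientation: str     # '+' or '-'
    path: str            # best-scoring reference path label
    score: float
    bases: list[AlignedBase] = field(default_factory=list)


@dataclass
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0    # score of the first gapped position
    gap_extend: float = -1.0
    min_score_frac: float = 0.8

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner(mode="local")
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


def _path_cache(graph: PangenomeGraph) -> dict:
    cache = graph.__dict__.get("_align_cache")
    if cache is None or cache["labels"] != list(graph.paths):
        labels = list(graph.paths)  # insertion order = tree pre-order
        cache = {
            "labels": labels,
            "seqs": {lab: graph.path_sequence(lab) for lab in labels},
        }
        cache["codes"] = {lab: _encode(s) for lab, s in cache["seqs"].items()}
        cache["layout"] = {lab: graph.path_layout(lab) for lab in labels}
        graph.__dict__["_align_cache"] = cache
    return cache


def align_fragment(read: ReadRecord, graph: PangenomeGraph,
                   scoring: AlignScoring | None = None) -> Optional[FragmentAlignment]:
    """Align one fragment against every reference path in both orientations;
    return the projected best alignment or None when the best score falls
    below min_score_frac * read length. Ties are broken by path order (tree
    pre-order) and then by forward orientation."""
    if not graph.paths:
        raise AlignmentError("empty graph")
    scoring = scoring or AlignScoring()
    L = len(read.seq)
    if L < 1:
        raise AlignmentError(f"read {read.id}: empty sequence")

    cache = _path_cache(graph)
    qseqs = {"+": read.seq, "-": revcomp(read.seq)}
    qcodes = {ori: _encode(s) for ori, s in qseqs.items()}

    best = None  # (score, path rank, orientation rank)
    for rank, lab in enumerate(cache["labels"]):
        tcodes = cache["codes"][lab]
        for ori_rank, ori in enumerate("+-"):
            score, end = affine_local_score(qcodes[ori], tcodes, scoring.match,
                                            scoring.mismatch, scoring.gap_open,
                                            scoring.gap_extend)
            key = (-score, rank, ori_rank)
            if best is None or key < best[0]:
                best = (key, lab, ori, score, end)
    _, lab, ori, score, end = best
    if score <= 0 or score < scoring.min_score_frac * L:
        return None

    # traceback on a window around the scan's best end position; an optimal
    # local alignment cannot span more target than its score budget allows
    pseq = cache["seqs"][lab]
    aligner = scoring.aligner()
    w0 = max(0, end - 3 * L - 8)
    aln = aligner.align(pseq[w0:end], qseqs[ori])[0]
    if abs(aln.score - score) > 1e-6:  # defensive: fall back to the full path
        w0 = 0
        aln = aligner.align(pseq, qseqs[ori])[0]
        if abs(aln.score - score) > 1e-6:
            raise AlignmentError(f"read {read.id}: traceback score {aln.score} "
                                 f"!= scan score {score}")
    bases = _extract_events(read, qseqs[ori], ori, aln, cache, lab, w0)
    return FragmentAlignment(read.id, ori, lab, float(score), bases)


def _extract_events(read: ReadRecord, qseq: str, ori: str, aln,
                    cache: dict, lab: str, w0: int = 0) -> list[AlignedBase]:
    L = len(qseq)
    eps = read.eps
    layout = cache["layout"][lab]
    starts = [s for _, s in layout]
    node_ids = [n for n, _ in layout]
    pseq = cache["seqs"][lab]

    def project(t: int) -> tuple[int, int]:
        i = bisect_right(starts, t) - 1
        return node_ids[i], t - starts[i]

    tblocks, qblocks = aln.aligned
    events: list[tuple[float, AlignedBase]] = []  # (query position for ordering, base)

    def orig(qi: int) -> int:
        return qi if ori == "+" else L - 1 - qi

    def add_read_base(qi: int, event: str, node=None, offset=0):
        oi = orig(qi)
        b = read.seq[oi]
        if b == "N":
            event, node, offset = "unresolved", None, 0
        elif event == "insertion":
            node, offset = None, 0
        events.append((qi, AlignedBase(b, float(eps[oi]), event, node, offset, oi, L - 1 - oi)))

    qstart, qend = qblocks[0][0], qblocks[-1][1]
    for qi in range(0, qstart):
        add_read_base(qi, "softclip")
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if prev_t is not None:
            for qi in range(prev_q, q0):  # insertion: read bases without a node
                add_read_base(qi, "insertion")
            for t in range(prev_t, t0):   # deletion: path bases skipped by the read
                oi = orig(max(prev_q - 1, 0))
                node, off = project(t + w0)
                events.append((prev_q - 0.5, AlignedBase("-", 0.0, "deletion",
                                                         node, off, oi, L - 1 - oi)))
        for t, qi in zip(range(t0, t1), range(q0, q1)):
            node, off = project(t + w0)
            ev = "match" if qseq[qi] == pseq[t + w0] else "mismatch"
            add_read_base(qi, ev, node, off)
        prev_t, prev_q = t1, q1
    for qi in range(qend, L):
        add_read_base(qi, "softclip")

    events.sort(key=lambda e: e[0], reverse=(ori == "-"))
    return [b for _, b in events]


# ---------------------------------------------------------------------------
# FASTQ input
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[ReadRecord]:
    """Plain or gzipped FASTQ (single-end or interleaved merged pairs)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield ReadRecord(rec.id, str(rec.seq), qual)


def align_fastq(path, graph: PangenomeGraph,
                scoring: AlignScoring | None = None) -> list[FragmentAlignment]:
    out = []
    for read in read_fastq(path):
        aln = align_fragment(read, graph, scoring)
        if aln is not None:
            out.append(aln)
    return out


# ---------------------------------------------------------------------------
# Alignment table serialization (lossless TSV round-trip)
# ---------------------------------------------------------------------------

_TABLE_VERSION = "branchmix-alignments\tv1"
_COLUMNS = ["read_id", "orientation", "path", "score", "idx",
            "event", "base", "eps", "node", "offset", "pos5", "pos3"]


def serialize_alignments(alignments: list[FragmentAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{_TABLE_VERSION}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for a in alignments:
            for i, b in enumerate(a.bases):
                node = "" if b.node is None else str(b.node)
                fh.write(f"{a.read_id}\t{a.orientation}\t{a.path}\t{a.score!r}\t{i}\t"
                         f"{b.event}\t{b.b}\t{b.eps!r}\t{node}\t{b.offset}\t{b.pos5}\t{b.pos3}\n")


def read_alignments(path) -> list[FragmentAlignment]:
    out: list[FragmentAlignment] = []
    current = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != f"#{_TABLE_VERSION}":
            raise AlignmentError(f"unsupported alignment table version: {header!r}")
        cols = fh.readline().rstrip("\n").split("\t")
        if cols != _COLUMNS:
            raise AlignmentError("unexpected alignment table columns")
        for ln, line in enumerate(fh, 3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_COLUMNS):
                raise AlignmentError(f"truncated row at line {ln}")
            rid, ori, lab, score, idx, ev, b, eps, node, off, p5, p3 = parts
            if current is None or current.read_id != rid:
                current = FragmentAlignment(rid, ori, lab, float(score))
                out.append(current)
            current.bases.append(AlignedBase(b, float(eps), ev,
                                             int(node) if node else None,
                                             int(off), int(p5), int(p3)))
    return out
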