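"""Greedy seed-and-extend assembly, read mapping and consensus calling.

The workflow mirrors the classic long-read chloroplast strategy: filter
reads on length and per-read quality, seed a draft with the longest read,
extend both ends with the best-overlapping unused read until the two ends
either meet (circularization) or nothing extends, then map all reads back
onto the draft and call a per-column majority consensus.

Overlap scoring is gapless: match +1, mismatch -2.  Candidate overlaps
are found by exact k-mer seeding with a seed size small enough that no
overlap passing the identity filter can be missed (see ``_align``), so
the greedy choice equals exhaustive all-offset scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import (KmerIndex, best_gapless_placement, guaranteed_seed_size,
                     kmer_codes)
from ._seq import decode, encode, revcomp_arr
from .simulate import Read, ReadSet

__all__ = [
    "QCParams", "Overlap", "DraftAssembly", "Pileup",
    "filter_reads", "best_extension", "greedy_assemble",
    "map_reads", "call_consensus",
]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

# tolerance so that exact boundaries like 3 mismatches over 30 bp at 90%
# identity are not lost to binary floating point
IDENT_EPS = 1e-9


@dataclass(frozen=True)
class QCParams:
    """Read QC thresholds; both boundaries are inclusive."""

    min_read_len: int = 50
    min_quality: float = 0.75

    def __post_init__(self):
        if self.min_read_len < 1:
            raise ValueError("min_read_len must be >= 1")
        if not 0.0 <= self.min_quality <= 1.0:
            raise ValueError("min_quality must be in [0, 1]")


@dataclass(frozen=True)
class Overlap:
    read_id: str
    contig_end: str  # five_prime | three_prime
    overlap_len: int
    mismatches: int
    score: int
    extension_len: int
    orientation: str  # forward | reverse_complement


@dataclass
class DraftAssembly:
    sequence: str
    circular: bool = False
    ir_closed: bool = False
    used_read_ids: set = field(default_factory=set)
    extension_log: list = field(default_factory=list)

    def __len__(self):
        return len(self.sequence)


@dataclass
class Pileup:
    """Per-column A/C/G/T counts over the draft, plus read placements."""

    counts: np.ndarray  # shape (4, draft_len)
    placements: list  # (read_id, orientation, start, mismatches)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.counts.size else 0.0


def filter_reads(reads: ReadSet, params: QCParams = QCParams()) -> ReadSet:
    """Keep reads with length >= min_read_len and quality >= min_quality."""
    kept = tuple(r for r in reads
                 if len(r) >= params.min_read_len
                 and r.quality >= params.min_quality)
    return ReadSet(reads=kept)


class _ReadPool:
    """Encoded reads in both orientations plus a shared k-mer index."""

    def __init__(self, reads: ReadSet, k: int):
        self.reads = list(reads)
        self.fwd = [encode(r.sequence) for r in self.reads]
        self.rev = [revcomp_arr(a) for a in self.fwd]
        self.used = np.zeros(len(self.reads), dtype=bool)
        self.k = k
        self.index = KmerIndex(self.fwd, k, both_strands=True)
        self.max_len = max((a.size for a in self.fwd), default=0)

    def oriented(self, i: int, orient: int) -> np.ndarray:
        return self.fwd[i] if orient == 0 else self.rev[i]


def _best_ext3(contig: np.ndarray, pool: _ReadPool, min_overlap: int,
               min_identity: float):
    """Best 3' extension: (read_idx, orient, L, mm, score, ext) or None."""
    n = contig.size
    if n < min_overlap:
        return None
    w = min(n, pool.max_len)
    window = contig[n - w:]
    if window.size < pool.k:
        return None
    qpos, ridx, orients, rpos = pool.index.lookup(
        kmer_codes(window, pool.k))
    if qpos.size == 0:
        return None
    keep = ~pool.used[ridx]
    qpos, ridx, orients, rpos = (qpos[keep], ridx[keep],
                                 orients[keep], rpos[keep])
    # read (in its orient) starts at contig position s = p - j
    starts = (n - w + qpos) - rpos
    cand = np.unique(
        np.stack([ridx, orients.astype(np.int64), starts], axis=1), axis=0)
    best = None
    best_key = None
    for i, orient, s in cand:
        i, orient, s = int(i), int(orient), int(s)
        if s < 0:
            continue
        r = pool.oriented(i, orient)
        L = n - s
        ext = r.size - L
        if L < min_overlap or ext < 1:
            continue
        mm = int(np.count_nonzero(contig[s:] != r[:L]))
        if mm > (1.0 - min_identity) * L + IDENT_EPS:
            continue
        score = (L - mm) - 2 * mm
        rid = pool.reads[i].id
        # higher score, then longer extension, then smaller id, fwd first
        key = (score, ext, _NegStr(rid), -orient)
        if best_key is None or key > best_key:
            best_key = key
            best = (i, orient, L, mm, score, ext)
    return best


class _NegStr:
    """Wrapper so that *smaller* strings compare as larger in a max-key."""

    __slots__ = ("s",)

    def __init__(self, s):
        self.s = s

    def __gt__(self, other):
        return self.s < other.s

    def __eq__(self, other):
        return self.s == other.s

    def __lt__(self, other):
        return self.s > other.s


def best_extension(contig: str, end: str, reads: ReadSet,
                   min_overlap: int = 50, min_identity: float = 0.90,
                   _pool: _ReadPool | None = None) -> Overlap | None:
    """Best-scoring terminal overlap extending the contig at one end.

    Evaluates every read in both orientations at every gapless offset
    (via exhaustive-equivalent seeding); qualifying overlaps need
    overlap_len >= min_overlap, identity >= min_identity and at least one
    novel base.  Ties break toward the longer extension, then the
    lexicographically smallest read id.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if end not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown contig end {end!r}")
    pool = _pool
    if pool is None:
        k = guaranteed_seed_size(min_overlap, 1.0 - min_identity)
        pool = _ReadPool(reads, k)
    arr = encode(contig)
    if end == FIVE_PRIME:
        arr = revcomp_arr(arr)
    hit = _best_ext3(arr, pool, min_overlap, min_identity)
    if hit is None:
        return None
    i, orient, L, mm, score, ext = hit
    if end == FIVE_PRIME:
        orient = 1 - orient  # orientation is relative to the forward contig
    return Overlap(read_id=pool.reads[i].id, contig_end=end,
                   overlap_len=L, mismatches=mm, score=score,
                   extension_len=ext,
                   orientation="forward" if orient == 0
                   else "reverse_complement")


def _self_circular_overlap(contig: np.ndarray, min_overlap: int,
                           min_identity: float, max_l: int, k: int):
    """Best end-to-end overlap of the contig with itself (suffix vs
    prefix); returns (L, mm) or None.

    Candidate overlap lengths are found by shared k-mers between the
    prefix and suffix windows (exhaustive-equivalent for qualifying
    overlaps, same pigeonhole argument as read seeding).
    """
    n = contig.size
    w = min(max_l, n - min_overlap)
    if w < min_overlap or w < k:
        return None
    prefix = contig[:w]
    suffix = contig[n - w:]
    pc = kmer_codes(prefix, k)
    sc = kmer_codes(suffix, k)
    order = np.argsort(sc, kind="stable")
    sc_sorted = sc[order]
    lo = np.searchsorted(sc_sorted, pc, side="left")
    hi = np.searchsorted(sc_sorted, pc, side="right")
    ls = set()
    for j, (a, b) in enumerate(zip(lo, hi)):
        for t in order[np.arange(a, b)] if b > a else ():
            # prefix pos j aligns with global pos n - w + t
            L = w - int(t) + j
            if min_overlap <= L <= w:
                ls.add(L)
    best = None
    for L in sorted(ls):
        mm = int(np.count_nonzero(contig[n - L:] != contig[:L]))
        if mm <= (1.0 - min_identity) * L + IDENT_EPS:
            score = (L - mm) - 2 * mm
            if best is None or score > best[0]:
                best = (score, L, mm)
    if best is None:
        return None
    return best[1], best[2]


def _novel_rc_anchor(novel: np.ndarray, contig: np.ndarray, k: int,
                     min_overlap: int, min_identity: float):
    """Detect reverse-complement duplication of draft content by a
    candidate's novel sequence (entry into the second inverted-repeat
    copy).

    Returns (j0, q) or None: j0 is the first novel index lying inside
    the duplicated region, and q the contig index such that
    novel[j] == complement(contig[q - (j - j0)]) along the matched
    diagonal -- the anchor used to complete the circle by mirroring.
    """
    if novel.size < min_overlap:
        return None
    rc = revcomp_arr(novel)
    codes = kmer_codes(rc, k)
    if codes.size == 0:
        return None
    cidx = KmerIndex([contig], k, both_strands=False)
    qpos, _, _, tpos = cidx.lookup(codes)
    if qpos.size == 0:
        return None
    budget = 1.0 - min_identity
    best = None  # (window_matches, dd, i0, i1)
    for d in np.unique(tpos - qpos):
        d = int(d)
        lo = max(0, -d)
        hi = min(rc.size, contig.size - d)
        if hi - lo < min_overlap:
            continue
        neq = rc[lo:hi] != contig[lo + d:hi + d]
        mism = np.flatnonzero(neq)
        span = hi - lo
        edges = np.concatenate([[-1], mism, [span]])
        for c in range(int(budget * span + IDENT_EPS) + 1):
            if c + 1 >= edges.size:
                break
            diffs = edges[c + 1:] - edges[:-(c + 1)]
            j = int(diffs.argmax())
            wl = int(diffs[j]) - 1
            if wl >= min_overlap and c <= budget * wl + IDENT_EPS:
                i0 = lo + int(edges[j]) + 1
                i1 = i0 + wl
                matches = wl - c
                if best is None or matches > best[0]:
                    best = (matches, d, i0, i1)
    if best is None:
        return None
    _, dd, i0, i1 = best
    # rc window [i0, i1) maps to novel window [len-i1, len-i0)
    j0 = novel.size - i1
    q = dd + novel.size - 1 - j0
    return j0, q


def greedy_assemble(reads: ReadSet, min_overlap: int = 50,
                    min_identity: float = 0.90,
                    qc: QCParams | None = QCParams()) -> DraftAssembly:
    """Seed-and-extend greedy assembly of one circular or linear contig.

    The longest QC-passing read seeds the draft; the 3' and 5' ends are
    extended alternately with the best-scoring unused overlap.  An end
    terminates when (a) nothing extends, or (b) the chosen candidate's
    novel sequence reverse-complement-matches draft sequence already
    laid down over >= min_overlap bases -- the signature of running into
    the far boundary of the second inverted-repeat copy (``ir_closed``).
    Assembly stops when the two ends overlap each other by >=
    min_overlap at >= min_identity; the duplicated junction is trimmed
    once (keeping the 5' copy) and the contig is circular.  When both
    ends terminate at the second IR copy, the circle is completed by
    mirroring: the yet-unwalked stretch is the reverse complement of
    draft sequence between the two termination anchors.
    """
    filtered = filter_reads(reads, qc) if qc is not None else reads
    if len(filtered) == 0:
        raise ValueError("no usable reads")
    k = guaranteed_seed_size(min_overlap, 1.0 - min_identity)
    pool = _ReadPool(filtered, k)
    seed_idx = max(range(len(pool.reads)),
                   key=lambda i: (pool.fwd[i].size, _NegStr(
                       pool.reads[i].id)))
    pool.used[seed_idx] = True
    contig = pool.fwd[seed_idx].copy()
    draft = DraftAssembly(sequence="", circular=False, ir_closed=False,
                          used_read_ids={pool.reads[seed_idx].id})
    active = {THREE_PRIME: True, FIVE_PRIME: True}
    anchors: dict[str, tuple[int, int]] = {}  # end -> (q_fwd, lshift_then)
    lshift = 0
    max_self = 3 * max(pool.max_len, min_overlap)
    while any(active.values()):
        for end in (THREE_PRIME, FIVE_PRIME):
            if not active[end]:
                continue
            circ = _self_circular_overlap(contig, min_overlap,
                                          min_identity, max_self, k)
            if circ is not None:
                L, _ = circ
                contig = contig[:contig.size - L]  # keep the 5' copy
                draft.circular = True
                active = {THREE_PRIME: False, FIVE_PRIME: False}
                break
            arr = contig if end == THREE_PRIME else revcomp_arr(contig)
            hit = _best_ext3(arr, pool, min_overlap, min_identity)
            if hit is None:
                active[end] = False
                continue
            i, orient, L, mm, score, ext = hit
            r = pool.oriented(i, orient)
            novel = r[r.size - ext:]
            anchor = _novel_rc_anchor(novel, arr, k, min_overlap,
                                      min_identity)
            if anchor is not None:
                # entering the second IR copy: lay down any unique lead-in
                # of the novel sequence, record the mirror anchor, stop
                j0, q_loc = anchor
                lead = novel[:j0]
                if end == THREE_PRIME:
                    contig = np.concatenate([contig, lead])
                    q_fwd = q_loc
                else:
                    contig = np.concatenate([revcomp_arr(lead), contig])
                    lshift += lead.size
                    # q_loc indexes the reverse-complemented contig
                    # (before the prepend); mirror into forward coords
                    q_fwd = (contig.size - lead.size) - 1 - q_loc \
                        + lead.size
                draft.ir_closed = True
                anchors[end] = (q_fwd, lshift)
                active[end] = False
                continue
            if end == THREE_PRIME:
                contig = np.concatenate([contig, novel])
                out_orient = orient
            else:
                contig = np.concatenate([revcomp_arr(novel), contig])
                lshift += novel.size
                out_orient = 1 - orient
            pool.used[i] = True
            rid = pool.reads[i].id
            draft.used_read_ids.add(rid)
            draft.extension_log.append(Overlap(
                read_id=rid, contig_end=end, overlap_len=L,
                mismatches=mm, score=score, extension_len=ext,
                orientation="forward" if out_orient == 0
                else "reverse_complement"))
    if not draft.circular and len(anchors) == 2:
        (q3, ls3) = anchors[THREE_PRIME]
        (q5, ls5) = anchors[FIVE_PRIME]
        q3 += lshift - ls3
        q5 += lshift - ls5
        if 0 <= q5 < q3 < contig.size:
            missing = revcomp_arr(contig[q5:q3 + 1])
            contig = np.concatenate([contig, missing])
            draft.circular = True
    draft.sequence = decode(contig)
    return draft


def map_reads(reads: ReadSet, draft: DraftAssembly,
              min_identity: float = 0.90) -> Pileup:
    """Place each read at its best gapless position on the draft.

    Circular drafts are doubled so reads may wrap the origin; placements
    are normalized modulo the draft length.  Reads whose best placement
    falls below ``min_identity`` are discarded.  Ties break toward more
    matches, then the forward strand, then the smaller start.
    """
    n = len(draft.sequence)
    if n == 0:
        raise ValueError("empty draft")
    arr = encode(draft.sequence)
    target = np.concatenate([arr, arr]) if draft.circular else arr
    min_read = min((len(r) for r in reads), default=50)
    k = guaranteed_seed_size(max(min_read, 20), 1.0 - min_identity)
    index = KmerIndex([target], k, both_strands=True)
    counts = np.zeros((4, n), dtype=np.int64)
    placements = []
    for r in reads:
        q = encode(r.sequence)
        if q.size > target.size:
            continue
        hit = best_gapless_placement(q, target, index, min_identity)
        if hit is None:
            continue
        orient, start, mm = hit
        if draft.circular and start >= n:
            start -= n
        qq = q if orient == 0 else revcomp_arr(q)
        cols = (start + np.arange(qq.size)) % n
        np.add.at(counts, (qq, cols), 1)
        placements.append((r.id,
                           "forward" if orient == 0
                           else "reverse_complement", start, mm))
    return Pileup(counts=counts, placements=placements)


def call_consensus(pileup: Pileup, draft: DraftAssembly) -> str:
    """Per-column majority base; ties break A < C < G < T; zero-depth
    columns keep the draft base."""
    n = len(draft.sequence)
    if pileup.counts.shape[1] != n:
        raise ValueError("pileup does not match draft length")
    if n == 0:
        return ""
    winner = pileup.counts.argmax(axis=0).astype(np.uint8)
    depth = pileup.depth
    arr = encode(draft.sequence)
    out = np.where(depth > 0, winner, arr).astype(np.uint8)
    return decode(out)
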