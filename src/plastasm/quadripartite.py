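"""Inverted-repeat detection and LSC/SSC/IR partitioning of a circle.

A land-plant plastome carries two long exact inverted-repeat copies (IRa,
IRb) separating a large and a small single-copy region.  ``find_ir_pair``
locates the longest exact inverted-repeat pair on the circle (rolling-hash
binary search over the doubled sequence), ``partition_regions`` names the
two single-copy arcs by length, ``canonicalize`` rotates and orients the
genome into the conventional LSC-IRa-SSC-IRb layout, and ``region_stats``
reports per-region length and GC content at table precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp, round_half_up

__all__ = ["IRPair", "RegionPartition", "find_ir_pair",
           "partition_regions", "canonicalize", "region_stats"]

@dataclass(frozen=True)
class IRPair:
    """0-based half-open circular coordinates of the two IR copies."""

    ira_start: int
    ira_end: int
    irb_start: int
    irb_end: int
    length: int


@dataclass(frozen=True)
class RegionPartition:
    """Intervals of LSC, SSC, IRa, IRb on the circle (may wrap)."""

    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    irb: tuple[int, int]
    genome_len: int

    def length(self, name: str) -> int:
        a, b = getattr(self, name)
        n = self.genome_len
        return (b - a) % n if (b - a) % n or a == b else n

    @property
    def lengths(self) -> dict[str, int]:
        return {n: self.length(n) for n in ("lsc", "ssc", "ira", "irb")}


def _vec_pow(base: int, exps: np.ndarray, mod: int) -> np.ndarray:
    """Vectorized base**exps % mod for uint64 exponent arrays."""
    result = np.ones(exps.size, dtype=np.uint64)
    b = base % mod
    e = exps.astype(np.uint64).copy()
    m = np.uint64(mod)
    while e.max(initial=0):
        odd = (e & np.uint64(1)).astype(bool)
        result[odd] = (result[odd] * np.uint64(b)) % m
        b = (b * b) % mod
        e >>= np.uint64(1)
    return result


def _window_hashes_fast(arr: np.ndarray, length: int) -> np.ndarray:
    """Polynomial hashes of every window of ``length``, two prime moduli
    folded into one uint64 key.  Exact in uint64: all residues < 2^31 and
    prefix sums stay below 2^50 for sequences up to ~1 Mb."""
    n = arr.size
    if n < length:
        return np.empty(0, dtype=np.uint64)
    nw = n - length + 1
    out = []
    for mod, base in ((2147483647, 131), (2147483629, 137)):
        m = np.uint64(mod)
        a = arr.astype(np.uint64) + np.uint64(1)
        exps = (n - 1 - np.arange(n)).astype(np.uint64)
        pw = _vec_pow(base, exps, mod)
        vals = (a * pw) % m
        pref = np.zeros(n + 1, dtype=np.uint64)
        np.cumsum(vals, out=pref[1:])  # < 2^50, no overflow
        wsum = (pref[length:] - pref[:-length]) % m
        inv_base = pow(base, mod - 2, mod)
        norm = _vec_pow(inv_base,
                        (n - length - np.arange(nw)).astype(np.uint64), mod)
        out.append((wsum * norm) % m)
    return (out[0] << np.uint64(32)) | out[1]


def _circ_disjoint(a0: int, a1: int, b0: int, b1: int, n: int) -> bool:
    """Are circular intervals [a0,a1) and [b0,b1) (lengths < n) disjoint?"""
    def covers(x0, x1, p):
        if x0 <= x1:
            return x0 <= p < x1
        return p >= x0 or p < x1
    for p in (b0, (b1 - 1) % n):
        if covers(a0 % n, a1 % n, p):
            return False
    for p in (a0 % n, (a1 - 1) % n):
        if covers(b0 % n, b1 % n, p):
            return False
    return True


def _ir_pairs_at(arr: np.ndarray, rc: np.ndarray, n: int, length: int):
    """All disjoint inverted-repeat pairs of exactly ``length`` on the
    circle; yields (a, b) with a <= b (starts of the two copies)."""
    if length > n // 2 or length < 1:
        return []
    d = np.concatenate([arr, arr[:length - 1]]) if length > 1 else arr
    u = np.concatenate([rc, rc[:length - 1]]) if length > 1 else rc
    hd = _window_hashes_fast(d, length)[:n]
    hu = _window_hashes_fast(u, length)[:n]
    order = np.argsort(hu, kind="stable")
    hu_sorted = hu[order]
    lo = np.searchsorted(hu_sorted, hd, side="left")
    hi = np.searchsorted(hu_sorted, hd, side="right")
    pairs = []
    dd = np.concatenate([arr, arr])
    for a in np.flatnonzero(hi > lo):
        a = int(a)
        for t in order[lo[a]:hi[a]]:
            # window of RC(circle) starting at t covers circle start b:
            b = (n - int(t) - length) % n
            if a > b:
                continue
            if not _circ_disjoint(a, a + length, b, b + length, n):
                continue
            # verify exactly (hash collisions)
            w1 = dd[a:a + length]
            w2 = dd[b:b + length]
            if np.array_equal(w1, np.array([3, 2, 1, 0],
                                           dtype=np.uint8)[w2[::-1]]):
                pairs.append((a, b))
    return pairs


def find_ir_pair(sequence: str, min_ir_len: int = 1000) -> IRPair | None:
    """Longest exact inverted-repeat pair with disjoint intervals on the
    circle; ties break toward the smallest IRa start.

    Binary search on repeat length with rolling hashes over the doubled
    sequence; all candidate pairs are verified exactly.
    """
    n = len(sequence)
    if n < 2 * min_ir_len or min_ir_len < 1:
        return None
    arr = encode(sequence)
    rc = encode(revcomp(sequence))
    lo, hi = min_ir_len, n // 2
    best_len = None
    while lo <= hi:
        mid = (lo + hi) // 2
        if _ir_pairs_at(arr, rc, n, mid):
            best_len = mid
            lo = mid + 1
        else:
            hi = mid - 1
    if best_len is None:
        return None
    pairs = _ir_pairs_at(arr, rc, n, best_len)
    a, b = min(pairs)
    return IRPair(ira_start=a, ira_end=a + best_len,
                  irb_start=b, irb_end=b + best_len, length=best_len)


def partition_regions(sequence: str, ir: IRPair) -> RegionPartition:
    """Name the two single-copy arcs between the IR copies by length.

    The longer arc becomes LSC, the shorter SSC; zero-length arcs are
    permitted (degenerate circles).  Region lengths always sum to the
    genome length.
    """
    n = len(sequence)

    def norm(start, length):
        a = start % n
        b = a + length
        return (a, b if b <= n else b - n)

    len1 = (ir.irb_start - ir.ira_end) % n
    len2 = (ir.ira_start - ir.irb_end) % n
    arc1 = norm(ir.ira_end, len1)    # after the first copy
    arc2 = norm(ir.irb_end, len2)    # after the second copy
    if len1 >= len2:
        # LSC is the arc after the first copy, so the copy *following*
        # the LSC (labelled IRa by convention) is the second one
        lsc, ssc = arc1, arc2
        ira = norm(ir.irb_start, ir.length)
        irb = norm(ir.ira_start, ir.length)
    else:
        lsc, ssc = arc2, arc1
        ira = norm(ir.ira_start, ir.length)
        irb = norm(ir.irb_start, ir.length)
    return RegionPartition(lsc=lsc, ssc=ssc, ira=ira, irb=irb,
                           genome_len=n)


def _slice_circ(seq: str, iv: tuple[int, int]) -> str:
    a, b = iv
    n = len(seq)
    a, b = a % n, b % n
    return seq[a:b] if a <= b else seq[a:] + seq[:b]


def canonicalize(sequence: str,
                 partition: RegionPartition) -> tuple[str, RegionPartition]:
    """Rotate/orient the circle into LSC-IRa-SSC-IRb with LSC at 0.

    The strand is fixed by requiring the SSC to be lexicographically <=
    its reverse complement, so any rotation or reflection of the same
    circle canonicalizes to the identical byte string.
    """
    lsc = _slice_circ(sequence, partition.lsc)
    ira = _slice_circ(sequence, partition.ira)
    ssc = _slice_circ(sequence, partition.ssc)
    irb = _slice_circ(sequence, partition.irb)
    if ssc <= revcomp(ssc):
        seq = lsc + ira + ssc + irb
        l, i, s = len(lsc), len(ira), len(ssc)
    else:
        # traverse the circle on the other strand: region order reverses
        # and each region's content is reverse-complemented
        seq = revcomp(lsc) + revcomp(irb) + revcomp(ssc) + revcomp(ira)
        l, i, s = len(lsc), len(irb), len(ssc)
    n = len(sequence)
    part = RegionPartition(lsc=(0, l), ira=(l, l + i),
                           ssc=(l + i, l + i + s), irb=(l + i + s, n),
                           genome_len=n)
    return seq, part


def region_stats(sequence: str, partition: RegionPartition) -> dict:
    """Per-region and whole-genome length and GC% (1-decimal, half-up)."""
    out = {}
    for name in ("lsc", "ssc", "ira", "irb"):
        sub = _slice_circ(sequence, getattr(partition, name))
        if not sub:
            out[name] = {"length": 0, "gc_pct": None}
            continue
        gc = 100.0 * (sub.count("G") + sub.count("C")) / len(sub)
        out[name] = {"length": len(sub), "gc_pct": round_half_up(gc, 1)}
    gc_all = 100.0 * (sequence.count("G") + sequence.count("C")) \
        / len(sequence)
    ir_len = out["ira"]["length"]
    out["ir"] = {"length": ir_len,
                 "gc_pct": out["ira"]["gc_pct"]}
    out["whole"] = {"length": len(sequence),
                    "gc_pct": round_half_up(gc_all, 1)}
    return out


def flip_ssc(sequence: str, min_ir_len: int = 200) -> str | None:
    """Return the other SSC-orientation isomer of a circular plastome.

    Plastid DNA exists in vivo as an equimolar mix of two isomers that
    differ only in the orientation of the small single-copy region;
    reads shorter than the IR cannot distinguish them.  Detects the IR
    pair, reverse-complements the SSC in place and returns the result
    (None when no IR pair is found).
    """
    ir = find_ir_pair(sequence, min_ir_len=min_ir_len)
    if ir is None:
        return None
    part = partition_regions(sequence, ir)
    lsc = _slice_circ(sequence, part.lsc)
    ira = _slice_circ(sequence, part.ira)
    ssc = _slice_circ(sequence, part.ssc)
    irb = _slice_circ(sequence, part.irb)
    # rebuild on the original rotation: start from LSC start
    flipped = lsc + ira + revcomp(ssc) + irb
    # restore the input rotation so only the SSC segment changed
    shift = part.lsc[0] % len(sequence)
    return flipped[-shift:] + flipped[:-shift] if shift else flipped
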