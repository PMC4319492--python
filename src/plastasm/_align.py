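"""Gapless alignment primitives built on exact k-mer seeding.

The assembler and mapper only ever score *gapless* overlaps, so a shared
k-mer between query and target pins the full alignment to one diagonal.
For a minimum alignment length ``L`` and a mismatch budget of at most
``floor(r*L)`` (identity ``1-r``), the pigeonhole principle guarantees an
exact run of at least ``ceil((L - m) / (m + 1))`` bases, so a seed size at
or below that bound makes seeded search equivalent to exhaustive search
for every alignment that can pass the identity filter.
"""

from __future__ import annotations

import numpy as np

from ._seq import revcomp_arr


def guaranteed_seed_size(min_len: int, max_mismatch_rate: float,
                         lo: int = 4, hi: int = 12) -> int:
    """Largest seed k that cannot miss a qualifying gapless alignment."""
    worst = hi
    for length in range(min_len, max(min_len * 10, 200) + 1):
        m = int(max_mismatch_rate * length)
        run = -(-(length - m) // (m + 1))  # ceil
        worst = min(worst, run)
    return max(lo, min(worst, hi))


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers of an encoded sequence (4^k alphabet)."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr.astype(np.int64), k)
    return win @ powers


class KmerIndex:
    """Sorted-array index of k-mers over a collection of encoded sequences.

    Records (seq_idx, orient, pos) per k-mer; orient 0 = as given,
    1 = reverse complement.
    """

    def __init__(self, seqs: list[np.ndarray], k: int,
                 both_strands: bool = True):
        self.k = k
        codes, sidx, orients, poss = [], [], [], []
        for i, arr in enumerate(seqs):
            for orient in (0, 1) if both_strands else (0,):
                a = arr if orient == 0 else revcomp_arr(arr)
                kc = kmer_codes(a, k)
                codes.append(kc)
                sidx.append(np.full(kc.size, i, dtype=np.int64))
                orients.append(np.full(kc.size, orient, dtype=np.int8))
                poss.append(np.arange(kc.size, dtype=np.int64))
        if codes:
            codes = np.concatenate(codes)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._sidx = np.concatenate(sidx)[order]
            self._orients = np.concatenate(orients)[order]
            self._poss = np.concatenate(poss)[order]
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._sidx = self._orients = self._poss = self._codes

    def lookup(self, kc_query: np.ndarray):
        """For an array of query k-mer codes, return hit arrays
        (query_pos, seq_idx, orient, pos) for all matches."""
        lo = np.searchsorted(self._codes, kc_query, side="left")
        hi = np.searchsorted(self._codes, kc_query, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e.astype(np.int8), e
        qpos = np.repeat(np.arange(kc_query.size), counts)
        # expand [lo, hi) ranges into flat indices
        idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)
                              if b > a])
        return qpos, self._sidx[idx], self._orients[idx], self._poss[idx]


def mismatches_at(target: np.ndarray, query: np.ndarray, start: int) -> int:
    """Hamming distance of query placed at target[start:start+len(query)]."""
    seg = target[start:start + query.size]
    return int(np.count_nonzero(seg != query))


def best_gapless_placement(query: np.ndarray, target: np.ndarray,
                           index: "KmerIndex", min_identity: float):
    """Best full-length gapless placement of query on the indexed target.

    Returns (orient, start, mismatches) or None if no placement reaches
    ``min_identity``.  Ties: higher match count, then forward strand,
    then smaller start.
    """
    k = index.k
    if query.size < k:
        return None
    qpos, _, orients, tpos = index.lookup(kmer_codes(query, k))
    if qpos.size == 0:
        return None
    n = target.size
    best = None
    for orient in (0, 1):
        sel = orients == orient
        if not sel.any():
            continue
        q = query if orient == 0 else revcomp_arr(query)
        if orient == 0:
            starts = tpos[sel] - qpos[sel]
        else:
            # hit position p lives in RC(target) coordinates; mirror the
            # implied placement of RC(query) back onto the forward target
            starts = n - tpos[sel] - query.size + qpos[sel]
        starts = np.unique(starts[(starts >= 0) &
                                  (starts + query.size <= n)])
        for s in starts:
            mm = mismatches_at(target, q, int(s))
            cand = (query.size - mm, -orient, -int(s))
            if mm <= (1.0 - min_identity) * query.size + 1e-9 and \
                    (best is None or cand > best[0]):
                best = (cand, orient, int(s), mm)
    if best is None:
        return None
    return best[1], best[2], best[3]
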