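"""Dispersed-repeat, tandem-repeat and SSR scanners.

Three detectors in the style of the classic plastome repeat toolchain:

* ``find_dispersed_repeats`` — maximal forward (F) and inverted/
  palindromic (P) repeat pairs of length >= 30 bp within a fixed Hamming
  budget (default 3 mismatches, i.e. 90% identity at the cutoff length).
* ``find_tandem_repeats`` — exact tandem arrays of a primitive unit
  (default unit >= 10 bp, >= 2 copies, array >= 30 bp).
* ``find_ssrs`` — MISA-style microsatellites with per-unit-size copy
  thresholds (mono 8, di 4, tri 3, tetra 3, penta 3, hexa 3).

All three work on linear sequences by default; circular mode scans the
doubled sequence and deduplicates wrapped coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp, round_half_up

__all__ = [
    "DispersedParams", "RepeatHit", "TandemHit", "SSRParams", "SSRLocus",
    "find_dispersed_repeats", "find_tandem_repeats", "find_ssrs",
    "classify_ssr_motifs", "canonical_rotation", "primitive_period",
]


@dataclass(frozen=True)
class DispersedParams:
    min_len: int = 30
    max_hamming: int = 3
    min_identity: float = 0.90

    def __post_init__(self):
        if self.min_len < 1 or self.max_hamming < 0:
            raise ValueError("invalid dispersed-repeat parameters")


@dataclass(frozen=True)
class RepeatHit:
    type: str  # "F" forward | "P" inverted/palindromic
    length: int
    pos1: int
    pos2: int
    hamming: int
    unit: str


@dataclass(frozen=True)
class TandemHit:
    unit: str
    unit_len: int
    copies: float
    array_start: int
    array_len: int


@dataclass(frozen=True)
class SSRParams:
    """Minimum copy number per unit size (1..6)."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: {1: 8, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3})

    def __post_init__(self):
        if set(self.min_repeats) != {1, 2, 3, 4, 5, 6} or \
                any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("thresholds must cover unit sizes 1-6, all >= 2")


@dataclass(frozen=True)
class SSRLocus:
    unit: str
    copies: int
    start: int
    length: int
    motif_class: str


def primitive_period(unit: str) -> int:
    """Smallest p such that unit is a whole number of repeats of its
    first p characters."""
    n = len(unit)
    for p in range(1, n + 1):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return p
    return n


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation (AT and TA share class AT)."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _budget_windows(neq: np.ndarray, h: int, min_len: int):
    """Maximal windows of a mismatch indicator with at most ``h``
    mismatches; yields (start, length, n_mismatches).

    A window is maximal when extending it on either side would add an
    (h+1)-th mismatch or cross the boundary.
    """
    span = neq.size
    if span == 0:
        return
    mism = np.flatnonzero(neq)
    if mism.size <= h:
        if span >= min_len:
            yield 0, span, int(mism.size)
        return
    edges = np.concatenate([[-1], mism, [span]])
    # window j spans (edges[j], edges[j+h+1]) exclusive: h mismatches
    starts = edges[: len(mism) - h + 1] + 1
    ends = edges[h + 1:]
    lens = ends - starts
    for j in np.flatnonzero(lens >= min_len):
        yield int(starts[j]), int(lens[j]), h


def _suppress_contained(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Drop hits fully contained in a longer hit of the same type."""
    out = []
    for x in hits:
        contained = False
        for y in hits:
            if y.type != x.type or y.length <= x.length:
                continue
            x1 = (x.pos1, x.pos1 + x.length)
            x2 = (x.pos2, x.pos2 + x.length)
            y1 = (y.pos1, y.pos1 + y.length)
            y2 = (y.pos2, y.pos2 + y.length)
            def inside(a, b):
                return b[0] <= a[0] and a[1] <= b[1]
            if (inside(x1, y1) and inside(x2, y2)) or \
                    (inside(x1, y2) and inside(x2, y1)):
                contained = True
                break
        if not contained:
            out.append(x)
    return out


def find_dispersed_repeats(sequence: str,
                           params: DispersedParams = DispersedParams(),
                           circular: bool = False) -> list[RepeatHit]:
    """All maximal forward and inverted repeat pairs within the Hamming
    budget, containment-suppressed, sorted by length desc then pos1."""
    n = len(sequence)
    if n < params.min_len:
        return []
    seq = sequence + sequence if circular else sequence
    arr = encode(seq)
    m = arr.size
    h, min_len = params.max_hamming, params.min_len
    raw: list[RepeatHit] = []
    # forward: copy at i vs copy at i+d
    for d in range(1, m - min_len + 1):
        neq = arr[: m - d] != arr[d:]
        for start, length, mm in _budget_windows(neq, h, min_len):
            raw.append(RepeatHit("F", length, start, start + d, mm,
                                 seq[start:start + length]))
    # inverted: copy vs reverse complement elsewhere
    rc = encode(revcomp(seq))
    for e in range(-(m - min_len), m - min_len + 1):
        lo = max(0, -e)
        hi = min(m, m - e)
        if hi - lo < min_len:
            continue
        neq = arr[lo:hi] != rc[lo + e:hi + e]
        for w0, length, mm in _budget_windows(neq, h, min_len):
            a = lo + w0
            b = m - (a + e) - length  # start of the partner copy
            if a < b:
                raw.append(RepeatHit("P", length, a, b, mm,
                                     seq[a:a + length]))
    if circular:
        raw = _dedup_circular_pairs(raw, n)
    hits = _suppress_contained(raw)
    hits.sort(key=lambda r: (-r.length, r.pos1, r.pos2, r.type))
    return hits


def _dedup_circular_pairs(hits: list[RepeatHit], n: int) -> list[RepeatHit]:
    seen = {}
    for r in hits:
        if r.pos1 >= n or r.length > n:
            continue
        key = (r.type, r.pos1 % n, r.pos2 % n, r.length)
        if key not in seen:
            seen[key] = RepeatHit(r.type, r.length, r.pos1 % n,
                                  r.pos2 % n, r.hamming, r.unit)
    return list(seen.values())


def find_tandem_repeats(sequence: str, min_unit: int = 10,
                        min_copies: float = 2, min_array: int = 30,
                        circular: bool = False) -> list[TandemHit]:
    """Maximal exact tandem arrays of a primitive unit.

    An array at period p is a maximal run where S[i] == S[i+p]; the unit
    is the first p bases, required to be primitive so the same array is
    reported once at its true period.
    """
    n = len(sequence)
    if n < min_array:
        return []
    seq = sequence + sequence if circular else sequence
    arr = encode(seq)
    m = arr.size
    hits = []
    seen = set()
    for p in range(min_unit, m // 2 + 1):
        eq = arr[: m - p] == arr[p:]
        # maximal runs of True
        padded = np.concatenate([[False], eq, [False]])
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)
        for i0, i1 in zip(run_starts, run_ends):
            r = int(i1 - i0)
            array_len = r + p
            copies = array_len / p
            if copies < min_copies or array_len < min_array:
                continue
            unit = seq[i0:i0 + p]
            if primitive_period(unit) != p:
                continue
            start = int(i0)
            if circular:
                if start >= n or array_len > n:
                    continue
                key = (start % n, p, array_len)
                if key in seen:
                    continue
                seen.add(key)
            hits.append(TandemHit(unit=unit, unit_len=p, copies=copies,
                                  array_start=start, array_len=array_len))
    hits.sort(key=lambda t: (t.array_start, t.unit_len))
    return hits


def find_ssrs(sequence: str, params: SSRParams = SSRParams(),
              circular: bool = False) -> list[SSRLocus]:
    """MISA-style maximal microsatellite loci with primitive units.

    For each unit size p the scanner finds maximal runs of period p,
    counts whole copies (partial trailing units do not count), applies
    the per-size threshold and requires the unit to be primitive, so a
    run reportable at several unit sizes appears once, at the smallest.
    """
    n = len(sequence)
    seq = sequence + sequence if circular else sequence
    arr = encode(seq)
    m = arr.size
    loci = []
    seen = set()
    for p, threshold in sorted(params.min_repeats.items()):
        if m <= p:
            continue
        eq = arr[: m - p] == arr[p:]
        padded = np.concatenate([[False], eq, [False]])
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)
        for i0, i1 in zip(run_starts, run_ends):
            r = int(i1 - i0)
            copies = r // p + 1
            if copies < threshold:
                continue
            unit = seq[i0:i0 + p]
            if primitive_period(unit) != p:
                continue
            start = int(i0)
            length = p * copies
            if circular:
                if start >= n or length > n:
                    continue
                key = (start % n, p)
                if key in seen:
                    continue
                seen.add(key)
            loci.append(SSRLocus(unit=unit, copies=copies, start=start,
                                 length=length,
                                 motif_class=canonical_rotation(unit)))
    loci.sort(key=lambda s: (s.start, len(s.unit)))
    return loci


def classify_ssr_motifs(loci: list[SSRLocus]) -> dict:
    """Group loci by unit size and canonical rotation class.

    Returns {unit_size: {motif_class: {"count": n, "pct": percent}}}
    where percentages are per unit-size stratum, 1-decimal half-up.
    """
    out: dict[int, dict[str, dict]] = {}
    for locus in loci:
        stratum = out.setdefault(len(locus.unit), {})
        rec = stratum.setdefault(locus.motif_class, {"count": 0})
        rec["count"] += 1
    for stratum in out.values():
        total = sum(rec["count"] for rec in stratum.values())
        for rec in stratum.values():
            rec["pct"] = round_half_up(100.0 * rec["count"] / total, 1)
    return out
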