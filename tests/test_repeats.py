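"""Dispersed/tandem/SSR scanner contracts and brute-force equivalence."""

import numpy as np
import pytest

from plastasm._seq import revcomp
from plastasm.repeats import (DispersedParams, SSRParams, canonical_rotation,
                              classify_ssr_motifs, find_dispersed_repeats,
                              find_ssrs, find_tandem_repeats,
                              primitive_period, SSRLocus)
from conftest import random_dna


# ---------------------------------------------------------------- oracles

def oracle_dispersed(seq, min_len=30, h=3):
    """Plain-python enumeration of all maximal F and P repeat windows."""
    n = len(seq)
    hits = set()

    def windows(neq):
        span = len(neq)
        mism = [i for i, x in enumerate(neq) if x]
        if len(mism) <= h:
            if span >= min_len:
                yield 0, span, len(mism)
            return
        edges = [-1] + mism + [span]
        for j in range(len(mism) - h + 1):
            s = edges[j] + 1
            e = edges[j + h + 1]
            if e - s >= min_len:
                yield s, e - s, h

    for d in range(1, n - min_len + 1):
        neq = [seq[i] != seq[i + d] for i in range(n - d)]
        for s, ln, mm in windows(neq):
            hits.add(("F", ln, s, s + d, mm))
    t = revcomp(seq)
    for e_diag in range(-(n - min_len), n - min_len + 1):
        lo = max(0, -e_diag)
        hi = min(n, n - e_diag)
        if hi - lo < min_len:
            continue
        neq = [seq[i] != t[i + e_diag] for i in range(lo, hi)]
        for w0, ln, mm in windows(neq):
            a = lo + w0
            b = n - (a + e_diag) - ln
            if a < b:
                hits.add(("P", ln, a, b, mm))
    # containment suppression, same definition as the scanner contract
    out = []
    items = list(hits)
    for x in items:
        tx, lx, p1, p2, _ = x
        keep = True
        for y in items:
            ty, ly, q1, q2, _ = y
            if ty != tx or ly <= lx:
                continue
            if (q1 <= p1 and p1 + lx <= q1 + ly
                    and q2 <= p2 and p2 + lx <= q2 + ly) or \
               (q2 <= p1 and p1 + lx <= q2 + ly
                    and q1 <= p2 and p2 + lx <= q1 + ly):
                keep = False
                break
        if keep:
            out.append(x)
    return sorted(out, key=lambda r: (-r[1], r[2], r[3], r[0]))


def oracle_tandem(seq, min_unit=10, min_copies=2, min_array=30):
    n = len(seq)
    hits = []
    for p in range(min_unit, n // 2 + 1):
        i = 0
        while i < n - p:
            if seq[i] != seq[i + p]:
                i += 1
                continue
            j = i
            while j < n - p and seq[j] == seq[j + p]:
                j += 1
            run = j - i
            array_len = run + p
            copies = array_len / p
            unit = seq[i:i + p]
            if (copies >= min_copies and array_len >= min_array
                    and primitive_period(unit) == p):
                hits.append((i, p, array_len, copies, unit))
            i = j + 1
    return sorted(hits)


def oracle_ssrs(seq, thresholds=None):
    thresholds = thresholds or {1: 8, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}
    n = len(seq)
    loci = []
    for p, thr in thresholds.items():
        i = 0
        while i < n - p:
            if seq[i] != seq[i + p]:
                i += 1
                continue
            j = i
            while j < n - p and seq[j] == seq[j + p]:
                j += 1
            run = j - i
            copies = run // p + 1
            unit = seq[i:i + p]
            if copies >= thr and primitive_period(unit) == p:
                loci.append((i, p, copies, unit))
            i = j + 1
    return sorted(loci)


# ------------------------------------------------------------------ tests

class TestDispersed:
    def test_planted_exact_forward_copy(self):
        rng = np.random.default_rng(0)
        u = random_dna(rng, 35)
        seq = u + random_dna(rng, 150) + u
        hits = find_dispersed_repeats(seq)
        top = [hit for hit in hits if hit.length >= 35]
        assert any(hit.type == "F" and hit.length == 35
                   and hit.hamming == 0 for hit in top)

    def test_planted_inverted_copy_52bp(self):
        rng = np.random.default_rng(1)
        u = random_dna(rng, 52)
        seq = random_dna(rng, 60) + u + random_dna(rng, 150) + revcomp(u)
        hits = find_dispersed_repeats(seq)
        # maximal windows may extend past the planted copy within the
        # Hamming budget; require a P hit covering the planted interval
        assert any(hit.type == "P" and hit.length >= 52
                   and hit.pos1 <= 60 + 52 and hit.pos1 + hit.length >= 60
                   for hit in hits)

    def test_hamming_boundary_three_mismatches_at_30(self):
        rng = np.random.default_rng(2)
        u = list(random_dna(rng, 30))
        v = list(u)
        for p in (5, 15, 25):
            v[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[v[p]]
        seq = "".join(u) + random_dna(rng, 200) + "".join(v)
        hits = find_dispersed_repeats(seq, DispersedParams())
        assert any(hit.length >= 30 and hit.hamming == 3 for hit in hits)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(300 + seed)
        seq = list(random_dna(rng, 260))
        if seed % 2:
            u = random_dna(rng, 31)
            seq[10:41] = u
            mutated = list(u)
            for p in rng.choice(31, size=3, replace=False):
                mutated[p] = "ACGT"[int(rng.integers(0, 4))]
            seq[150:181] = mutated
        seq = "".join(seq)
        got = [(h.type, h.length, h.pos1, h.pos2, h.hamming)
               for h in find_dispersed_repeats(seq)]
        assert got == oracle_dispersed(seq)

    def test_no_contained_hits_reported(self):
        rng = np.random.default_rng(4)
        u = random_dna(rng, 60)
        seq = u + random_dna(rng, 100) + u
        hits = find_dispersed_repeats(seq)
        for x in hits:
            for y in hits:
                if x is y or x.type != y.type or y.length <= x.length:
                    continue
                assert not (y.pos1 <= x.pos1
                            and x.pos1 + x.length <= y.pos1 + y.length
                            and y.pos2 <= x.pos2
                            and x.pos2 + x.length <= y.pos2 + y.length)


class TestTandem:
    def test_planted_20bp_unit_twice(self):
        rng = np.random.default_rng(5)
        unit = "GTTATTGTAGGAGTGAAATC"
        seq = random_dna(rng, 100) + unit * 2 + random_dna(rng, 100)
        hits = find_tandem_repeats(seq)
        assert any(t.unit_len == 20 and t.copies == 2.0
                   and t.array_len == 40 for t in hits)

    def test_random_sequence_mostly_empty(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 400)
        got = [(t.array_start, t.unit_len, t.array_len, t.copies, t.unit)
               for t in find_tandem_repeats(seq)]
        assert got == oracle_tandem(seq)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_with_planted_arrays(self, seed):
        rng = np.random.default_rng(500 + seed)
        seq = list(random_dna(rng, 500))
        for _ in range(3):
            p = int(rng.integers(10, 25))
            unit = random_dna(rng, p)
            copies = int(rng.integers(2, 4))
            pos = int(rng.integers(0, 500 - p * copies))
            seq[pos:pos + p * copies] = unit * copies
        seq = "".join(seq)
        got = sorted((t.array_start, t.unit_len, t.array_len, t.copies,
                      t.unit) for t in find_tandem_repeats(seq))
        assert got == oracle_tandem(seq)

    def test_non_primitive_units_suppressed(self):
        rng = np.random.default_rng(7)
        unit = random_dna(rng, 10)
        seq = random_dna(rng, 50) + unit * 4 + random_dna(rng, 50)
        hits = find_tandem_repeats(seq)
        assert all(primitive_period(t.unit) == t.unit_len for t in hits)
        assert any(t.unit_len == 10 and t.copies == 4.0 for t in hits)


class TestSSRs:
    def test_mono_threshold_boundary(self):
        rng = np.random.default_rng(8)
        flank1, flank2 = "CGCGTGTGAC", "GTGCACGTGC"
        assert any(s.unit == "A" and s.copies == 8
                   for s in find_ssrs(flank1 + "A" * 8 + flank2))
        assert not any(s.unit == "A"
                       for s in find_ssrs(flank1 + "A" * 7 + flank2))

    def test_twenty_t_is_longest_mononucleotide(self):
        rng = np.random.default_rng(9)
        seq = (random_dna(rng, 300) + "C" + "T" * 20 + "C"
               + random_dna(rng, 300))
        loci = find_ssrs(seq)
        monos = [s for s in loci if len(s.unit) == 1]
        longest = max(monos, key=lambda s: s.length)
        assert longest.unit == "T" and longest.copies == 20

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(700 + seed)
        seq = list(random_dna(rng, 800))
        # plant a few loci of assorted unit sizes
        for p, copies in ((1, 9), (2, 5), (3, 4), (4, 3)):
            unit = random_dna(rng, p)
            pos = int(rng.integers(0, 700))
            seq[pos:pos + p * copies] = unit * copies
        seq = "".join(seq)
        got = sorted((s.start, len(s.unit), s.copies, s.unit)
                     for s in find_ssrs(seq))
        assert got == oracle_ssrs(seq)

    def test_units_never_periodic(self):
        rng = np.random.default_rng(10)
        seq = random_dna(rng, 200) + "AT" * 12 + random_dna(rng, 200)
        for s in find_ssrs(seq):
            assert primitive_period(s.unit) == len(s.unit)

    def test_threshold_loosening_is_monotone(self):
        rng = np.random.default_rng(11)
        seq = "".join(random_dna(rng, 2000))
        tight = {(s.start, s.unit) for s in find_ssrs(seq)}
        loose = SSRParams(min_repeats={1: 6, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2})
        loosened = {(s.start, s.unit) for s in find_ssrs(seq, loose)}
        assert tight <= loosened


class TestMotifClasses:
    def test_rotation_classes_group_at_ta(self):
        loci = [SSRLocus("AT", 4, 0, 8, canonical_rotation("AT")),
                SSRLocus("AT", 5, 50, 10, canonical_rotation("AT")),
                SSRLocus("AT", 4, 100, 8, canonical_rotation("AT")),
                SSRLocus("TA", 4, 200, 8, canonical_rotation("TA")),
                SSRLocus("TA", 4, 300, 8, canonical_rotation("TA")),
                SSRLocus("TA", 4, 400, 8, canonical_rotation("TA"))]
        table = classify_ssr_motifs(loci)
        assert table[2]["AT"]["count"] == 6
        assert table[2]["AT"]["pct"] == 100.0

    def test_mononucleotide_fractions(self):
        loci = []
        pos = 0
        for unit, count in (("A", 58), ("T", 70), ("C", 2), ("G", 1)):
            for _ in range(count):
                loci.append(SSRLocus(unit, 8, pos, 8, unit))
                pos += 20
        table = classify_ssr_motifs(loci)
        assert table[1]["T"]["pct"] == 53.4
        assert table[1]["A"]["pct"] == 44.3
        assert table[1]["C"]["pct"] == 1.5
        assert table[1]["G"]["pct"] == 0.8

    def test_empty_input(self):
        assert classify_ssr_motifs([]) == {}


class TestCircularMode:
    def test_ssr_rotation_invariance(self):
        rng = np.random.default_rng(12)
        seq = "C" + "T" * 12 + "G" + random_dna(rng, 200)
        base = {(s.unit, s.copies) for s in find_ssrs(seq, circular=True)}
        rot = seq[-50:] + seq[:-50]
        rotated = {(s.unit, s.copies)
                   for s in find_ssrs(rot, circular=True)}
        assert base == rotated

    def test_wrapping_locus_detected_once(self):
        rng = np.random.default_rng(13)
        core = random_dna(rng, 200)
        seq = "T" * 6 + core + "C" + "T" * 6  # 12-T run across the origin
        loci = [s for s in find_ssrs(seq, circular=True)
                if s.unit == "T" and s.copies >= 12]
        assert len(loci) == 1
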