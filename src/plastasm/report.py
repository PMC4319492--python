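"""Summary statistics, assembly validation and the end-to-end pipeline.

``read_stats`` and ``coverage_depth`` reproduce the arithmetic of a
sequencing-summary table; ``validate_regions`` scores an assembly against
reference amplicons (the in-silico analogue of Sanger validation);
``compare_to_truth`` checks rotation/strand equivalence of a circular
assembly against a known genome; ``run_pipeline`` chains simulation, QC,
assembly, mapping, consensus, partitioning, repeat/SSR scans, codon usage
and validation into one JSON-serializable run report.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp, revcomp_arr, round_half_up
from . import assemble as asm
from . import quadripartite as quad
from . import repeats as rep
from . import codons as cod
from .simulate import (GenomeSpec, ReadSet, build_plastome,
                       simulate_ccs_reads)

__all__ = ["SummaryStats", "ValidationReport", "read_stats",
           "coverage_depth", "validate_regions", "compare_to_truth",
           "run_pipeline", "PipelineError"]


@dataclass(frozen=True)
class SummaryStats:
    n_reads: int
    total_bases: int
    mean_len: int | None  # rounded half-up; None for an empty set
    longest: int


@dataclass(frozen=True)
class TargetResult:
    name: str
    length: int
    mismatches: int | None
    start: int | None
    strand: str | None
    identity: float | None
    located: bool


@dataclass(frozen=True)
class ValidationReport:
    aligned_bases: int
    mismatches: int
    error_rate_pct: float
    accuracy_pct: float
    targets: tuple[TargetResult, ...]

    @property
    def unlocatable(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.targets if not t.located)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage."""


def read_stats(reads: ReadSet) -> SummaryStats:
    """Read count, total bases, half-up-rounded mean length, longest."""
    n = len(reads)
    total = reads.total_bases
    longest = max((len(r) for r in reads), default=0)
    mean = int(round_half_up(total / n, 0)) if n else None
    return SummaryStats(n_reads=n, total_bases=total, mean_len=mean,
                        longest=longest)


def coverage_depth(total_bases: int, genome_len: int) -> tuple[float, int]:
    """Mean depth of coverage, exact and rounded to the nearest integer."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    depth = total_bases / genome_len
    return depth, int(round_half_up(depth, 0))


def _best_exhaustive(ref: np.ndarray, target: np.ndarray,
                     chunk_bytes: int = 48_000_000):
    """Best full-length gapless placement of ref over every offset of
    target, both strands.  Returns (matches, strand, start) or None."""
    L = ref.size
    n = target.size
    if L > n:
        return None
    best = None
    for strand, q in (("+", ref), ("-", revcomp_arr(ref))):
        rows = max(1, chunk_bytes // max(L, 1))
        for off in range(0, n - L + 1, rows):
            stop = min(off + rows, n - L + 1)
            win = np.lib.stride_tricks.sliding_window_view(
                target[off:stop + L - 1], L)
            matches = (win == q).sum(axis=1)
            i = int(matches.argmax())
            cand = (int(matches[i]), strand == "+", -(off + i))
            if best is None or cand > best[0]:
                best = (cand, strand, off + i)
    matches, strand, start = best[0][0], best[1], best[2]
    return matches, strand, start


def validate_regions(assembly: str, references, circular: bool = True,
                     min_locate_identity: float = 0.80) -> ValidationReport:
    """Score reference regions against their best placement on the
    assembly.

    Each reference (name, sequence) is placed gaplessly at its best
    offset on either strand (the assembly is doubled when circular so
    references may span the origin).  References whose best identity is
    below ``min_locate_identity`` are reported unlocatable and excluded
    from the totals.  Error rate is 100 * mismatches / aligned bases and
    accuracy its complement, both rounded half-up to 3 decimals.
    """
    arr = encode(assembly)
    target = np.concatenate([arr, arr]) if circular else arr
    n = arr.size
    targets = []
    total_mm = 0
    total_bases = 0
    for item in references:
        name, seq = item[0], item[1]
        ref = encode(seq)
        hit = _best_exhaustive(ref, target)
        if hit is None:
            targets.append(TargetResult(name, ref.size, None, None, None,
                                        None, False))
            continue
        matches, strand, start = hit
        identity = matches / ref.size
        if identity < min_locate_identity:
            targets.append(TargetResult(name, ref.size, None, None, None,
                                        round_half_up(identity, 3), False))
            continue
        mm = ref.size - matches
        targets.append(TargetResult(name, ref.size, mm, start % n, strand,
                                    round_half_up(identity, 5), True))
        total_mm += mm
        total_bases += ref.size
    err = 100.0 * total_mm / total_bases if total_bases else 0.0
    return ValidationReport(
        aligned_bases=total_bases, mismatches=total_mm,
        error_rate_pct=round_half_up(err, 3),
        accuracy_pct=round_half_up(100.0 - err, 3),
        targets=tuple(targets))


def compare_to_truth(assembly: str, truth: str,
                     circular: bool = True) -> tuple[bool, float]:
    """Rotation/strand equivalence and best-alignment identity.

    Equivalent means equal length and the assembly (or its reverse
    complement) occurs exactly in the doubled truth.  Identity is the
    best full-length gapless match fraction over all rotations and both
    strands (denominator: the longer sequence).
    """
    if not assembly or not truth:
        raise ValueError("empty sequence")
    doubled = truth + truth if circular else truth
    equivalent = (len(assembly) == len(truth)) and (
        assembly in doubled or revcomp(assembly) in doubled)
    if equivalent:
        return True, 1.0
    short, long_ = sorted((assembly, truth), key=len)
    target = encode(long_ + long_) if circular else encode(long_)
    hit = _best_exhaustive(encode(short), target)
    identity = hit[0] / len(long_) if hit else 0.0
    return False, identity


def _stage(report, name, func):
    t0 = time.perf_counter()
    try:
        result = func()
    except Exception as exc:  # noqa: BLE001 - re-labelled per stage
        raise PipelineError(f"{name}: {exc}") from exc
    report["timings"][name] = round(time.perf_counter() - t0, 3)
    return result


def run_pipeline(config: dict) -> dict:
    """Run simulate -> filter -> assemble -> map -> consensus ->
    partition -> scans -> codon usage -> validation and return one
    JSON-serializable report.

    The ``simulate`` block is optional; alternatively supply ``reads``
    (a ReadSet) and, for truth comparison, ``truth`` (a sequence).
    """
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed, "params": {k: v for k, v in config.items()
                                             if k not in ("reads", "truth")},
                    "stages": {}, "timings": {}}
    truth_seq = config.get("truth")
    genome = None
    if "simulate" in config:
        sim = dict(config["simulate"])
        cov = sim.pop("coverage", 30.0)
        read_kw = {k: sim.pop(k) for k in
                   ("mean_len", "len_sd", "max_len", "error_rate",
                    "min_len") if k in sim}
        spec = GenomeSpec(**{**sim, "seed": sim.get("seed", seed)})

        def do_sim():
            g = build_plastome(spec)
            r = simulate_ccs_reads(g, coverage=cov, seed=seed + 1,
                                   **read_kw)
            return g, r
        genome, reads = _stage(report, "simulate", do_sim)
        truth_seq = genome.sequence
        report["stages"]["simulate"] = {
            "genome_length": len(genome.sequence),
            "coverage_requested": cov, "n_reads": len(reads)}
    else:
        reads = config["reads"]

    qc = asm.QCParams(**config.get("qc", {}))
    filtered = _stage(report, "qc", lambda: asm.filter_reads(reads, qc))
    stats = read_stats(filtered)
    report["stages"]["qc"] = {
        "reads_in": len(reads), "reads_out": len(filtered),
        "total_bases": stats.total_bases, "mean_read_len": stats.mean_len,
        "longest_read": stats.longest}

    akw = config.get("assemble", {})
    draft = _stage(report, "assemble",
                   lambda: asm.greedy_assemble(filtered, qc=None, **akw))
    report["stages"]["assembly"] = {
        "contigs": 1, "length": len(draft), "circular": draft.circular,
        "ir_closed": draft.ir_closed, "reads_used": len(draft.used_read_ids),
        "extensions": len(draft.extension_log)}

    pileup = _stage(report, "map", lambda: asm.map_reads(
        filtered, draft, akw.get("min_identity", 0.90)))
    depth = pileup.depth
    report["stages"]["map"] = {
        "reads_placed": len(pileup.placements),
        "mean_depth": round(float(depth.mean()), 2),
        "zero_depth_columns": int((depth == 0).sum()),
        "genome_coverage_complete": bool((depth > 0).all())}

    consensus = _stage(report, "consensus",
                       lambda: asm.call_consensus(pileup, draft))
    if genome is not None or truth_seq:
        stats2 = read_stats(filtered)
        depth_x = coverage_depth(stats2.total_bases, len(consensus))
        report["stages"]["consensus"] = {
            "length": len(consensus), "mean_coverage_x": depth_x[1]}
    else:
        report["stages"]["consensus"] = {"length": len(consensus)}

    min_ir = config.get("min_ir_len", 200)

    def do_partition():
        ir = quad.find_ir_pair(consensus, min_ir_len=min_ir)
        if ir is None:
            return None
        part = quad.partition_regions(consensus, ir)
        canon, cpart = quad.canonicalize(consensus, part)
        return ir, part, canon, cpart
    part_out = _stage(report, "partition", do_partition)
    if part_out is None:
        report["stages"]["partition"] = {"ir_found": False}
        canon = consensus
    else:
        ir, part, canon, cpart = part_out
        report["stages"]["partition"] = {
            "ir_found": True, "ir_length": ir.length,
            "regions": quad.region_stats(canon, cpart)}

    scan_cfg = config.get("scan", {})
    circ_scan = bool(scan_cfg.get("circular", True))

    def do_scan():
        disp = rep.find_dispersed_repeats(canon, circular=circ_scan)
        tand = rep.find_tandem_repeats(canon, circular=circ_scan)
        ssrs = rep.find_ssrs(canon, circular=circ_scan)
        return disp, tand, ssrs
    disp, tand, ssrs = _stage(report, "scan", do_scan)
    report["stages"]["repeats"] = {
        "dispersed_forward": sum(1 for h in disp if h.type == "F"),
        "dispersed_inverted": sum(1 for h in disp if h.type == "P"),
        "tandem": len(tand), "ssr_loci": len(ssrs),
        "ssr_classes": rep.classify_ssr_motifs(ssrs)}

    cds = config.get("cds")
    if cds is None and genome is not None:
        cds = [(f"cds{i}", genome.sequence[f.start:f.end])
               for i, f in enumerate(genome.truth) if f.kind == "CDS"]
    if cds:
        table = _stage(report, "codons", lambda: cod.compute_rscu(
            cod.count_codons(cds)))
        report["stages"]["codon_usage"] = {
            "total_codons": sum(e.count for e in table),
            "at_pct": cod.at_content(canon)}
    report["stages"].setdefault("codon_usage", {"at_pct":
                                                cod.at_content(canon)})

    refs = config.get("validate_references")
    if refs is None and truth_seq:
        # six synthetic amplicons from the truth sequence
        n = len(truth_seq)
        step = max(n // 8, 200)
        refs = [(f"amplicon{i}", truth_seq[a:a + min(step, n - a)])
                for i, a in enumerate(range(0, n, 2 * step))][:6]
    if refs:
        vrep = _stage(report, "validate", lambda: validate_regions(
            consensus, refs, circular=draft.circular))
        report["stages"]["validation"] = {
            "aligned_bases": vrep.aligned_bases,
            "mismatches": vrep.mismatches,
            "error_rate_pct": vrep.error_rate_pct,
            "accuracy_pct": vrep.accuracy_pct,
            "unlocatable": list(vrep.unlocatable)}

    if truth_seq:
        def do_compare():
            eq, ident = compare_to_truth(consensus, truth_seq,
                                         circular=True)
            # reads shorter than the IR cannot identify the orientation
            # of the SSC (the two in-vivo isomers); report equivalence
            # both strictly and modulo that inversion
            eq_iso, ident_iso = eq, ident
            if not eq:
                alt = quad.flip_ssc(consensus, min_ir_len=min_ir)
                if alt is not None:
                    eq_iso, ident_iso = compare_to_truth(
                        alt, truth_seq, circular=True)
            return eq, ident, eq_iso, ident_iso
        eq, ident, eq_iso, ident_iso = _stage(report, "compare",
                                              do_compare)
        report["stages"]["truth_comparison"] = {
            "equivalent": eq, "identity": round(ident, 6),
            "equivalent_up_to_ssc_orientation": eq_iso,
            "identity_up_to_ssc_orientation": round(ident_iso, 6),
            "length_delta": len(consensus) - len(truth_seq)}
    return report
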