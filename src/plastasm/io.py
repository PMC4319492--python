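"""Readers and writers for FASTA/FASTQ/GFF3/BED/TSV artifacts."""

from __future__ import annotations

import json
import math
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assemble import DraftAssembly, Pileup
from .simulate import Read, ReadSet, SyntheticPlastome

__all__ = [
    "write_genome_fasta", "read_fasta", "write_truth_gff3",
    "write_reads_fastq", "read_reads_fastq", "write_reads_fasta_tsv",
    "read_reads_fasta_tsv", "write_consensus_fasta", "write_regions_bed",
    "write_region_stats_tsv", "write_pileup_tsv", "write_repeats_gff3",
    "write_repeats_tsv", "write_rscu_tsv", "write_report_json",
]


def _phred_from_quality(q: float) -> int:
    """Per-read scalar quality -> flat Phred value (capped at 60)."""
    if q >= 1.0:
        return 60
    return min(60, max(0, int(round(-10.0 * math.log10(1.0 - q)))))


def write_genome_fasta(genome: SyntheticPlastome, path) -> None:
    r = genome.regions
    desc = " ".join(f"{name}={a}-{b}" for name, (a, b) in
                    (("lsc", r.lsc), ("ira", r.ira),
                     ("ssc", r.ssc), ("irb", r.irb)))
    rec = SeqRecord(Seq(genome.sequence), id="synthetic_plastome",
                    description=desc)
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_truth_gff3(genome: SyntheticPlastome, path) -> None:
    """Planted-feature truth table; GFF3 coordinates (1-based inclusive)."""
    type_map = {"SSR": "microsatellite", "tandem": "tandem_repeat",
                "forward_repeat": "direct_repeat",
                "inverted_repeat": "inverted_repeat", "CDS": "CDS"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region synthetic_plastome 1 "
                 f"{len(genome.sequence)}\n")
        for f in genome.truth:
            attrs = [f"kind={f.kind}"]
            for key in ("unit", "copies"):
                if key in f.payload:
                    attrs.append(f"{key}={f.payload[key]}")
            fh.write("\t".join([
                "synthetic_plastome", "plastasm",
                type_map[f.kind], str(f.start + 1), str(f.end), ".",
                "+", ".", ";".join(attrs)]) + "\n")


def write_reads_fastq(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            phred = chr(33 + _phred_from_quality(r.quality)) * len(r)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{phred}\n")


def read_reads_fastq(path) -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        phreds = rec.letter_annotations["phred_quality"]
        mean_err = sum(10.0 ** (-p / 10.0) for p in phreds) / len(phreds)
        reads.append(Read(id=rec.id, sequence=str(rec.seq).upper(),
                          quality=1.0 - mean_err))
    return ReadSet(reads=tuple(reads))


def write_reads_fasta_tsv(reads: ReadSet, fasta_path, tsv_path) -> None:
    SeqIO.write([SeqRecord(Seq(r.sequence), id=r.id, description="")
                 for r in reads], str(fasta_path), "fasta")
    with open(tsv_path, "w") as fh:
        fh.write("id\tlength\tquality\torigin_start\torigin_end\tstrand\n")
        for r in reads:
            o = r.origin or ("", "", "")
            fh.write(f"{r.id}\t{len(r)}\t{r.quality:.6f}"
                     f"\t{o[0]}\t{o[1]}\t{o[2]}\n")


def read_reads_fasta_tsv(fasta_path, tsv_path=None) -> ReadSet:
    quals = {}
    if tsv_path and Path(tsv_path).exists():
        with open(tsv_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            qi = header.index("quality")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                quals[parts[0]] = float(parts[qi])
    reads = tuple(Read(id=rid, sequence=seq, quality=quals.get(rid, 1.0))
                  for rid, seq in read_fasta(fasta_path))
    return ReadSet(reads=reads)


def write_consensus_fasta(sequence: str, draft: DraftAssembly, path,
                          name: str = "consensus") -> None:
    desc = (f"circular={'true' if draft.circular else 'false'} "
            f"ir_closed={'true' if draft.ir_closed else 'false'}")
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description=desc)],
                str(path), "fasta")


def write_regions_bed(partition, path, name: str = "genome") -> None:
    """Four regions as BED (0-based half-open); wrapped intervals split."""
    n = partition.genome_len
    with open(path, "w") as fh:
        for region in ("lsc", "ira", "ssc", "irb"):
            a, b = getattr(partition, region)
            a, b = a % n, b % n or (n if a else 0)
            if a < b:
                fh.write(f"{name}\t{a}\t{b}\t{region.upper()}\n")
            else:
                fh.write(f"{name}\t{a}\t{n}\t{region.upper()}\n")
                if b:
                    fh.write(f"{name}\t0\t{b}\t{region.upper()}\n")


def write_region_stats_tsv(stats: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tlength_bp\tgc_pct\n")
        for region in ("whole", "lsc", "ssc", "ir"):
            s = stats[region]
            gc = "NA" if s["gc_pct"] is None else s["gc_pct"]
            fh.write(f"{region.upper()}\t{s['length']}\t{gc}\n")


def write_pileup_tsv(pileup: Pileup, path) -> None:
    depth = pileup.depth
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tT\tdepth\n")
        for i in range(pileup.counts.shape[1]):
            a, c, g, t = pileup.counts[:, i]
            fh.write(f"{i + 1}\t{a}\t{c}\t{g}\t{t}\t{depth[i]}\n")


def write_repeats_gff3(dispersed, tandem, ssrs, path,
                       name: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in dispersed:
            for pos in (h.pos1, h.pos2):
                fh.write("\t".join([
                    name, "plastasm", "dispersed_repeat",
                    str(pos + 1), str(pos + h.length), ".", "+", ".",
                    f"type={h.type};hamming={h.hamming};"
                    f"mate={h.pos2 + 1 if pos == h.pos1 else h.pos1 + 1}"])
                    + "\n")
        for t in tandem:
            fh.write("\t".join([
                name, "plastasm", "tandem_repeat", str(t.array_start + 1),
                str(t.array_start + t.array_len), ".", "+", ".",
                f"unit={t.unit};copies={t.copies:g}"]) + "\n")
        for s in ssrs:
            fh.write("\t".join([
                name, "plastasm", "microsatellite", str(s.start + 1),
                str(s.start + s.length), ".", "+", ".",
                f"unit={s.unit};copies={s.copies};"
                f"class={s.motif_class}"]) + "\n")


def write_repeats_tsv(dispersed, tandem, path) -> None:
    """Combined repeat table in the style of a published repeat summary."""
    with open(path, "w") as fh:
        fh.write("number\tsize_bp\ttype\tstart1\tstart2\tunit\n")
        rows = [(h.length, h.type, h.pos1 + 1, h.pos2 + 1, h.unit)
                for h in dispersed]
        rows += [(t.array_len, "T", t.array_start + 1, "",
                  f"{t.unit}(x{t.copies:g})") for t in tandem]
        for i, row in enumerate(rows, 1):
            fh.write(f"{i}\t" + "\t".join(str(x) for x in row) + "\n")


def write_rscu_tsv(table, path) -> None:
    with open(path, "w") as fh:
        fh.write("amino_acid\tcodon\tcount\trscu\ttrna\n")
        for e in table:
            rscu = "NA" if e.rscu_display is None else f"{e.rscu_display:.2f}"
            fh.write(f"{e.amino_acid}\t{e.codon}\t{e.count}\t{rscu}\t"
                     f"{e.trna or ''}\n")


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
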