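# plastasm

Simulation, greedy long-read assembly and characterization of
quadripartite chloroplast (plastid) genomes.

Land-plant plastomes are ~120–160 kb circles with a conserved
quadripartite layout: a large single-copy region (LSC) and a small
single-copy region (SSC) separated by two long, exactly mirrored
inverted-repeat copies (IRa/IRb). Assembling them from error-corrected
long reads (CCS) is simple enough that a transparent, fully tested
seed-and-extend workflow can do it end to end — and transparent enough
that every stage can be verified against planted ground truth. That is
what this package provides, for people building or teaching organelle
assembly pipelines and for anyone who needs a self-contained, no-download
test bed for plastome structure, repeat and codon-usage analysis:

* **`plastasm.simulate`** — build a synthetic plastome
  (LSC + IRa + SSC + IRb, exact per-region GC, IRb = reverse complement
  of IRa), plant SSRs / tandem arrays / dispersed repeats / CDS at known
  coordinates, and simulate CCS-like reads (uniform circular sampling,
  truncated-normal lengths, i.i.d. substitution errors, per-read scalar
  quality = 1 − realized mismatch fraction) and Sanger-style amplicons.
* **`plastasm.assemble`** — QC filtering (length ≥ 50 bp, quality
  ≥ 0.75), greedy seed-and-extend assembly (gapless overlap scoring,
  match +1 / mismatch −2, defaults min_overlap 50 bp / identity 90%),
  IR-aware circularization, k-mer-seeded read mapping and per-column
  majority consensus.
* **`plastasm.quadripartite`** — exact inverted-repeat pair detection on
  the circle, LSC/SSC/IR partitioning, canonical rotation/orientation,
  per-region GC at table precision, and the SSC-orientation isomer flip.
* **`plastasm.repeats`** — dispersed forward/palindromic repeats
  (≥ 30 bp within a Hamming budget of 3, i.e. 90% identity at the
  cutoff), exact tandem arrays of primitive units, and MISA-style SSRs
  (mono ≥ 8, di ≥ 4, tri–hexa ≥ 3 copies) with motif-class summaries.
* **`plastasm.codons`** — codon counting, relative synonymous codon
  usage (RSCU_i = n_i · k / Σ n over each synonymous family, stops as one
  3-codon family, serine as one 6-codon family) and Watson–Crick
  codon–anticodon matching.
* **`plastasm.report`** — sequencing-summary arithmetic, validation of
  an assembly against reference amplicons (error rate =
  100·mismatches/aligned bp), truth comparison, and a `run_pipeline`
  orchestrator emitting one JSON run report.

## Worked example

```python
from plastasm import (GenomeSpec, build_plastome, simulate_ccs_reads,
                      greedy_assemble, map_reads, call_consensus,
                      find_ir_pair, partition_regions, region_stats,
                      compare_to_truth)
from plastasm.quadripartite import flip_ssc

spec = GenomeSpec(lsc_len=3500, ssc_len=1000, ir_len=750, seed=42)
genome = build_plastome(spec)
reads = simulate_ccs_reads(genome, coverage=50, mean_len=400,
                           len_sd=120, max_len=800, error_rate=0.005,
                           seed=7)
draft = greedy_assemble(reads)
consensus = call_consensus(map_reads(reads, draft), draft)
print(len(consensus), draft.circular, draft.ir_closed)
print(compare_to_truth(consensus, genome.sequence))
print(compare_to_truth(flip_ssc(consensus, 200), genome.sequence))

ir = find_ir_pair(consensus, min_ir_len=200)
stats = region_stats(consensus, partition_regions(consensus, ir))
print({k: v for k, v in stats.items() if k in ("lsc", "ssc", "ir")})
```

prints

```
6000 True True
(False, 0.8853333333333333)
(True, 1.0)
{'lsc': {'length': 3500, 'gc_pct': 36.1}, 'ssc': {'length': 1000,
'gc_pct': 32.7}, 'ir': {'length': 750, 'gc_pct': 42.9}}
```

The 6,000 bp circle comes back as one circular contig of exactly the
right length and structure. The strict comparison says "not equivalent"
at identity 0.885 because, with 400 bp reads and a 750 bp IR, no read
spans an IR copy and the orientation of the SSC is genuinely
unidentifiable — plastid DNA exists in vivo as an equimolar mix of the
two inversion isomers. Flipping the SSC (`flip_ssc`) shows the assembly
is the *other* isomer of the truth, base-for-base (identity 1.0). The
IR pair is detected at its planted 750 bp and the per-region GC matches
the generating spec (the IR's 322/750 G+C sites round to 42.9%).

A command-line umbrella mirrors the library:

```bash
plastasm simulate --lsc 3500 --ssc 1000 --ir 750 --coverage 50 \
    --mean-len 400 --max-len 800 --seed 42 --out-prefix sim
plastasm assemble --reads sim.reads.fastq --out-prefix asm
plastasm partition --in asm.consensus.fasta --min-ir-len 200 \
    --out-prefix parts
plastasm scan --in asm.consensus.fasta --mode all --out-prefix rep
```

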