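# Methods

## The model system

The package targets the quadripartite architecture of land-plant
chloroplast genomes: a circle of four regions in the fixed order
LSC – IRa – SSC – IRb, where the two IR copies are exact reverse
complements. All coordinates are 0-based half-open internally; anything
user-facing (GFF3, pileup TSV) is 1-based inclusive per the respective
format conventions. Region order on the circle and the LSC/SSC naming
convention (purely by arc length) follow standard plastome usage.

## Synthetic genomes and reads

`build_plastome` draws each region independently. The number of strong
(G/C) bases per region is fixed at `round(gc * length)` and their
positions and identities (G vs C, A vs T) are drawn uniformly, so the
empirical GC of every region matches its target to within rounding —
deliberately tighter than per-base Bernoulli sampling, whose binomial
noise at 1 kb (σ ≈ 1.5 pp) would routinely exceed a ±2 pp tolerance.
One base at each IR boundary is flipped to its complement (staying
within its GC class) when it would otherwise extend the planted IR by
chance, so the planted IR pair is exactly maximal and detectable at its
planted coordinates.

Reads emulate circular-consensus long reads at the level that matters
for a substitution-only acceptance surface: uniform start positions on
the circle (reads may wrap the origin), uniform strand, truncated-normal
lengths (defaults mean 880 bp, sd mean/3, hard floor 50 bp — the QC
floor — and cap 2,261 bp), and i.i.d. substitution errors at a
configurable rate (default 2.7 × 10⁻⁴). Indels, chimeras, coverage
biases and the sub-read consensus process of real CCS are **not**
modelled; a per-read scalar quality in [0, 1], defined as one minus the
realized mismatch fraction, stands in for the platform's per-read
quality score, which is never formally defined in public material.
Reads are drawn until total bases reach coverage × genome length, so the
realized coverage overshoots by at most one read. Passing tests on this
generator therefore demonstrate correctness of the algorithms under the
stated error model, not robustness to indel-rich or biased real data.

`simulate_amplicons` slices target ranges and plants an exact number of
substitutions at positions drawn without replacement across the
concatenated targets — the ground truth for validation arithmetic.

All randomness in a module flows from one explicit integer seed;
identical seeds give byte-identical outputs.

## Assembly

`greedy_assemble` seeds with the longest QC-passing read and alternates
extending the 3′ and 5′ ends with the best-scoring unused read. Overlap
scoring is gapless — match +1, mismatch −2 — over terminal overlaps of
at least `min_overlap` (default 50 bp) at identity ≥ `min_identity`
(default 0.90, mirroring the repeat-analysis identity convention), with
ties broken toward the longer extension and then the lexicographically
smallest read id. Candidate overlaps are found by exact k-mer seeding;
the seed size is chosen from the pigeonhole bound
ceil((L − m)/(m + 1)) over qualifying lengths L and mismatch budgets m,
which guarantees every alignment that can pass the identity filter
shares an exact k-mer with the target, so seeded search returns the
same optimum as exhaustive all-offset scoring (the oracle tests assert
exactly this). Gapless scoring is adequate because the simulator is
substitution-only; there is no indel-aware polishing.

Termination per end: (a) no qualifying extension; (b) the chosen
candidate's novel sequence aligns to the existing draft in
reverse-complement orientation over ≥ min_overlap bases — the signature
of reaching the far boundary of the *second* IR copy. On (b) the unique
lead-in of the novel sequence is laid down, the mirror anchor (the
diagonal of the RC alignment) is recorded, and the end stops
(`ir_closed`). The whole assembly stops when the two contig ends overlap
each other by ≥ min_overlap at ≥ min_identity; the duplicated junction
is trimmed once, keeping the 5′ copy. When both ends stop at the second
IR copy, the circle is completed by mirroring: the unwalked stretch of
the circle equals the reverse complement of the draft between the two
recorded anchors. An earlier design that merely flagged (b) and kept
extending could run around the circle twice when the two ends committed
to different SSC orientations; terminating at the second copy makes the
SSC-exit decision unique and the completion deterministic.

**Isomer ambiguity.** When the IR is longer than the longest read, no
read spans a full IR copy and the orientation of the SSC relative to the
LSC is information-theoretically unidentifiable — plastid DNA in vivo is
an equimolar mix of the two inversion isomers, and published genomes fix
the orientation by convention or reference. The assembler accordingly
recovers the exact truth when reads can anchor through the IR and one of
the two isomers otherwise. `quadripartite.flip_ssc` converts between
isomers; the end-to-end recovery test scores equivalence up to that
inversion, and the pipeline report states both the strict and the
isomer-tolerant comparison.

`map_reads` places each read at its best full-length gapless position on
the (doubled, if circular) draft, both strands, discarding reads whose
best identity is below threshold; ties prefer more matches, the forward
strand, then the smaller start. `call_consensus` takes the per-column
majority with ties broken A < C < G < T and zero-depth columns keeping
the draft base. At coverage 50× and error rates ≤ 1%, the probability
that a column's majority is wrong is negligible, which is why the
end-to-end identity criterion (≥ 99.97%) is met with margin.

## Quadripartite structure

`find_ir_pair` finds the longest exact inverted-repeat pair with
disjoint intervals on the circle by binary search on length, comparing
rolling polynomial hashes (two 31-bit prime moduli folded into one
64-bit key; candidates verified exactly) of the doubled sequence against
its reverse complement. Exact matching is appropriate because both the
generator and the assembler's mirror completion produce perfect copies;
a mismatch-tolerant mode is deliberately out of scope. Ties break toward
the smallest IRa start. Junction-ambiguous bases are assigned by
maximality — whichever copy the exact extension reaches first — which is
one of the two defensible conventions.

`partition_regions` names the longer arc LSC; `canonicalize` rotates the
circle to start at the LSC and picks the strand on which the SSC is
lexicographically ≤ its reverse complement, making the canonical form
rotation- and reflection-invariant (note this fixes the *strand*, not
the isomer: the two SSC-orientation isomers remain distinct sequences,
as they should). GC percentages round half-up to 1 decimal, matching
table precision.

## Repeats and SSRs

The dispersed-repeat scanner enumerates, per alignment diagonal (forward
for F hits, against the reverse complement for P hits), all maximal
windows containing at most 3 mismatches (the Hamming budget at the 30 bp
/ 90% cutoff); a window is maximal when any extension adds a fourth
mismatch or crosses the boundary, so planted exact copies are often
reported slightly longer than planted, extended into flanking sequence
within the budget. Hits contained in a longer hit of the same type (both
intervals nested) are suppressed. E-value ranking of the original
suffix-tree tool is not reproduced.

Tandem detection is exact: a maximal run where S[i] = S[i+p] for a
period p ≥ 10 yields an array of length run + p; arrays need ≥ 2 copies
and ≥ 30 bp, and the unit must be primitive (its minimal period is p),
which also dereplicates reports at multiples of the true period. The
probabilistic alignment scoring of the classic tandem-repeat finder is
intentionally not reproduced; every published array in the target table
is an exact ×2 array that this detector reports identically.

SSR scanning uses the same maximal-run machinery for unit sizes 1–6 with
copy thresholds mono 8 / di 4 / tri 3 / tetra 3 / penta 3 / hexa 3 (the
published thresholds sentence maps three numbers onto six size classes;
di = 4 follows the sentence order). Partial trailing units do not count
toward copies; primitivity again ensures a run is reported once at its
smallest unit. Adjacent loci are reported separately (no compound-locus
merging). Motif classes group units by their lexicographically smallest
rotation (AT/TA → AT) without strand collapsing, since published mono
counts keep A and T separate.

Circular scanning doubles the sequence and deduplicates wrapped
coordinates; the default is linear, matching scans of a linearized
deposited record.

## Codon usage

RSCU_i = n_i · k / Σn over the codon's synonymous family (k = family
size). Two conventions are required to regenerate the published table
exactly and are therefore built in: the three stop codons form one
family (36/((36+26+22)/3) = 1.29), and serine is one six-codon family
(UCN + AGU/AGC, giving UCU = 1.67). Families with zero total have
undefined RSCU. Display rounding is half-up to 2 decimals; full
precision is kept internally. The genetic code is the bacterial/plastid
table (whose 64 assignments coincide with the standard code), taken from
Biopython's code tables. Anticodon matching is strict Watson–Crick
(anticodon = reverse complement of codon, U ≡ T); wobble pairing is out
of scope. Duplicate anticodons (initiator vs elongator Met) are joined
and flagged with a warning.

## Validation and reporting

Mean read length rounds half-up to an integer; coverage is total bases /
genome length, printed as the nearest integer. Validation places each
reference amplicon at its best gapless position (exhaustive over all
offsets and both strands, chunked to bound memory) on the doubled
assembly; references below 80% best identity are flagged unlocatable and
excluded; error rate = 100 · mismatches / aligned bases and accuracy its
complement, both half-up at 3 decimals, so accuracy + error = 100.000
exactly before rounding. `run_pipeline` chains all stages, labels any
failure with its stage, and emits a JSON report that is byte-identical
across runs with the same seed apart from timings.

## Problem sizes and numerical choices

The test suite exercises genomes from toy circles up to the full
156,749 bp scale (structure and partition arithmetic); end-to-end
assembly recovery runs ten seeded 6–15.5 kb genomes with IRs of
0.5–2 kb at coverage 50× and error rates {0, 0.5%, 1%}, sizes chosen to
keep the whole recovery experiment around two minutes on one CPU while
spanning the regimes where IR traversal is trivial (IR ≪ read length)
and where the isomer decision is a coin flip (IR > max read length).
Identity thresholds are applied with a 10⁻⁹ absolute epsilon so exact
boundaries like 3 mismatches over 30 bp survive binary floating point.
All rounding that feeds printed tables is decimal half-up, not banker's
rounding.

## Known limitations

Substitution-only error model (no indels or chimeras); gapless overlap
and mapping (adequate only under that model); exact-match IR detection;
single-contig assembly only (no scaffolding or multi-contig resolution);
no gene annotation, no wobble pairing, no SSR compound merging, no
primer design. The SSC-orientation isomer cannot be, and is not,
resolved from reads shorter than the IR.
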