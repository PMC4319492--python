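"""Codon counting, relative synonymous codon usage and anticodon pairing.

RSCU for codon *i* in a synonymous family of size *k* with counts *n* is

    RSCU_i = n_i / mean(n) = n_i * k / sum(n)

so 1 means no bias.  Stop codons are treated as one three-member family
and serine's family spans all six of its codons (UCN plus AGU/AGC).  The
genetic code used is the bacterial/plastid table, whose 64 codon
assignments coincide with the standard code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data import CodonTable

from ._seq import round_half_up, revcomp

__all__ = ["GeneticCode", "CodonCounts", "RSCUEntry", "RSCUTable",
           "count_codons", "compute_rscu", "match_anticodons",
           "at_content", "to_rna", "to_dna"]


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """Codon-to-amino-acid map plus the synonymous-family partition."""

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]]

    @classmethod
    def plastid(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[11]
        codon_to_aa = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_to_aa[stop] = "*"
        families: dict[str, list[str]] = {}
        for codon, aa in sorted(codon_to_aa.items()):
            families.setdefault(aa, []).append(codon)
        return cls(codon_to_aa=codon_to_aa,
                   families={aa: tuple(v) for aa, v in families.items()})

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[to_dna(codon)]]


@dataclass(frozen=True)
class CodonCounts:
    counts: dict[str, int]

    def __post_init__(self):
        for codon, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {codon}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(to_dna(codon), 0)


@dataclass(frozen=True)
class RSCUEntry:
    codon: str  # RNA spelling, as usage tables print it
    amino_acid: str
    count: int
    rscu: float | None  # None when the whole family is unobserved
    trna: str | None = None

    @property
    def rscu_display(self) -> float | None:
        return None if self.rscu is None else round_half_up(self.rscu, 2)


@dataclass(frozen=True)
class RSCUTable:
    entries: dict[str, RSCUEntry]  # keyed by RNA codon

    def __getitem__(self, codon: str) -> RSCUEntry:
        return self.entries[to_rna(codon)]

    def __iter__(self):
        return iter(self.entries.values())


def count_codons(cds_sequences) -> CodonCounts:
    """Count non-overlapping triplets from position 0 of each CDS.

    Accepts plain sequences or (id, sequence) pairs; U is read as T.
    Sequences must be in frame (length divisible by 3) and unambiguous.
    """
    counts: dict[str, int] = {}
    for i, item in enumerate(cds_sequences):
        if isinstance(item, (tuple, list)):
            sid, seq = item
        else:
            sid, seq = f"seq{i}", item
        seq = to_dna(seq)
        if len(seq) % 3:
            raise ValueError(f"CDS {sid!r} length {len(seq)} not a "
                             "multiple of 3")
        if set(seq) - set("ACGT"):
            raise ValueError(f"CDS {sid!r} contains ambiguity characters")
        for j in range(0, len(seq), 3):
            codon = seq[j:j + 3]
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts=counts)


def compute_rscu(counts: CodonCounts,
                 code: GeneticCode | None = None,
                 trnas: list[tuple[str, str]] | None = None) -> RSCUTable:
    """RSCU per codon: count * family_size / family_total.

    Families with zero total get an undefined (None) RSCU.  Full
    precision is kept; ``rscu_display`` rounds half-up to 2 decimals as
    printed usage tables do.
    """
    code = code or GeneticCode.plastid()
    anticodon_map = match_anticodons(
        list(code.codon_to_aa), trnas) if trnas else {}
    entries = {}
    for aa, family in code.families.items():
        family_total = sum(counts.get(c) for c in family)
        k = len(family)
        for codon in family:
            c = counts.get(codon)
            rscu = (c * k / family_total) if family_total else None
            rna = to_rna(codon)
            entries[rna] = RSCUEntry(
                codon=rna, amino_acid=aa, count=c, rscu=rscu,
                trna=anticodon_map.get(to_rna(codon)))
    return RSCUTable(entries=entries)


def match_anticodons(codons: list[str],
                     trnas: list[tuple[str, str]] | None) -> dict:
    """Watson-Crick codon-anticodon pairing (no wobble).

    A tRNA recognizes a codon when its anticodon is the reverse
    complement of the codon.  Several tRNAs sharing one anticodon (e.g.
    initiator and elongator Met) are flagged with a warning and joined.
    """
    out: dict[str, str | None] = {}
    if not trnas:
        return {to_rna(c): None for c in codons}
    by_anticodon: dict[str, list[str]] = {}
    for name, anticodon in trnas:
        by_anticodon.setdefault(to_dna(anticodon), []).append(name)
    for anticodon, names in by_anticodon.items():
        if len(names) > 1:
            warnings.warn(f"duplicate anticodon {to_rna(anticodon)} for "
                          f"{', '.join(names)}", stacklevel=2)
    for codon in codons:
        anticodon = revcomp(to_dna(codon))
        names = by_anticodon.get(anticodon)
        out[to_rna(codon)] = ", ".join(names) if names else None
    return out


def at_content(sequence: str) -> float:
    """A+T percentage, 1-decimal half-up; complements the GC content."""
    if not sequence:
        raise ValueError("empty sequence")
    s = to_dna(sequence)
    return round_half_up(100.0 * (s.count("A") + s.count("T")) / len(s), 1)


def extract_cds_from_gff(sequence: str, gff_path) -> list[tuple[str, str]]:
    """Extract in-frame CDS sequences from a genome and a GFF3 file.

    CDS features (1-based inclusive coordinates) sharing a Parent (or
    ID) are concatenated in file order; minus-strand genes are
    reverse-complemented after concatenation of their parts in declared
    order.  Returns (gene_id, sequence) pairs.
    """
    parts: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            start, end, strand = int(fields[3]), int(fields[4]), fields[6]
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";")
                         if "=" in kv)
            gid = attrs.get("Parent") or attrs.get("ID") \
                or f"cds_{start}_{end}"
            if gid not in parts:
                parts[gid] = []
                order.append(gid)
            parts[gid].append((sequence[start - 1:end], strand))
    out = []
    for gid in order:
        segs = parts[gid]
        strand = segs[0][1]
        joined = "".join(s for s, _ in segs)
        out.append((gid, revcomp(joined) if strand == "-" else joined))
    return out
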