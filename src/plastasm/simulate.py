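"""Synthetic quadripartite plastome and CCS-like read simulation.

A plastid genome is modelled as a circle of four regions in the order
LSC - IRa - SSC - IRb, where IRb is the exact reverse complement of IRa.
Region lengths and GC contents are free parameters; the defaults follow
the layout typical of land-plant chloroplast genomes.  Features (SSRs,
tandem arrays, dispersed repeat copies, CDS segments) can be planted at
known coordinates so that every scanner downstream has a ground truth.

Reads emulate circular-consensus (CCS) long reads: start positions are
uniform on the circle, strands are uniform, lengths follow a truncated
normal, and errors are i.i.d. substitutions.  Each read carries a scalar
quality in [0, 1] defined as one minus its realized mismatch fraction,
standing in for the platform's per-read quality score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import BASES, decode, encode, revcomp

__all__ = [
    "GenomeSpec", "PlantedFeature", "SyntheticPlastome", "Read", "ReadSet",
    "build_plastome", "plant_features", "simulate_ccs_reads",
    "simulate_amplicons",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Region lengths (bp), per-region GC fractions and the RNG seed."""

    lsc_len: int
    ssc_len: int
    ir_len: int
    gc_lsc: float = 0.361
    gc_ssc: float = 0.327
    gc_ir: float = 0.430
    seed: int = 0

    def __post_init__(self):
        for name in ("lsc_len", "ssc_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ir_len < 0:
            raise ValueError("ir_len must be >= 0")
        for name in ("gc_lsc", "gc_ssc", "gc_ir"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def total(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class PlantedFeature:
    """A feature written into the genome at known coordinates.

    Coordinates are 0-based half-open on the canonical rotation.  The
    payload holds the literal sequence written plus descriptive fields
    (unit/copies for SSRs and tandem arrays).
    """

    kind: str  # SSR | tandem | forward_repeat | inverted_repeat | CDS
    start: int
    end: int
    payload: dict = field(default_factory=dict)

    KINDS = frozenset({"SSR", "tandem", "forward_repeat",
                       "inverted_repeat", "CDS"})

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        seq = self.payload.get("seq")
        if seq is not None and len(seq) != self.end - self.start:
            raise ValueError("payload sequence length != coordinate span")
        if self.kind == "CDS" and (self.end - self.start) % 3:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def seq(self) -> str:
        if "seq" in self.payload:
            return self.payload["seq"]
        unit, copies = self.payload["unit"], self.payload["copies"]
        return (unit * -(-int(np.ceil(copies * len(unit))) // len(unit))
                )[: self.end - self.start]


@dataclass(frozen=True)
class Regions:
    """0-based half-open intervals of the four regions on the circle."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]


@dataclass(frozen=True)
class SyntheticPlastome:
    sequence: str
    regions: Regions
    truth: tuple[PlantedFeature, ...] = ()
    spec: GenomeSpec | None = None

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: float
    origin: tuple[int, int, str] | None = None  # start, end, strand

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class ReadSet:
    reads: tuple[Read, ...]

    def __post_init__(self):
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate read ids")
        for r in self.reads:
            if not r.sequence:
                raise ValueError(f"empty sequence for read {r.id}")

    def __len__(self):
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)


def _random_region(rng: np.random.Generator, length: int,
                   gc: float) -> np.ndarray:
    """Region with *exactly* round(gc * length) strong (G/C) bases."""
    n_gc = int(round(gc * length))
    strong = np.zeros(length, dtype=bool)
    strong[rng.choice(length, size=n_gc, replace=False)] = True
    out = np.empty(length, dtype=np.uint8)
    out[strong] = rng.choice([1, 2], size=n_gc)          # C or G
    out[~strong] = rng.choice([0, 3], size=length - n_gc)  # A or T
    return out


def build_plastome(spec: GenomeSpec) -> SyntheticPlastome:
    """Build a random circular genome LSC + IRa + SSC + IRb.

    IRb is constructed as the exact reverse complement of IRa, and each
    region's GC count is fixed to round(gc * length), so empirical GC
    matches the spec to well within rounding for any region size.
    """
    rng = np.random.default_rng(spec.seed)
    lsc = _random_region(rng, spec.lsc_len, spec.gc_lsc)
    ira = (_random_region(rng, spec.ir_len, spec.gc_ir)
           if spec.ir_len else np.empty(0, dtype=np.uint8))
    ssc = _random_region(rng, spec.ssc_len, spec.gc_ssc)
    if spec.ir_len:
        # break chance complementarity at the IR boundaries so the
        # planted IR pair is exactly maximal; flipping a base to its
        # complement stays within its GC class
        if lsc.size > 1 and lsc[-1] == 3 - lsc[0]:
            lsc[-1] = 3 - lsc[-1]
        if ssc.size > 1 and ssc[0] == 3 - ssc[-1]:
            ssc[0] = 3 - ssc[0]
    seq_lsc, seq_ira, seq_ssc = decode(lsc), decode(ira), decode(ssc)
    seq = seq_lsc + seq_ira + seq_ssc + revcomp(seq_ira)
    l, i, s = spec.lsc_len, spec.ir_len, spec.ssc_len
    regions = Regions(lsc=(0, l), ira=(l, l + i),
                      ssc=(l + i, l + i + s), irb=(l + i + s, l + 2 * i + s))
    return SyntheticPlastome(sequence=seq, regions=regions, spec=spec)


def _region_of(regions: Regions, start: int, end: int) -> str | None:
    for name in ("lsc", "ira", "ssc", "irb"):
        a, b = getattr(regions, name)
        if a <= start and end <= b:
            return name
    return None


def plant_features(genome: SyntheticPlastome,
                   features: list[PlantedFeature]) -> SyntheticPlastome:
    """Write features into the genome and re-mirror IRb from IRa.

    Features must not overlap each other, must fit inside a single
    region, and may not target IRb (which is regenerated as the reverse
    complement of IRa after planting, so IR symmetry always holds).
    """
    ordered = sorted(features, key=lambda f: f.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping features at {a.start}-{a.end} / "
                f"{b.start}-{b.end}")
    n = len(genome.sequence)
    seq = list(genome.sequence)
    for f in ordered:
        if not (0 <= f.start < f.end <= n):
            raise ValueError(f"feature {f.start}-{f.end} outside genome")
        region = _region_of(genome.regions, f.start, f.end)
        if region is None:
            raise ValueError(
                f"feature {f.start}-{f.end} straddles a region boundary")
        if region == "irb":
            raise ValueError("plant into IRa instead of IRb; IRb is "
                             "regenerated as its mirror")
        fs = f.seq.upper()
        if set(fs) - set(BASES):
            raise ValueError("feature sequence must be over ACGT")
        seq[f.start:f.end] = fs
    ia, ib = genome.regions.ira, genome.regions.irb
    ira_seq = "".join(seq[ia[0]:ia[1]])
    seq[ib[0]:ib[1]] = revcomp(ira_seq)
    return replace(genome, sequence="".join(seq),
                   truth=genome.truth + tuple(ordered))


def simulate_ccs_reads(genome: SyntheticPlastome, coverage: float,
                       mean_len: int = 880, len_sd: float | None = None,
                       max_len: int = 2261, error_rate: float = 0.00027,
                       seed: int = 0, min_len: int = 50) -> ReadSet:
    """Sample CCS-like reads uniformly from the circular genome.

    Reads are drawn until total bases reach ``coverage * genome length``
    (so realized coverage overshoots by at most one read).  Lengths are
    truncated-normal in [min_len, max_len] (sd defaults to mean/3);
    substitution errors are i.i.d. at ``error_rate``; per-read quality is
    1 minus the realized mismatch fraction.
    """
    if not np.isfinite(coverage) or coverage < 0:
        raise ValueError("coverage must be a finite non-negative number")
    if mean_len < 1:
        raise ValueError("mean_len must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(genome.sequence)
    arr = encode(genome.sequence)
    doubled = np.concatenate([arr, arr])
    target = coverage * n
    sd = mean_len / 3.0 if len_sd is None else len_sd
    reads: list[Read] = []
    total = 0
    while total < target:
        if sd > 0:
            length = 0
            while not (min_len <= length <= max_len):
                length = int(round(rng.normal(mean_len, sd)))
        else:
            length = max(min_len, min(mean_len, max_len))
        length = min(length, n)
        start = int(rng.integers(0, n))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        frag = doubled[start:start + length].copy()
        if strand == "-":
            frag = frag[::-1]
            frag = np.array([3, 2, 1, 0], dtype=np.uint8)[frag]
        n_err = 0
        if error_rate > 0:
            err = rng.random(length) < error_rate
            n_err = int(err.sum())
            if n_err:
                shifts = rng.integers(1, 4, size=n_err).astype(np.uint8)
                frag[err] = (frag[err] + shifts) % 4
        reads.append(Read(
            id=f"read{len(reads):06d}",
            sequence=decode(frag),
            quality=1.0 - n_err / length,
            origin=(start, (start + length) % n, strand)))
        total += length
    return ReadSet(reads=tuple(reads))


def simulate_amplicons(genome: SyntheticPlastome,
                       targets: list[tuple[int, int]],
                       mismatches: int, seed: int = 0) -> list[str]:
    """Slice target ranges and plant exactly ``mismatches`` substitutions.

    The substituted positions are drawn without replacement across the
    concatenation of all targets, emulating Sanger amplicons that differ
    from the assembly at a known number of sites.
    """
    if mismatches < 0:
        raise ValueError("mismatches must be >= 0")
    n = len(genome.sequence)
    for a, b in targets:
        if not (0 <= a < b <= n):
            raise ValueError(f"range {a}-{b} outside genome")
    rng = np.random.default_rng(seed)
    slices = [encode(genome.sequence[a:b]) for a, b in targets]
    total = sum(s.size for s in slices)
    if mismatches > total:
        raise ValueError("more mismatches than target bases")
    flat_pos = rng.choice(total, size=mismatches, replace=False)
    bounds = np.cumsum([0] + [s.size for s in slices])
    for p in flat_pos:
        i = int(np.searchsorted(bounds, p, side="right")) - 1
        j = int(p - bounds[i])
        slices[i][j] = (slices[i][j] + rng.integers(1, 4)) % 4
    return [decode(s) for s in slices]
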