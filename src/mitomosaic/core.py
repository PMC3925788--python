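"""Shared domain types and sequence utilities.

Coordinates are 1-based inclusive throughout, matching the conventions of
BLAST tabular output and GFF3. Circular sequences are stored linearised from
an arbitrary origin; helpers here handle slices that wrap around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase A/C/G/T)."""
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code; '*' marks stops.

    Plant mitochondria use the standard code for the codons relevant here,
    so no organellar code table is applied.
    """
    return str(Seq(cds).translate())


@dataclass(frozen=True)
class CircularGenome:
    """A DNA sequence with (optionally) circular topology.

    The coordinate frame for every downstream analysis: positions are
    1-based inclusive on the stored linearisation.
    """

    id: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"genome contains non-ACGT characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Extract [start, end] 1-based inclusive; wraps the origin when circular."""
        n = len(self.sequence)
        if start < 1 or end < start:
            raise ValueError(f"invalid interval [{start}, {end}]")
        if end <= n:
            return self.sequence[start - 1 : end]
        if not self.is_circular:
            raise ValueError(f"interval [{start}, {end}] exceeds linear sequence of length {n}")
        if end - start + 1 > n:
            raise ValueError("interval longer than the circle")
        return (self.sequence + self.sequence)[start - 1 : end]


@dataclass(frozen=True)
class GeneAnnotation:
    """A single-exon gene model on a reference sequence."""

    gene_id: str
    start: int
    end: int
    strand: str
    type: str = "gene"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def cds(self, genome: CircularGenome) -> str:
        """Coding sequence in gene orientation."""
        s = genome.fetch(self.start, self.end)
        return revcomp(s) if self.strand == "-" else s


@dataclass
class RepeatPair:
    """One direct or inverted repeat occurrence pair.

    ``start1 < start2`` under canonical ordering; for inverted pairs the
    second occurrence is the reverse complement of the first, up to
    ``mismatches`` substitutions.
    """

    start1: int
    start2: int
    length: int
    orientation: str  # "direct" | "inverted"
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in {"direct", "inverted"}:
            raise ValueError("orientation must be 'direct' or 'inverted'")
        if self.start1 >= self.start2:
            raise ValueError("canonical ordering requires start1 < start2")

    def key(self) -> tuple:
        return (self.start1, self.start2, self.length, self.orientation)


@dataclass
class TruthSet:
    """Ground truth emitted by the simulator for recovery tests."""

    planted_repeats: list[RepeatPair] = field(default_factory=list)
    # each junction: (subject-coordinate pair on the pre-recombination genome,
    #                 footprint length in bp)
    planted_junctions: list[tuple[tuple[int, int], int]] = field(default_factory=list)
    # each editing site: (position, gene_id, codon_pos, per-sample presence)
    planted_editing: list[dict] = field(default_factory=list)
    # contig_id -> ((start, end, orientation on source genome), "mito"|"nuclear_copy")
    contig_origins: dict[str, tuple[tuple, str]] = field(default_factory=dict)
    genes: list[GeneAnnotation] = field(default_factory=list)
    # optional: planted fusion design (gene id, retained tail aa, junction position)
    planted_fusion: dict | None = None
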