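"""Chimeric ORF detection at rearrangement breakpoints.

Cytoplasmic male sterility is typically caused by a novel transcript that
fuses part of an ATP-synthase gene to unrelated sequence across a
recombination junction. This module finds ORFs spanning a breakpoint and
matches their peptides against the known gene peptides by longest identical
block: a recombination-derived chimera is *identical* to the donor gene over
the retained region, so ungapped exact matching (no substitution matrix) is
the right instrument, and the block length reports how much of the donor —
typically its carboxyl-terminal tail — the chimera retains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import STOP_CODONS, CircularGenome, GeneAnnotation, revcomp, translate

#: identical blocks shorter than this are indistinguishable from chance
MIN_REPORTED_BLOCK = 15


@dataclass(frozen=True)
class ORF:
    """An open reading frame: ATG..stop, coordinates 1-based inclusive.

    ``end - start + 1`` is divisible by 3 and includes the stop codon; the
    peptide excludes it. ``frame`` is 0-2 on the reading strand.
    """

    start: int
    end: int
    strand: str
    frame: int
    peptide: str
    seq_id: str = ""


@dataclass(frozen=True)
class FusionCall:
    """A breakpoint-spanning ORF matching part of a known gene peptide."""

    breakpoint: int
    orf: ORF
    matched_gene: str
    n_identical_aa: int
    n_extra_aa: int
    matched_region: str  # amino-terminal | carboxyl-terminal | internal | complete


def _scan_strand(seq: str, min_aa: int, strand: str, total_len: int):
    """Yield ORFs on one reading strand of a linear sequence."""
    n = len(seq)
    for frame in range(3):
        atg = None  # first ATG after the previous in-frame stop
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if codon == "ATG" and atg is None:
                atg = p
            if codon in STOP_CODONS:
                if atg is not None and (p - atg) // 3 >= min_aa:
                    peptide = translate(seq[atg:p])
                    if strand == "+":
                        start, end = atg + 1, p + 3
                    else:
                        start, end = total_len - (p + 3) + 1, total_len - atg
                    yield ORF(start=start, end=end, strand=strand,
                              frame=frame, peptide=peptide)
                atg = None


def find_orfs(sequence: str, min_aa: int = 30, seq_id: str = "") -> list[ORF]:
    """All ORFs of >= min_aa residues, both strands, all six frames.

    ATG starts only; the standard genetic code; an ORF runs from the first
    ATG after the previous in-frame stop to the next stop (which must be
    present — truncated reading frames at the sequence end are not ORFs).
    Coordinates are reported on the forward strand of ``sequence``.
    """
    orfs = []
    n = len(sequence)
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for orf in _scan_strand(seq, min_aa, strand, n):
            orfs.append(ORF(start=orf.start, end=orf.end, strand=orf.strand,
                            frame=orf.frame, peptide=orf.peptide, seq_id=seq_id))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def longest_identical_block(a: str, b: str) -> tuple[int, int, int]:
    """Longest common substring of two peptides.

    Returns (length, start_in_a, start_in_b); ties resolve to the earliest
    position in ``a`` then ``b``.
    """
    best = (0, 0, 0)
    if not a or not b:
        return best
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[0]:
                    best = (cur[j], i - cur[j], j - cur[j])
        prev = cur
    return best


def gene_peptides(genome: CircularGenome, genes: list[GeneAnnotation]) -> dict[str, str]:
    """Translate each gene's CDS; trailing stop stripped."""
    out = {}
    for g in genes:
        pep = translate(g.cds(genome))
        out[g.gene_id] = pep.rstrip("*")
    return out


def call_fusions(
    breakpoints: list[int],
    genome: CircularGenome,
    peptides: dict[str, str],
    flank: int = 500,
    min_aa: int = 30,
    min_block: int = MIN_REPORTED_BLOCK,
) -> list[FusionCall]:
    """Call chimeric ORFs at rearrangement breakpoints.

    For each breakpoint position, ORFs within ``flank`` bp on either side
    that span the junction are matched against every known gene peptide;
    the best gene (longest identical block) is reported when the block
    reaches ``min_block`` residues. ``n_extra_aa`` counts ORF residues
    outside the matching block. ``matched_region`` locates the block within
    the *gene* peptide (amino-terminal / carboxyl-terminal / internal /
    complete), which for CMS candidates is typically carboxyl-terminal.
    """
    n = len(genome)
    calls = []
    for pos in breakpoints:
        if not 1 <= pos <= n:
            raise ValueError(f"breakpoint {pos} outside genome bounds 1..{n}")
        if genome.is_circular:
            start0 = (pos - 1 - flank) % n
            window = (genome.sequence * 2)[start0 : start0 + 2 * flank + 1]
            junction = flank + 1  # 1-based offset of the breakpoint in the window
        else:
            w_lo = max(1, pos - flank)
            w_hi = min(n, pos + flank)
            start0 = w_lo - 1
            window = genome.sequence[w_lo - 1 : w_hi]
            junction = pos - start0
        for orf in find_orfs(window, min_aa=min_aa, seq_id=genome.id):
            if not orf.start <= junction <= orf.end:
                continue
            best = None
            for gene_id, pep in peptides.items():
                blk, _, b_start = longest_identical_block(orf.peptide, pep)
                if best is None or blk > best[0]:
                    best = (blk, gene_id, b_start, len(pep))
            if best is None or best[0] < min_block:
                continue
            blk, gene_id, b_start, pep_len = best
            if blk == pep_len:
                region = "complete"
            elif b_start + blk == pep_len:
                region = "carboxyl-terminal"
            elif b_start == 0:
                region = "amino-terminal"
            else:
                region = "internal"
            placed = ORF(
                start=start0 + orf.start, end=start0 + orf.end,
                strand=orf.strand, frame=orf.frame,
                peptide=orf.peptide, seq_id=genome.id,
            )
            calls.append(FusionCall(
                breakpoint=pos, orf=placed, matched_gene=gene_id,
                n_identical_aa=blk, n_extra_aa=len(orf.peptide) - blk,
                matched_region=region,
            ))
    return calls
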