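"""Synthetic circular mitogenomes with planted, recoverable structure.

The generator emulates the statistical structure the downstream analyses
assume: a circular genome with dispersed direct/inverted repeats, ORF-bearing
genes, repeat-mediated recombination producing rearranged variants whose
junctions carry the recombining repeat as a footprint, contig fragmentation
with low-depth nuclear-copy decoys, and C->U RNA-editing sites visible in
per-sample RNA pileups. Every planted feature is recorded in a
:class:`~mitomosaic.core.TruthSet` so recovery can be scored exactly.

All randomness flows from one ``numpy`` Generator; every operation accepts
an explicit ``rng`` (or derives one from ``config.rng_seed``), and
:func:`simulate_all` runs the full pipeline off a single stream in a fixed,
documented order, so identical configs give byte-identical outputs.

Background sequence is i.i.d. uniform over A/C/G/T: repeat and depth
statistics, not base composition, are what the downstream methods key on.
Planted repeat copies get mismatching flanking bases ("hardened" borders) so
that the planted coordinates are exactly the maximal-repeat coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    STOP_CODONS,
    CircularGenome,
    GeneAnnotation,
    RepeatPair,
    TruthSet,
    revcomp,
    translate,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


class PlacementError(RuntimeError):
    """Raised when planted features cannot be placed without overlap."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic mitogenome, with defaults at study scale.

    The defaults mirror the observed properties the analyses target: a
    dominant 101 bp direct repeat pair carrying one mismatch plus a larger
    exact inverted repeat; contig read depths spread over a three-fold
    range; nuclear-copy decoys below 10% of mitochondrial depth; six RNA
    samples with heavily (80%) edited C->U sites. The genome length is a
    free parameter kept at desk scale (12 kb).
    """

    genome_length: int = 12_000
    # (length, orientation, mismatches planted into the second copy)
    repeat_spec: tuple[tuple[int, str, int], ...] = (
        (101, "direct", 1),
        (300, "inverted", 0),
    )
    n_genes: int = 6
    gene_length_range: tuple[int, int] = (300, 900)
    n_recombinations: int = 1
    contig_break_rate: float = 1e-3
    nuclear_copy_fraction: float = 0.25
    depth_mean: float = 100.0
    nuclear_depth_ratio: float = 0.08
    editing_sites: int = 30
    editing_fraction: float = 0.8
    pileup_error_rate: float = 0.0
    n_rna_samples: int = 6
    # sample_id -> how many planted sites to leave unedited in that sample
    differential_omissions: dict[str, int] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeat_spec:
            longest = max(ln for ln, _, _ in self.repeat_spec)
            if self.genome_length <= 2 * longest:
                raise ValueError("genome_length must exceed twice the longest repeat")
        for name in ("contig_break_rate", "nuclear_copy_fraction",
                     "editing_fraction", "pileup_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.nuclear_depth_ratio < 1.0:
            raise ValueError("nuclear_depth_ratio must be in [0, 1)")
        for ln, ori, mm in self.repeat_spec:
            if ori not in {"direct", "inverted"}:
                raise ValueError(f"bad repeat orientation {ori!r}")
            if mm >= ln:
                raise ValueError("repeat mismatches must be fewer than its length")

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_rna_samples)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


# ---------------------------------------------------------------------------
# feature placement helpers
# ---------------------------------------------------------------------------

class _Registry:
    """Occupied-interval registry; placements get a guard margin."""

    def __init__(self, n: int, margin: int = 20):
        self.n = n
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def reserve(self, length: int, rng: np.random.Generator, tries: int = 500) -> int:
        """Return a 0-based start for a non-wrapping, non-overlapping interval."""
        for _ in range(tries):
            start = int(rng.integers(self.margin, self.n - length - self.margin))
            lo, hi = start - self.margin, start + length + self.margin
            if all(hi <= a or lo >= b for a, b in self.taken):
                self.taken.append((lo, hi))
                return start
        raise PlacementError(
            f"could not place a {length} bp feature on a {self.n} bp genome"
        )


def _random_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]

def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons - 2) sense codons + stop; length 3 * n_codons."""
    body = "".join(
        _NON_STOP_CODONS[int(i)]
        for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 2)
    )
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    return "ATG" + body + stop


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_master_circle(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CircularGenome, TruthSet]:
    """Generate a circular genome with planted repeats and ORF-bearing genes.

    Repeats are written as fresh random sequence at both occurrence sites
    (the second copy reverse-complemented for inverted pairs, with the
    requested number of interior substitutions), and their flanks are forced
    to mismatch so the planted pair is maximal at exactly the planted
    coordinates. Planted features never wrap the origin. Raises
    :class:`PlacementError` when the requested features cannot be placed.
    """
    rng = config.rng() if rng is None else rng
    n = config.genome_length
    arr = _random_sequence(n, rng)
    seq = bytearray(arr.tobytes())
    registry = _Registry(n)
    truth = TruthSet()

    # genes first (largest features), then repeats
    lo, hi = config.gene_length_range
    for g in range(config.n_genes):
        n_codons = max(3, int(rng.integers(lo, hi + 1)) // 3)
        length = 3 * n_codons
        start0 = registry.reserve(length, rng)
        cds = _random_cds(n_codons, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        written = cds if strand == "+" else revcomp(cds)
        seq[start0 : start0 + length] = written.encode()
        truth.genes.append(
            GeneAnnotation(gene_id=f"gene{g + 1:02d}", start=start0 + 1,
                           end=start0 + length, strand=strand, type="gene")
        )

    for length, orientation, n_mm in config.repeat_spec:
        a = registry.reserve(length, rng)
        b = registry.reserve(length, rng)
        a, b = sorted((a, b))
        unit = _random_sequence(length, rng).tobytes().decode()
        seq[a : a + length] = unit.encode()
        copy2 = unit if orientation == "direct" else revcomp(unit)
        copy2 = bytearray(copy2.encode())
        # interior substitutions, spread evenly, never at the borders
        for t in range(n_mm):
            pos = 1 + (t + 1) * (length - 2) // (n_mm + 1)
            copy2[pos] = ord(_other_base(chr(copy2[pos]), rng))
        seq[b : b + length] = bytes(copy2)
        _harden_flanks(seq, a, b, length, orientation, rng)
        truth.planted_repeats.append(
            RepeatPair(start1=a + 1, start2=b + 1, length=length,
                       orientation=orientation, mismatches=n_mm)
        )

    genome = CircularGenome(id="sim_master_circle", sequence=seq.decode())
    return genome, truth


def _harden_flanks(seq: bytearray, a: int, b: int, length: int,
                   orientation: str, rng: np.random.Generator) -> None:
    """Force the bases flanking both copies to break any extension."""
    comp = str.maketrans("ACGT", "TGCA")
    n = len(seq)

    def setne(pos: int, forbidden: str) -> None:
        pos %= n
        if chr(seq[pos]) == forbidden:
            seq[pos] = ord(_other_base(forbidden, rng))

    if orientation == "direct":
        setne(b - 1, chr(seq[(a - 1) % n]))
        setne(b + length, chr(seq[(a + length) % n]))
    else:
        # leftward extension pairs seq[a-1] with comp(seq[b+length]);
        # rightward pairs seq[a+length] with comp(seq[b-1])
        setne(b + length, chr(seq[(a - 1) % n]).translate(comp))
        setne(b - 1, chr(seq[(a + length) % n]).translate(comp))


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

@dataclass
class RecombinationResult:
    """Product(s) of one crossover plus the updated truth.

    Inverted-repeat recombination yields a single genome with the
    intervening segment inverted; direct-repeat recombination on a circle
    excises it into two smaller circles (hence a list).
    """

    genomes: list[CircularGenome]
    truth: TruthSet


def apply_recombination(
    genome: CircularGenome, repeat: RepeatPair, truth: TruthSet
) -> RecombinationResult:
    """Cross over between the two copies of ``repeat``.

    Models homologous recombination: for an inverted pair the segment
    strictly between the copies is reverse-complemented in place; for a
    direct pair the circle resolves into two circles, each retaining one
    full repeat copy. Both junctions carry a full copy of the repeat (the
    footprint); the truth gains one planted junction per breakpoint, as the
    pair of pre-recombination coordinates flanking it.
    """
    s = genome.sequence
    n = len(s)
    L = repeat.length
    a0, b0 = repeat.start1 - 1, repeat.start2 - 1  # 0-based copy starts
    if a0 + L > b0:
        raise ValueError("repeat copies overlap; recombination rejected")
    if b0 + L > n:
        raise ValueError("repeat extends past the sequence end")
    copy1 = s[a0 : a0 + L]
    copy2 = s[b0 : b0 + L]
    expected = copy1 if repeat.orientation == "direct" else revcomp(copy1)
    mm = sum(x != y for x, y in zip(copy2, expected))
    if mm > max(repeat.mismatches, 0):
        raise ValueError("repeat is not present in the genome at the stated coordinates")

    new_truth = replace(
        truth,
        planted_junctions=list(truth.planted_junctions) + [
            ((a0 + L, b0 + L), L),          # copy1 end paired with copy2 end
            ((a0 + 1, b0 + 1), L),          # copy1 start paired with copy2 start
        ],
        genes=list(truth.genes),
    )

    if repeat.orientation == "inverted":
        u_r = s[: a0 + L]
        v = s[a0 + L : b0]
        rest = s[b0:]
        product = CircularGenome(
            id=genome.id + "_inv", sequence=u_r + revcomp(v) + rest,
            is_circular=genome.is_circular,
        )
        new_truth.genes = _remap_genes_inversion(truth.genes, a0 + L + 1, b0)
        return RecombinationResult(genomes=[product], truth=new_truth)

    # direct repeat on a circle: excision into two circles
    if not genome.is_circular:
        raise ValueError("direct-repeat excision requires a circular genome")
    circle1 = CircularGenome(id=genome.id + "_exA", sequence=s[a0:b0])
    circle2 = CircularGenome(id=genome.id + "_exB", sequence=s[b0:] + s[:a0])
    return RecombinationResult(genomes=[circle1, circle2], truth=new_truth)


def _remap_genes_inversion(genes: list[GeneAnnotation], lo: int, hi: int):
    """Remap gene coordinates after inverting [lo, hi] (1-based inclusive)."""
    out = []
    for g in genes:
        if g.end < lo or g.start > hi:
            out.append(g)
        elif g.start >= lo and g.end <= hi:
            out.append(GeneAnnotation(
                gene_id=g.gene_id,
                start=lo + hi - g.end,
                end=lo + hi - g.start,
                strand="-" if g.strand == "+" else "+",
                type=g.type,
            ))
        # genes straddling an inversion border are broken; drop them
    return out


# ---------------------------------------------------------------------------
# fragmentation into contigs
# ---------------------------------------------------------------------------

def fragment_to_contigs(
    genome: CircularGenome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: TruthSet | None = None,
    collapse_repeat: RepeatPair | None = None,
):
    """Tile the circle into contigs with scaffold links, depths and decoys.

    Returns ``(contigs, links, depths, truth)`` where ``contigs`` is a list
    of ``(contig_id, sequence)``, ``links`` records oriented end-to-end
    adjacencies ``(a, end_a, b, end_b, support)`` and ``depths`` maps
    contig ids to mean read depth. Mitochondrial depths are drawn uniformly
    over a three-fold range around ``depth_mean``; a ``nuclear_copy_fraction``
    of contigs is re-emitted under decoy ids at depths below
    ``nuclear_depth_ratio`` of the mitochondrial level and without links
    (nuclear insertions do not scaffold with organellar contigs).

    With ``collapse_repeat`` the circle is additionally cut exactly at the
    two copy boundaries of that (exact) repeat and both copies are emitted
    as a single contig — an assembly-style repeat collapse that turns the
    contig graph into loops sharing the repeat node. The second copy
    appears in the tiling with "-" orientation for an inverted pair.
    """
    rng = config.rng() if rng is None else rng
    truth = TruthSet() if truth is None else truth
    s = genome.sequence
    n = len(s)

    cuts: set[int] = set()
    repeat_tiles: dict[tuple[int, int], tuple[str, str]] = {}
    if collapse_repeat is not None:
        r = collapse_repeat
        if r.mismatches:
            raise ValueError("repeat collapse requires exact copies")
        a0, b0 = r.start1 - 1, r.start2 - 1
        cuts.update((a0, a0 + r.length, b0, b0 + r.length))
        ori2 = "+" if r.orientation == "direct" else "-"
        repeat_tiles[(a0, a0 + r.length)] = ("repeat01", "+")
        repeat_tiles[(b0, b0 + r.length)] = ("repeat01", ori2)

    n_random = max(2 if not cuts else 1, int(rng.binomial(n, config.contig_break_rate)))
    forbidden = set()
    for lo, hi in repeat_tiles:
        forbidden.update(range(lo, hi))
    attempts = 0
    while len(cuts) < n_random + 4 * bool(repeat_tiles) and attempts < 10_000:
        attempts += 1
        c = int(rng.integers(0, n))
        if c not in forbidden:
            cuts.add(c)
    order = sorted(cuts)
    if len(order) < 2:
        order = sorted({0, n // 2})

    tiles: list[tuple[str, str, str, tuple[int, int]]] = []  # id, seq, orientation, span
    counter = 0
    for i, start in enumerate(order):
        end = order[(i + 1) % len(order)]
        span = (start, end if end > start else end + n)
        piece = s[start:end] if end > start else s[start:] + s[:end]
        key = (start, end)
        if key in repeat_tiles:
            cid, ori = repeat_tiles[key]
            if ori == "-":
                piece = revcomp(piece)
        else:
            counter += 1
            cid, ori = f"ctg{counter:03d}", "+"
        tiles.append((cid, piece, ori, span))

    contigs: dict[str, str] = {}
    for cid, piece, ori, span in tiles:
        if cid not in contigs:
            contigs[cid] = piece
            truth.contig_origins[cid] = ((span[0] + 1, span[1], ori), "mito")

    links = []
    seen_links: dict[tuple, int] = {}
    for i in range(len(tiles)):
        a_id, _, a_ori, _ = tiles[i]
        b_id, _, b_ori, _ = tiles[(i + 1) % len(tiles)]
        end_a = "3'" if a_ori == "+" else "5'"
        end_b = "5'" if b_ori == "+" else "3'"
        support = int(rng.poisson(20)) + 1
        seen_links[(a_id, end_a, b_id, end_b)] = (
            seen_links.get((a_id, end_a, b_id, end_b), 0) + support
        )
    links = [(a, ea, b, eb, sup) for (a, ea, b, eb), sup in seen_links.items()]

    depths = {
        cid: float(config.depth_mean * rng.uniform(0.6, 1.8)) for cid in contigs
    }

    # nuclear-copy decoys: same sequence, new id, low depth, no links
    ids = list(contigs)
    n_decoys = int(round(config.nuclear_copy_fraction * len(ids)))
    if config.nuclear_copy_fraction > 0:
        n_decoys = max(1, n_decoys)
    decoy_src = list(rng.choice(ids, size=min(n_decoys, len(ids)), replace=False))
    out_contigs = [(cid, contigs[cid]) for cid in contigs]
    for k, src in enumerate(decoy_src):
        did = f"numt{k + 1:02d}"
        out_contigs.append((did, contigs[src]))
        depths[did] = float(
            config.depth_mean * config.nuclear_depth_ratio * rng.uniform(0.2, 0.6)
        )
        origin = truth.contig_origins[src][0]
        truth.contig_origins[did] = (origin, "nuclear_copy")

    return out_contigs, links, depths, truth


# ---------------------------------------------------------------------------
# pileup simulation (RNA editing evidence)
# ---------------------------------------------------------------------------

def _empty_pileup(genome: CircularGenome) -> pd.DataFrame:
    seq = genome.sequence
    return pd.DataFrame({
        "position": np.arange(1, len(seq) + 1),
        "ref": list(seq),
        "A": 0, "C": 0, "G": 0, "T": 0,
    })


def _fill_counts(df: pd.DataFrame, depth: np.ndarray, error: float,
                 rng: np.random.Generator) -> None:
    refs = df["ref"].to_numpy()
    for base in "ACGT":
        col = np.where(refs == base, depth, 0)
        df[base] = col
    if error > 0:
        for base in "ACGT":
            n_err = rng.binomial(df[base].to_numpy(), error)
            df[base] -= n_err
            others = [b for b in "ACGT" if b != base]
            split = rng.multinomial(1, [1 / 3] * 3, size=len(df)) * n_err[:, None]
            for j, ob in enumerate(others):
                df[ob] += split[:, j]


def simulate_pileups(
    genome: CircularGenome,
    annotations: list[GeneAnnotation],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: TruthSet | None = None,
):
    """Simulate genomic and per-sample RNA pileups with planted C->U sites.

    Editing sites are placed on positions whose gene-orientation base is C
    (genomic C inside plus-strand genes, genomic G inside minus-strand
    genes). In the RNA pileups the edited fraction of reads carries T (A on
    the forward strand for minus-strand genes) with a Binomial draw around
    ``editing_fraction``; all other positions follow the genome, plus an
    optional uniform error rate. ``differential_omissions`` leaves a chosen
    number of sites unedited in specific samples, emulating sample-specific
    loss of editing.
    """
    rng = config.rng() if rng is None else rng
    truth = TruthSet() if truth is None else truth
    s = genome.sequence
    n = len(s)

    candidates: list[tuple[int, GeneAnnotation]] = []
    for gene in annotations:
        want = "C" if gene.strand == "+" else "G"
        for pos in range(gene.start, gene.end + 1):
            if s[pos - 1] == want:
                candidates.append((pos, gene))
    if config.editing_sites > len(candidates):
        raise ValueError(
            f"requested {config.editing_sites} editing sites but only "
            f"{len(candidates)} genic C positions are available"
        )
    pick = rng.choice(len(candidates), size=config.editing_sites, replace=False)
    sites = [candidates[int(i)] for i in sorted(pick)]

    samples = config.sample_ids
    edited_in: dict[int, set[str]] = {pos: set(samples) for pos, _ in sites}
    for sample, k in config.differential_omissions.items():
        if sample not in samples:
            raise ValueError(f"unknown sample in differential_omissions: {sample}")
        omit = rng.choice(len(sites), size=min(k, len(sites)), replace=False)
        for i in omit:
            edited_in[sites[int(i)][0]].discard(sample)

    for pos, gene in sites:
        offset = (pos - gene.start) if gene.strand == "+" else (gene.end - pos)
        codon_index = offset // 3
        codon_pos = offset % 3 + 1
        cds = gene.cds(genome)
        codon = cds[3 * codon_index : 3 * codon_index + 3]
        edited_codon = codon[: codon_pos - 1] + "T" + codon[codon_pos:]
        truth.planted_editing.append({
            "position": pos,
            "gene_id": gene.gene_id,
            "codon_index": codon_index,
            "codon_pos": codon_pos,
            "ref_aa": translate(codon),
            "edited_aa": translate(edited_codon),
            "samples": edited_in[pos],
        })

    gdna = _empty_pileup(genome)
    depth = rng.poisson(config.depth_mean, size=n).astype(int)
    np.maximum(depth, 1, out=depth)
    _fill_counts(gdna, depth, config.pileup_error_rate, rng)

    rna: dict[str, pd.DataFrame] = {}
    for sample in samples:
        df = _empty_pileup(genome)
        depth = rng.poisson(config.depth_mean, size=n).astype(int)
        np.maximum(depth, 1, out=depth)
        _fill_counts(df, depth, config.pileup_error_rate, rng)
        for pos, gene in sites:
            if sample not in edited_in[pos]:
                continue
            i = pos - 1
            d = int(depth[i])
            k = int(rng.binomial(d, config.editing_fraction))
            if config.editing_fraction >= 1.0:
                k = d
            ref_base = s[i]
            edited_base = "T" if gene.strand == "+" else "A"
            df.loc[i, ref_base] = max(0, int(df.loc[i, ref_base]) - k)
            df.loc[i, edited_base] = int(df.loc[i, edited_base]) + k
        rna[sample] = df
    return gdna, rna, truth


# ---------------------------------------------------------------------------
# gene-tail fusion scenario (CMS-style chimeric ORF)
# ---------------------------------------------------------------------------

def plant_gene_tail_fusion(
    rng: np.random.Generator | None = None,
    genome_length: int = 8_000,
    repeat_codons: int = 10,
    tail_codons: int = 23,
    head_codons: int = 17,
    body_codons: int = 40,
    seed: int | None = None,
) -> tuple[CircularGenome, TruthSet]:
    """Build a genome where recombination creates a chimeric gene-tail ORF.

    Plants an inverted repeat whose first copy sits in frame behind a novel
    ATG + head, and arranges the inverted segment so that, after crossover,
    the sequence continues in frame with the carboxyl-terminal tail (and
    stop) of an intact planted gene elsewhere on the circle. The fused ORF
    therefore encodes ``1 + head + repeat + tail`` amino acids of which the
    last ``repeat + tail`` are identical to the gene's carboxyl terminus —
    the classic CMS fusion-transcript signature. The repeat itself is kept
    below the fusion-caller reporting threshold so only the in-frame
    junction yields a call.

    Returns the *pre-recombination* genome and a truth set whose
    ``planted_repeats[0]`` is the recombining pair and whose
    ``planted_fusion`` records the gene, the expected identical tail length
    (in aa) and the junction position (valid on the recombination product).
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    L = 3 * repeat_codons

    unit = "".join(
        _NON_STOP_CODONS[int(i)] for i in rng.integers(0, len(_NON_STOP_CODONS), size=repeat_codons)
    )
    tail = "".join(
        _NON_STOP_CODONS[int(i)] for i in rng.integers(0, len(_NON_STOP_CODONS), size=tail_codons)
    )
    stop = "TAA"
    head = "".join(
        _NON_STOP_CODONS[int(i)] for i in rng.integers(0, len(_NON_STOP_CODONS), size=head_codons)
    )
    body = "".join(
        _NON_STOP_CODONS[int(i)] for i in rng.integers(0, len(_NON_STOP_CODONS), size=body_codons)
    )
    # make head and body disagree at both ends so the identical block is
    # exactly the repeat + tail
    while translate(head[:3]) == translate(body[:3]) or translate(head[-3:]) == translate(body[-3:]):
        head = "".join(
            _NON_STOP_CODONS[int(i)]
            for i in rng.integers(0, len(_NON_STOP_CODONS), size=head_codons)
        )

    seg_u = _random_sequence(800, rng).tobytes().decode()
    seg_z = _random_sequence(1500, rng).tobytes().decode()
    seg_w = _random_sequence(800, rng).tobytes().decode()
    pad = _random_sequence(
        max(0, genome_length - len(seg_u) - len(seg_z) - len(seg_w)
            - 2 * L - len("ATG" + head) - len(tail) - 3 - (3 * (2 + body_codons + repeat_codons + tail_codons))),
        rng,
    ).tobytes().decode()

    gene_cds = "ATG" + body + unit + tail + stop

    # pre-recombination layout:  u ATG head [R] z rc(tail stop) [rc(R)] w gene pad
    prefix = seg_u + "ATG" + head
    v = seg_z + revcomp(tail + stop)
    seq = prefix + unit + v + revcomp(unit) + seg_w + gene_cds + pad

    a0 = len(prefix)                      # 0-based start of repeat copy 1
    b0 = len(prefix) + L + len(v)         # 0-based start of repeat copy 2
    gene_start0 = b0 + L + len(seg_w)

    truth = TruthSet()
    truth.planted_repeats.append(
        RepeatPair(start1=a0 + 1, start2=b0 + 1, length=L, orientation="inverted")
    )
    truth.genes.append(GeneAnnotation(
        gene_id="atp_like1", start=gene_start0 + 1,
        end=gene_start0 + len(gene_cds), strand="+", type="gene",
    ))
    truth.planted_fusion = {
        "gene_id": "atp_like1",
        "retained_tail_aa": repeat_codons + tail_codons,
        "fused_orf_aa": 1 + head_codons + repeat_codons + tail_codons,
        "junction": a0 + L,  # 1-based position of the last repeat base
    }
    genome = CircularGenome(id="sim_fusion", sequence=seq)
    return genome, truth


# ---------------------------------------------------------------------------
# one-stop pipeline
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> dict:
    """Run the full generator off a single RNG stream in a fixed order.

    Order: master circle -> recombination (first planted repeat, up to
    ``n_recombinations``) -> fragmentation of the master circle ->
    pileups on the master circle. Returns a dict with all artifacts.
    """
    rng = config.rng()
    genome, truth = generate_master_circle(config, rng)
    products = []
    for repeat in truth.planted_repeats[: config.n_recombinations]:
        result = apply_recombination(genome, repeat, truth)
        products.append(result)
    contigs, links, depths, truth = fragment_to_contigs(genome, config, rng, truth)
    gdna, rna, truth = simulate_pileups(genome, truth.genes, config, rng, truth)
    return {
        "genome": genome,
        "truth": truth,
        "recombinants": products,
        "contigs": contigs,
        "links": links,
        "depths": depths,
        "genomic_pileup": gdna,
        "rna_pileups": rna,
    }
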