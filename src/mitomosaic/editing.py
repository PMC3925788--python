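"""C->U RNA-editing site calling from paired genomic/RNA pileups.

Plant mitochondrial transcripts are post-transcriptionally edited, almost
exclusively cytidine to uridine. An editing site shows as a position whose
genomic consensus is C while a substantial fraction of RNA reads carry T;
on the forward strand of a minus-strand gene the same event appears as
genomic G with RNA A. Only this class (and its strand mirror) is called as
editing — every other mismatch class is tallied separately as diagnostics,
never called.

Thresholds (minimum depths, genomic purity, edit fraction) are deliberate,
documented choices exposed on every entry point rather than inherited from
any particular variant caller.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from .core import CircularGenome, GeneAnnotation, translate

PILEUP_COLUMNS = ["position", "ref", "A", "C", "G", "T"]


@dataclass
class EditingSite:
    """One genomic-C / RNA-U position with per-sample support."""

    position: int
    strand: str  # strand of the (putative) transcript: + => C->T, - => G->A
    edit_fraction_per_sample: dict[str, float] = field(default_factory=dict)
    gene_id: str | None = None
    codon_index: int | None = None
    codon_pos: int | None = None  # 1..3 within the codon, gene orientation
    ref_aa: str | None = None
    edited_aa: str | None = None
    creates_stop: bool = False


@dataclass
class EditingSummary:
    n_sites: int
    n_nonsynonymous: int
    tally: dict[tuple[str, str], int]
    n_stop_created: int


def _strand_of_position(pos: int, genes: list[GeneAnnotation]) -> str:
    for g in genes:
        if g.start <= pos <= g.end:
            return g.strand
    return "+"


def _validate_pileup(df: pd.DataFrame, n: int | None, label: str) -> None:
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{label} pileup missing columns {missing}")
    if n is not None and len(df) != n:
        raise ValueError(
            f"{label} pileup has {len(df)} rows; expected {n} (genome length mismatch)"
        )


def call_editing_sites(
    genomic: pd.DataFrame,
    rna_by_sample: dict[str, pd.DataFrame],
    min_genomic_depth: int = 10,
    min_rna_depth: int = 10,
    min_genomic_c_purity: float = 0.9,
    min_edit_fraction: float = 0.1,
    genes: list[GeneAnnotation] | None = None,
    genome_length: int | None = None,
) -> list[EditingSite]:
    """Call C->U editing sites from a genomic pileup and per-sample RNA pileups.

    A site is emitted iff the genomic consensus is C (count fraction >=
    ``min_genomic_c_purity`` at depth >= ``min_genomic_depth``) on the
    transcript strand — genomic G with RNA A inside an annotated
    minus-strand gene is the same event seen from the forward strand — and
    the RNA T (resp. A) fraction reaches ``min_edit_fraction`` in at least
    one sample with depth >= ``min_rna_depth``. Per-sample edit fractions
    are recorded for *all* samples regardless of which passed.
    """
    _validate_pileup(genomic, genome_length, "genomic")
    for name, df in rna_by_sample.items():
        _validate_pileup(df, len(genomic), f"RNA[{name}]")
    genes = genes or []

    g_counts = genomic[["A", "C", "G", "T"]].to_numpy()
    g_depth = g_counts.sum(axis=1)
    positions = genomic["position"].to_numpy()
    rna_counts = {s: df[["A", "C", "G", "T"]].to_numpy() for s, df in rna_by_sample.items()}
    col = {b: i for i, b in enumerate("ACGT")}

    sites: list[EditingSite] = []
    for i, pos in enumerate(positions):
        strand = _strand_of_position(int(pos), genes)
        ref_base, edited_base = ("C", "T") if strand == "+" else ("G", "A")
        depth = g_depth[i]
        if depth < min_genomic_depth:
            continue
        if g_counts[i, col[ref_base]] / depth < min_genomic_c_purity:
            continue
        fractions: dict[str, float] = {}
        passed = False
        for sample, counts in rna_counts.items():
            d = counts[i].sum()
            frac = counts[i, col[edited_base]] / d if d > 0 else 0.0
            fractions[sample] = float(frac)
            if d >= min_rna_depth and frac >= min_edit_fraction:
                passed = True
        if passed:
            sites.append(EditingSite(position=int(pos), strand=strand,
                                     edit_fraction_per_sample=fractions))
    return sites


def mismatch_class_counts(
    genomic: pd.DataFrame, rna_by_sample: dict[str, pd.DataFrame],
    min_fraction: float = 0.1, min_depth: int = 10,
) -> Counter:
    """Diagnostic tally of all RNA/genomic mismatch classes (e.g. 'C>T').

    Counts positions (per class, pooled over samples) where a non-reference
    RNA base reaches ``min_fraction``; used to sanity-check that the C->T /
    G>A classes dominate, as true editing predicts.
    """
    refs = genomic["ref"].to_numpy()
    tally: Counter = Counter()
    for counts in (df[["A", "C", "G", "T"]].to_numpy() for df in rna_by_sample.values()):
        depths = counts.sum(axis=1)
        for i, ref in enumerate(refs):
            if depths[i] < min_depth:
                continue
            for j, base in enumerate("ACGT"):
                if base != ref and counts[i, j] / depths[i] >= min_fraction:
                    tally[f"{ref}>{base}"] += 1
    return tally


def annotate_consequence(
    site: EditingSite, genes: list[GeneAnnotation], genome: CircularGenome
) -> EditingSite:
    """Locate the site's codon and compute the amino-acid consequence.

    The codon is read in gene orientation; the edited amino acid results
    from replacing the edited position with T (the transcript's U) and
    translating with the standard code. Sites outside any annotated gene
    are returned unchanged. A gene whose span is not divisible into codons
    raises.
    """
    gene = next((g for g in genes if g.start <= site.position <= g.end), None)
    if gene is None:
        return site
    if len(gene) % 3:
        raise ValueError(f"{gene.gene_id}: length {len(gene)} not divisible into codons")
    offset = (site.position - gene.start) if gene.strand == "+" else (gene.end - site.position)
    codon_index = offset // 3
    codon_pos = offset % 3 + 1
    cds = gene.cds(genome)
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    edited_codon = codon[: codon_pos - 1] + "T" + codon[codon_pos:]
    ref_aa = translate(codon)
    edited_aa = translate(edited_codon)
    return replace(
        site, gene_id=gene.gene_id, codon_index=codon_index, codon_pos=codon_pos,
        ref_aa=ref_aa, edited_aa=edited_aa, creates_stop=(edited_aa == "*"),
    )


def summarize_editing(sites: list[EditingSite]) -> EditingSummary:
    """Tally annotated sites by (reference aa -> edited aa) class."""
    tally: dict[tuple[str, str], int] = {}
    n_nonsyn = 0
    n_stop = 0
    n_annotated = 0
    for s in sites:
        if s.ref_aa is None or s.edited_aa is None:
            continue
        n_annotated += 1
        tally[(s.ref_aa, s.edited_aa)] = tally.get((s.ref_aa, s.edited_aa), 0) + 1
        if s.ref_aa != s.edited_aa:
            n_nonsyn += 1
        if s.creates_stop:
            n_stop += 1
    return EditingSummary(n_sites=n_annotated, n_nonsynonymous=n_nonsyn,
                          tally=tally, n_stop_created=n_stop)


def differential_editing(
    sites: list[EditingSite],
    samples: list[str],
    focal_sample: str,
    threshold: float = 0.1,
) -> list[EditingSite]:
    """Sites edited in every sample except the focal one.

    The interesting pattern for a sterile cytotype: a site whose edit
    fraction reaches ``threshold`` in all non-focal samples but stays below
    it in the focal sample.
    """
    if focal_sample not in samples:
        raise ValueError(f"focal sample {focal_sample!r} not among samples {samples}")
    if len(samples) < 2:
        raise ValueError("differential comparison needs at least two samples")
    out = []
    for s in sites:
        fr = s.edit_fraction_per_sample
        others_ok = all(fr.get(smp, 0.0) >= threshold
                        for smp in samples if smp != focal_sample)
        if others_ok and fr.get(focal_sample, 0.0) < threshold:
            out.append(s)
    return out


def sites_to_frame(sites: list[EditingSite], samples: list[str]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "position": s.position, "strand": s.strand, "gene_id": s.gene_id or "",
            "codon_index": s.codon_index, "codon_pos": s.codon_pos,
            "ref_aa": s.ref_aa or "", "edited_aa": s.edited_aa or "",
            "creates_stop": s.creates_stop,
        }
        for smp in samples:
            row[f"frac_{smp}"] = s.edit_fraction_per_sample.get(smp, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
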