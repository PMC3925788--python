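"""Split-alignment rearrangement detection and breakpoint annotation.

A query contig that aligns to a reference master circle as several segments
that cannot be chained colinearly ("disjointed" BLAST hits) is diagnostic of
a structural rearrangement. After homologous recombination each junction
carries a full copy of the recombining repeat, visible as an *overlap*
between the query intervals of the two flanking segments — the breakpoint
repeat footprint. Breakpoints near genes are the candidates of interest for
cytoplasmic male sterility, so each one is annotated with the nearest gene
and strand-aware distances to its start and stop codons.

Input is either the 7-column BLAST-style tabular dialect
(query id, % identity, alignment length, q.start, q.end, s.start, s.end
[, e-value]; minus-strand hits have s.start > s.end) or a FASTA pair run
through the built-in exact seed-and-extend aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .core import CircularGenome, GeneAnnotation, revcomp

logger = logging.getLogger(__name__)

#: query-adjacent same-strand segments further apart than this on the
#: subject are called rearranged (matches the gene-proximity window)
DEFAULT_MAX_COLINEAR_GAP = 1000
#: alignment segments shorter than this are ignored for classification
DEFAULT_MIN_SEGMENT = 50
#: breakpoints closer than this on the subject are the same event
DEFAULT_MERGE_RADIUS = 50


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment segment (a BLAST HSP)."""

    query_id: str
    pct_identity: float
    align_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"{self.query_id}: q_start > q_end")
        if self.align_length < 1:
            raise ValueError(f"{self.query_id}: align_length < 1")
        if not 0 < self.pct_identity <= 100:
            raise ValueError(f"{self.query_id}: pct_identity out of (0, 100]")

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def s_low(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def s_high(self) -> int:
        return max(self.s_start, self.s_end)


@dataclass
class Breakpoint:
    """Junction between two query-adjacent, non-colinear segments."""

    left_segment: AlignmentRecord
    right_segment: AlignmentRecord
    footprint_length: int
    insertion_length: int
    subject_positions: tuple[int, int]
    nearest_gene: tuple[str, int, int] | None = None  # (gene_id, d_start, d_end)


@dataclass
class RearrangementCall:
    """Per-query chained classification with breakpoints."""

    query_id: str
    segments: list[AlignmentRecord]
    classification: str  # "colinear" | "rearranged" | "unaligned"
    breakpoints: list[Breakpoint] = field(default_factory=list)


# ---------------------------------------------------------------------------
# tabular input
# ---------------------------------------------------------------------------

COLUMNS = ["query_id", "pct_identity", "align_length",
           "q_start", "q_end", "s_start", "s_end", "evalue"]


def read_tabular_alignments(path) -> list[AlignmentRecord]:
    """Read the 7-column alignment dialect (e-value optional, 8th column).

    Minus-strand hits are inferred from s_start > s_end. Malformed rows
    raise with their line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    records = []
    for i, row in df.iterrows():
        try:
            records.append(AlignmentRecord(
                query_id=str(row.query_id),
                pct_identity=float(row.pct_identity),
                align_length=int(row.align_length),
                q_start=int(row.q_start),
                q_end=int(row.q_end),
                s_start=int(row.s_start),
                s_end=int(row.s_end),
                evalue=None if pd.isna(row.evalue) else float(row.evalue),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed alignment row at line {i + 1}: {exc}") from exc
    return records


def write_tabular_alignments(records: list[AlignmentRecord], path) -> None:
    rows = [(r.query_id, r.pct_identity, r.align_length, r.q_start, r.q_end,
             r.s_start, r.s_end, "" if r.evalue is None else r.evalue)
            for r in records]
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# internal exact seed-and-extend aligner
# ---------------------------------------------------------------------------

def seed_extend_align(
    query: str,
    subject: CircularGenome,
    min_seed: int = 20,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    query_id: str = "query",
) -> list[AlignmentRecord]:
    """Maximal exact ungapped local matches of query against both strands.

    Exact k-mer seeds anchor maximal extension; overlapping seeds on the
    same diagonal merge into one maximal segment. The circular subject is
    honoured by indexing across the origin; subject end coordinates may
    exceed the subject length for origin-crossing segments. Intended for
    synthetic analyses where the rearranged molecule derives from the
    reference by recombination; externally produced tabular alignments are
    the first-class input for real data.
    """
    s = subject.sequence
    n = len(s)
    k = min_seed
    if len(query) < k or n < k:
        return []
    ext = s + s[: k - 1] if subject.is_circular else s
    index: dict[str, list[int]] = {}
    for p in range(n if subject.is_circular else n - k + 1):
        index.setdefault(ext[p : p + k], []).append(p)

    segments: set[tuple[int, int, int, str]] = set()  # (q0, s0, length, strand)
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        m = len(q)
        claimed: set[tuple[int, int]] = set()  # (q_pos, diag) already inside a segment
        for qp in range(m - k + 1):
            for sp in index.get(q[qp : qp + k], ()):
                diag = (sp - qp) % n if subject.is_circular else sp - qp
                if (qp, diag) in claimed:
                    continue
                lo = 0
                while True:
                    qi, si = qp - lo - 1, sp - lo - 1
                    if qi < 0:
                        break
                    if subject.is_circular:
                        si %= n
                    elif si < 0:
                        break
                    if q[qi] != s[si]:
                        break
                    lo += 1
                    if lo + k >= n:
                        break
                hi = 0
                while True:
                    qi, si = qp + k + hi, sp + k + hi
                    if qi >= m:
                        break
                    if subject.is_circular:
                        si %= n
                    elif si >= n:
                        break
                    if q[qi] != s[si]:
                        break
                    hi += 1
                    if lo + k + hi >= n:
                        break
                q0 = qp - lo
                s0 = sp - lo
                length = lo + k + hi
                for t in range(length - k + 1):
                    claimed.add((q0 + t, diag))
                s0n = s0 % n if subject.is_circular else s0
                segments.add((q0, s0n, length, strand))

    records = []
    for q0, s0, length, strand in sorted(segments):
        if length < min_segment:
            continue
        if strand == "+":
            q_start, q_end = q0 + 1, q0 + length
            s_start, s_end = s0 + 1, s0 + length
        else:
            # q0 indexes the reverse-complemented query; map back
            q_end = len(query) - q0
            q_start = q_end - length + 1
            s_start, s_end = s0 + length, s0 + 1
        records.append(AlignmentRecord(
            query_id=query_id, pct_identity=100.0, align_length=length,
            q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        ))
    records.sort(key=lambda r: (r.q_start, r.q_end, r.s_low))
    return records


# ---------------------------------------------------------------------------
# chaining and classification
# ---------------------------------------------------------------------------

def breakpoint_footprint(seg1: AlignmentRecord, seg2: AlignmentRecord) -> tuple[int, int]:
    """Query-interval overlap (repeat footprint) and gap (insertion).

    ``footprint = max(0, min(q_end) - max(q_start) + 1)``;
    ``insertion = max(0, max(q_start) - min(q_end) - 1)``. Exactly one of
    the two can be positive; abutting segments give (0, 0). Symmetric in
    its arguments.
    """
    if seg1.query_id != seg2.query_id:
        raise ValueError("footprint is defined between segments of one query")
    footprint = max(0, min(seg1.q_end, seg2.q_end) - max(seg1.q_start, seg2.q_start) + 1)
    insertion = max(0, max(seg1.q_start, seg2.q_start) - min(seg1.q_end, seg2.q_end) - 1)
    return footprint, insertion


def _pair_colinear(a: AlignmentRecord, b: AlignmentRecord, max_gap: int) -> bool:
    """Is the query-adjacent pair (a, b) consistent with a colinear layout?"""
    if a.strand != b.strand:
        return False
    if a.strand == "+":
        if b.s_start < a.s_start:
            return False  # subject order inverted
        gap = b.s_start - a.s_end
    else:
        if b.s_start > a.s_start:
            return False  # subject must descend along the query on minus
        gap = a.s_end - b.s_start
    return gap <= max_gap


def chain_and_classify(
    records: list[AlignmentRecord],
    max_colinear_gap: int = DEFAULT_MAX_COLINEAR_GAP,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> RearrangementCall:
    """Chain one query's segments along the query and classify the layout.

    Segments (>= ``min_segment``; shorter ones are logged and ignored) are
    sorted by q_start. The call is *colinear* iff every query-adjacent pair
    is same-strand, subject-order consistent with the query order, and at
    most ``max_colinear_gap`` apart on the subject; otherwise *rearranged*,
    with one :class:`Breakpoint` per offending pair. No usable segment
    gives *unaligned*.
    """
    if records:
        qids = {r.query_id for r in records}
        if len(qids) > 1:
            raise ValueError(f"records span multiple queries: {sorted(qids)}")
    usable = []
    for r in records:
        if r.align_length < min_segment:
            logger.info("%s: dropping %d bp segment below %d bp minimum",
                        r.query_id, r.align_length, min_segment)
            continue
        usable.append(r)
    # a segment whose query interval lies inside another's is a secondary
    # hit (typically the other copy of a repeat the query spans) and would
    # fake a rearrangement on a perfectly colinear query
    contained = set()
    for i, r in enumerate(usable):
        for j, other in enumerate(usable):
            if i == j or j in contained:
                continue
            if (other.q_start <= r.q_start and r.q_end <= other.q_end
                    and (other.q_end - other.q_start) > (r.q_end - r.q_start)):
                contained.add(i)
                logger.info("%s: dropping segment [%d,%d] contained in [%d,%d]",
                            r.query_id, r.q_start, r.q_end,
                            other.q_start, other.q_end)
                break
    usable = [r for i, r in enumerate(usable) if i not in contained]
    if not usable:
        qid = records[0].query_id if records else ""
        return RearrangementCall(query_id=qid, segments=[], classification="unaligned")
    usable.sort(key=lambda r: (r.q_start, r.q_end))
    qid = usable[0].query_id
    breakpoints = []
    for a, b in zip(usable, usable[1:]):
        if _pair_colinear(a, b, max_colinear_gap):
            continue
        fp, ins = breakpoint_footprint(a, b)
        breakpoints.append(Breakpoint(
            left_segment=a, right_segment=b,
            footprint_length=fp, insertion_length=ins,
            subject_positions=(a.s_end, b.s_start),
        ))
    classification = "rearranged" if breakpoints else "colinear"
    return RearrangementCall(query_id=qid, segments=usable,
                             classification=classification, breakpoints=breakpoints)


def classify_all(
    records: list[AlignmentRecord], **kwargs
) -> dict[str, RearrangementCall]:
    """Group records by query id and classify each query."""
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_query.setdefault(r.query_id, []).append(r)
    return {qid: chain_and_classify(recs, **kwargs) for qid, recs in by_query.items()}


# ---------------------------------------------------------------------------
# gene proximity
# ---------------------------------------------------------------------------

def _codon_distances(p: int, gene: GeneAnnotation) -> tuple[int, int]:
    """Strand-aware distances from position p to the start and stop codons.

    Measured along the gene's own orientation: ``d_start`` is positive when
    p lies upstream of the start codon, ``d_end`` is positive when p lies
    before (upstream of) the gene's end.
    """
    if gene.strand == "+":
        return gene.start - p, gene.end - p
    return p - gene.end, p - gene.start


def _gene_distance(p: int, gene: GeneAnnotation) -> int:
    if gene.start <= p <= gene.end:
        return 0
    return min(abs(p - gene.start), abs(p - gene.end))


def annotate_breakpoints(
    call: RearrangementCall,
    genes: list[GeneAnnotation],
    window: int = 1000,
) -> RearrangementCall:
    """Attach the nearest gene within ``window`` bp to each breakpoint.

    Each breakpoint carries two subject coordinates (the junction as seen
    from its left and right segments); the gene minimising the interval
    distance over both is chosen, and the distances reported are taken from
    the subject position closest to that gene. Breakpoints with no gene in
    range stay unannotated.
    """
    new_bps = []
    for bp in call.breakpoints:
        best = None
        for gene in genes:
            for p in bp.subject_positions:
                d = _gene_distance(p, gene)
                if d <= window and (best is None or d < best[0]):
                    best = (d, gene, p)
        if best is None:
            new_bps.append(bp)
        else:
            _, gene, p = best
            d_start, d_end = _codon_distances(p, gene)
            new_bps.append(replace(bp, nearest_gene=(gene.gene_id, d_start, d_end)))
    return replace(call, breakpoints=new_bps)


# ---------------------------------------------------------------------------
# cross-sample presence
# ---------------------------------------------------------------------------

def compare_presence(
    calls_by_sample: dict[str, list[RearrangementCall]],
    merge_radius: int = DEFAULT_MERGE_RADIUS,
) -> pd.DataFrame:
    """Breakpoint x sample presence/absence matrix with uniqueness flags.

    Breakpoints from different samples are the same event when both subject
    coordinates agree within ``merge_radius`` (footprints blur the exact
    junction base). Returns a DataFrame indexed by representative subject
    position pair, one boolean column per sample, plus ``unique_to`` naming
    the sample when an event is present in exactly one.
    """
    catalogue: list[tuple[tuple[int, int], dict[str, bool]]] = []
    for sample, calls in calls_by_sample.items():
        for call in calls:
            for bp in call.breakpoints:
                pos = tuple(sorted(bp.subject_positions))
                for cat_pos, presence in catalogue:
                    if (abs(cat_pos[0] - pos[0]) <= merge_radius
                            and abs(cat_pos[1] - pos[1]) <= merge_radius):
                        presence[sample] = True
                        break
                else:
                    catalogue.append((pos, {sample: True}))
    samples = sorted(calls_by_sample)
    rows = []
    for pos, presence in catalogue:
        flags = {smp: presence.get(smp, False) for smp in samples}
        present = [smp for smp, v in flags.items() if v]
        flags["unique_to"] = present[0] if len(present) == 1 else ""
        rows.append({"subject_pos_1": pos[0], "subject_pos_2": pos[1], **flags})
    return pd.DataFrame(rows, columns=["subject_pos_1", "subject_pos_2", *samples,
                                       "unique_to"])
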