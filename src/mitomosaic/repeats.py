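"""Direct/inverted repeat census on circular genomes.

Plant mitochondrial genomes carry hundreds of dispersed direct and inverted
repeats which mediate homologous recombination between subgenomic molecules.
This module finds all *maximal* repeat occurrence pairs (pairs that cannot
be extended on either side without exceeding a Hamming-mismatch budget) and
bins them into the conventional size-class summary table.

Definitions
-----------
A direct pair (i, j, L) satisfies ``Hamming(S[i..i+L-1], S[j..j+L-1]) <= m``;
an inverted pair satisfies ``Hamming(S[i..i+L-1], revcomp(S[j..j+L-1])) <= m``.
Coordinates are 1-based; on circular genomes occurrences may wrap the origin.
Each unordered occurrence pair is reported once (a three-copy repeat yields
three pairs). "% genome" in the summary counts each pair's length once.

Two search strategies share these definitions: an exhaustive per-diagonal
scan (quadratic, default up to 10 kb) and an exact k-mer seed-and-extend
search for larger genomes; the seed length is chosen by pigeonhole so no
maximal pair above ``min_length`` can be missed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CircularGenome, RepeatPair

logger = logging.getLogger(__name__)

_COMP_TABLE = str.maketrans("ACGT", "TGCA")

#: genomes at or below this size use the exhaustive diagonal scan; above it
#: the k-mer-anchored search (equivalent output, near-linear cost) takes over
BRUTE_FORCE_MAX = 2_000

DEFAULT_BIN_EDGES: tuple[tuple[int, int | None], ...] = (
    (20, 40),
    (41, 60),
    (61, 80),
    (81, 100),
    (101, 200),
    (201, None),
)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _complement_array(arr: np.ndarray) -> np.ndarray:
    table = np.arange(256, dtype=np.uint8)
    for a, b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
        table[ord(a)] = ord(b)
    return table[arr]


# ---------------------------------------------------------------------------
# maximal low-mismatch window enumeration on a binary mismatch mask
# ---------------------------------------------------------------------------

def _maximal_windows_circular(mism_pos: np.ndarray, n: int, m: int):
    """Maximal windows with <= m mismatches on a circular mask of length n.

    Yields (start0, length, n_mismatches). If the whole circle fits within
    the budget a single full-length window anchored at 0 is yielded.
    """
    t = len(mism_pos)
    if t <= m:
        yield 0, n, t
        return
    M = mism_pos  # sorted by flatnonzero
    for k in range(t):
        lo = int(M[(k - 1) % t])
        hi = int(M[(k + m) % t])
        length = (hi - lo - 1) % n
        if length == 0:
            continue
        yield (lo + 1) % n, length, m


def _maximal_windows_linear(mism_pos: np.ndarray, n: int, m: int):
    """Maximal windows with <= m mismatches on a linear mask of length n."""
    if n <= 0:
        return
    M = [int(x) for x in mism_pos]
    t = len(M)
    bounds = [-1] + M + [n]
    for a in range(t + 1):
        count = min(m, t - a)
        if a > 0 and count < m:
            # extending left past bounds[a] would still fit the budget
            continue
        start = bounds[a] + 1
        right = bounds[min(a + m + 1, t + 1)]
        length = right - start
        if length > 0:
            yield start, length, count


# ---------------------------------------------------------------------------
# exhaustive diagonal scan
# ---------------------------------------------------------------------------

def _scan_direct(arr: np.ndarray, circular: bool, min_len: int, m: int, found: set):
    n = len(arr)
    for d in range(1, n):
        if circular:
            mask = arr != np.roll(arr, -d)
            for start, length, mm in _maximal_windows_circular(np.flatnonzero(mask), n, m):
                if length >= min_len:
                    _add_pair(found, start, start + d, min(length, n), "direct", mm, n)
        else:
            if n - d < min_len:
                break
            mask = arr[: n - d] != arr[d:]
            for start, length, mm in _maximal_windows_linear(np.flatnonzero(mask), n - d, m):
                if length >= min_len:
                    _add_pair(found, start, start + d, length, "direct", mm, n)


def _scan_inverted(arr: np.ndarray, circular: bool, min_len: int, m: int, found: set):
    n = len(arr)
    comp = _complement_array(arr)
    if circular:
        idx = np.arange(n)
        for c in range(n):
            mask = arr != comp[(c - idx) % n]
            for start, length, mm in _maximal_windows_circular(np.flatnonzero(mask), n, m):
                if length < min_len:
                    continue
                i = start
                j = (c - start - length + 1) % n
                if i % n == j:
                    continue  # a single self-palindromic occurrence, not a pair
                _add_pair(found, i, j, min(length, n), "inverted", mm, n)
    else:
        for c in range(2 * n - 1):
            p_lo = max(0, c - n + 1)
            p_hi = min(c, n - 1)
            ps = np.arange(p_lo, p_hi + 1)
            mask = arr[ps] != comp[c - ps]
            for start, length, mm in _maximal_windows_linear(
                np.flatnonzero(mask), p_hi - p_lo + 1, m
            ):
                if length < min_len:
                    continue
                i = p_lo + start
                j = c - (i + length - 1)
                if i == j:
                    continue
                _add_pair(found, i, j, length, "inverted", mm, n)


def _add_pair(found: set, i: int, j: int, length: int, orientation: str, mm: int, n: int):
    a, b = sorted((i % n, j % n))
    if a == b:
        return
    found.add((a + 1, b + 1, length, orientation, mm))


# ---------------------------------------------------------------------------
# seed-and-extend search for large genomes
# ---------------------------------------------------------------------------

def _seed_length(min_len: int, m: int) -> int:
    # pigeonhole: a window of length min_len with m mismatches contains an
    # exact run of at least ceil((min_len - m) / (m + 1))
    guarantee = -(-(min_len - m) // (m + 1))
    return max(4, min(20, guarantee))


def _extend_seed(seq: str, comp: str | None, i0: int, k: int, partner, n: int,
                 circular: bool, m: int):
    """All maximal windows containing the exact seed run [i0, i0+k-1].

    ``partner(i)`` maps an occurrence-1 index to its occurrence-2 index;
    bases are compared against ``comp`` (complemented genome) for inverted
    pairs, against ``seq`` itself for direct pairs. Enumerates every split
    of the mismatch budget between leftward and rightward extension, which
    yields exactly the maximal windows that contain the seed.
    """
    other = comp if comp is not None else seq

    def mism(i: int) -> bool | None:
        j = partner(i)
        if circular:
            return seq[i % n] != other[j % n]
        if 0 <= i < n and 0 <= j < n:
            return seq[i] != other[j]
        return None  # off the end of a linear sequence

    cap = n - k  # max extension steps on either side

    def scan(anchor: int, step: int):
        """Offsets of the first m+1 mismatches outward from the anchor,
        plus the furthest valid step when a boundary is hit first."""
        mm_at: list[int] = []
        furthest = 0
        for s in range(1, cap + 1):
            x = mism(anchor + step * s)
            if x is None:
                break
            furthest = s
            if x:
                mm_at.append(s)
                if len(mm_at) > m:
                    break
        return mm_at, furthest

    left_mm, left_max = scan(i0, -1)
    right_mm, right_max = scan(i0 + k - 1, +1)

    def reach(mm_list, budget, hard_max):
        # furthest extension using <= budget mismatches, and mismatches used
        if budget < len(mm_list):
            return mm_list[budget] - 1, budget
        return hard_max, len(mm_list)

    seen = set()
    for t in range(m + 1):
        lx, lc = reach(left_mm, t, left_max)
        rx, rc_ = reach(right_mm, m - t, right_max)
        length = lx + k + rx
        if circular and length > n:
            length = n
        start = i0 - lx
        key = (start, length)
        if key in seen:
            continue
        seen.add(key)
        yield (start % n if circular else start), length, lc + rc_


def _seed_search(seq: str, circular: bool, min_len: int, m: int, found: set):
    n = len(seq)
    k = _seed_length(min_len, m)
    if n < k:
        return
    comp = seq.translate(_COMP_TABLE)
    ext = seq + seq[: k - 1] if circular else seq
    index: dict[str, list[int]] = {}
    for p in range(n if circular else n - k + 1):
        index.setdefault(ext[p : p + k], []).append(p)

    candidates: set[tuple] = set()

    # direct: exact seed pairs (i, j both reading forward)
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                p1, p2 = positions[ai], positions[bi]
                d = (p2 - p1) % n if circular else p2 - p1
                for start, length, mm in _extend_seed(
                    seq, None, p1, k, lambda i, d=d: i + d, n, circular, m
                ):
                    if length >= min_len:
                        j = (start + d) % n if circular else start + d
                        candidates.add((start % n if circular else start,
                                        j, length, "direct", mm))

    # inverted: genome k-mers matched against reverse-complement k-mers.
    # rc substring at p of length k equals revcomp of the genome window
    # ending at j_end = n-1-p, so occurrence-1 index i pairs with c - i
    # on the antidiagonal c = q + j_end.
    rc = comp[::-1]
    ext_rc = rc + rc[: k - 1] if circular else rc
    for p in range(n if circular else n - k + 1):
        kmer = ext_rc[p : p + k]
        if kmer not in index:
            continue
        j_end = (n - 1 - p) % n
        for q in index[kmer]:
            c = (q + j_end) % n if circular else q + (n - 1 - p)
            j_start0 = (c - q - k + 1) % n if circular else c - q - k + 1
            if not circular and (j_start0 < 0 or c - q >= n):
                continue
            for start, length, mm in _extend_seed(
                seq, comp, q, k, lambda i, c=c: (c - i) % n if circular else c - i,
                n, circular, m
            ):
                if length < min_len:
                    continue
                j0 = (c - start - length + 1) % n if circular else c - start - length + 1
                if (start % n if circular else start) == j0:
                    continue
                candidates.add((start % n if circular else start,
                                j0, length, "inverted", mm))

    for i, j, length, ori, mm in candidates:
        if _is_maximal(seq, comp, i, j, length, ori, mm, m, n, circular):
            _add_pair(found, i, j, length, ori, mm, n)


def _is_maximal(seq: str, comp: str, i: int, j: int, length: int, ori: str,
                mm: int, m: int, n: int, circular: bool) -> bool:
    """True iff neither one-base extension of the window stays within budget."""
    if length >= n:
        return True

    def base_pair(ii: int, jj: int) -> bool | None:
        if circular:
            ii %= n
            jj %= n
        elif not (0 <= ii < n and 0 <= jj < n):
            return None
        if ori == "direct":
            return seq[ii] == seq[jj]
        return seq[ii] == comp[jj]

    if ori == "direct":
        left = base_pair(i - 1, j - 1)
        right = base_pair(i + length, j + length)
    else:
        # occurrence 2 spans [j, j+length-1]; occ1 left pairs with occ2 right
        left = base_pair(i - 1, j + length)
        right = base_pair(i + length, j - 1)
    for ext in (left, right):
        if ext is None:
            continue  # sequence boundary blocks extension
        if ext or mm < m:
            return False  # extension stays within budget
    return True


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def find_maximal_repeats(
    genome: CircularGenome,
    min_length: int = 20,
    max_mismatches: int = 0,
    method: str = "auto",
) -> list[RepeatPair]:
    """Find all maximal direct and inverted repeat pairs.

    Parameters
    ----------
    genome:
        Circular (or linear) genome to scan.
    min_length:
        Minimum repeat length reported, >= 8 (shorter saturates random
        sequence with chance matches).
    max_mismatches:
        Hamming mismatch budget within one occurrence pair.
    method:
        "diagonal" (exhaustive scan), "seed" (k-mer anchored), or "auto"
        (diagonal up to 10 kb, seed beyond).

    Returns
    -------
    list of RepeatPair sorted by (start1, start2, length); each unordered
    occurrence pair reported once.
    """
    if min_length < 8:
        raise ValueError("min_length must be >= 8")
    n = len(genome)
    if n < min_length:
        return []
    seq = genome.sequence
    circular = genome.is_circular
    if method == "auto":
        method = "diagonal" if n <= BRUTE_FORCE_MAX else "seed"

    found: set[tuple] = set()
    if method == "diagonal":
        arr = _encode(seq)
        _scan_direct(arr, circular, min_length, max_mismatches, found)
        _scan_inverted(arr, circular, min_length, max_mismatches, found)
    elif method == "seed":
        _seed_search(seq, circular, min_length, max_mismatches, found)
    else:
        raise ValueError(f"unknown method: {method!r}")

    pairs = [
        RepeatPair(start1=a, start2=b, length=ln, orientation=ori, mismatches=mm)
        for a, b, ln, ori, mm in found
    ]
    pairs.sort(key=lambda p: (p.start1, p.start2, p.length, p.orientation))
    return pairs


@dataclass
class RepeatSummary:
    """Size-binned repeat census with per-orientation counts."""

    bins: list[tuple[str, int, float, int, int]]
    total: tuple[str, int, float, int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.bins) + [self.total]
        return pd.DataFrame(
            rows,
            columns=["Repeat length (bp)", "Number of repeats", "% genome size",
                     "Direct", "Inverted"],
        )


def summarize_repeats(
    pairs: list[RepeatPair],
    genome_length: int,
    bin_edges: tuple[tuple[int, int | None], ...] = DEFAULT_BIN_EDGES,
) -> RepeatSummary:
    """Bin repeat pairs by length into the conventional census table.

    ``% genome size`` counts each pair's length once (not both copies),
    divided by the genome length; alternative conventions can be recomputed
    from the pair list.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    smallest = bin_edges[0][0]
    binned: dict[tuple, list[RepeatPair]] = {edge: [] for edge in bin_edges}
    for p in pairs:
        if p.length < smallest:
            logger.warning("repeat pair (%d,%d) length %d below smallest bin; excluded",
                           p.start1, p.start2, p.length)
            continue
        for lo, hi in bin_edges:
            if p.length >= lo and (hi is None or p.length <= hi):
                binned[(lo, hi)].append(p)
                break
    rows = []
    tot_n = tot_len = tot_d = tot_i = 0
    for lo, hi in bin_edges:
        sel = binned[(lo, hi)]
        label = f">{lo - 1}" if hi is None else f"{lo}-{hi}"
        n_d = sum(1 for p in sel if p.orientation == "direct")
        n_i = sum(1 for p in sel if p.orientation == "inverted")
        blen = sum(p.length for p in sel)
        rows.append((label, len(sel), 100.0 * blen / genome_length, n_d, n_i))
        tot_n += len(sel)
        tot_len += blen
        tot_d += n_d
        tot_i += n_i
    total = ("Total", tot_n, 100.0 * tot_len / genome_length, tot_d, tot_i)
    return RepeatSummary(bins=rows, total=total)
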