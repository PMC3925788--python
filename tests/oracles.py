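"""Independent brute-force oracles used to validate the library.

These deliberately share no search code with the implementation: repeats
are enumerated by exhaustive per-start longest-window arithmetic on
cumulative mismatch sums, and ORFs by a straightforward six-frame codon
scan. They are only feasible at small n, which is all the tests need.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")
STOPS = {"TAA", "TAG", "TGA"}

CODON_TABLE = {}


def _codon_table():
    if CODON_TABLE:
        return CODON_TABLE
    from Bio.Seq import Seq

    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                CODON_TABLE[a + b + c] = str(Seq(a + b + c).translate())
    return CODON_TABLE


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def _windows_on_mask(mask: np.ndarray, n_total: int, m: int, circular: bool):
    """All maximal <=m-mismatch windows on a (possibly circular) mask.

    For every start position the longest admissible window is found on the
    cumulative mismatch sum; a window survives iff it cannot be covered by
    extending the window that starts one base earlier.
    """
    ln = len(mask)
    if ln == 0:
        return
    if circular:
        cs = np.concatenate([[0], np.cumsum(np.tile(mask, 2))])
        starts = np.arange(ln)
        idx = np.searchsorted(cs, cs[starts] + m, side="right") - 1
        L = np.minimum(idx - starts, n_total)
        if (L >= n_total).any():
            yield 0, n_total, int(mask.sum())
            return
        for p in range(ln):
            prev = (p - 1) % ln
            if L[prev] <= L[p] and L[p] > 0:
                mm = int(cs[p + L[p]] - cs[p])
                yield p, int(L[p]), mm
    else:
        cs = np.concatenate([[0], np.cumsum(mask)])
        starts = np.arange(ln)
        idx = np.searchsorted(cs, cs[starts] + m, side="right") - 1
        idx = np.minimum(idx, ln)
        L = idx - starts
        for p in range(ln):
            if L[p] <= 0:
                continue
            if p > 0 and L[p - 1] > L[p]:
                continue  # covered by extending the earlier window
            mm = int(cs[p + L[p]] - cs[p])
            yield p, int(L[p]), mm


def brute_force_repeats(seq: str, circular: bool, min_len: int, max_mm: int) -> set:
    """Set of (start1, start2, length, orientation, mismatches), 1-based."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    carr = np.frombuffer(seq.translate(COMP).encode(), dtype=np.uint8)
    found = set()

    def add(i, j, length, ori, mm):
        a, b = sorted((i % n + 1, j % n + 1))
        if a != b:
            found.add((a, b, length, ori, mm))

    for d in range(1, n):
        if circular:
            mask = arr != np.roll(arr, -d)
            for p, L, mm in _windows_on_mask(mask, n, max_mm, True):
                if L >= min_len:
                    add(p, p + d, L, "direct", mm)
        else:
            if n - d < min_len:
                continue
            mask = arr[: n - d] != arr[d:]
            for p, L, mm in _windows_on_mask(mask, n, max_mm, False):
                if L >= min_len:
                    add(p, p + d, L, "direct", mm)

    if circular:
        idx = np.arange(n)
        for c in range(n):
            mask = arr != carr[(c - idx) % n]
            for p, L, mm in _windows_on_mask(mask, n, max_mm, True):
                if L < min_len:
                    continue
                j = (c - p - L + 1) % n
                if p % n == j:
                    continue
                add(p, j, L, "inverted", mm)
    else:
        for c in range(2 * n - 1):
            p_lo = max(0, c - n + 1)
            p_hi = min(c, n - 1)
            ps = np.arange(p_lo, p_hi + 1)
            mask = arr[ps] != carr[c - ps]
            for p, L, mm in _windows_on_mask(mask, n, max_mm, False):
                if L < min_len:
                    continue
                i = p_lo + p
                j = c - (i + L - 1)
                if i == j:
                    continue
                add(i, j, L, "inverted", mm)
    return found


def six_frame_orfs(seq: str, min_aa: int) -> set:
    """Set of (start, end, strand, peptide) by direct codon walking."""
    table = _codon_table()
    out = set()
    n = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            codons = [s[p : p + 3] for p in range(frame, len(s) - 2, 3)]
            run: list[int] = []  # candidate ATG offsets since last stop
            for ci, codon in enumerate(codons):
                if codon in STOPS:
                    if run:
                        atg = run[0]
                        n_aa = ci - atg
                        if n_aa >= min_aa:
                            pep = "".join(table[c] for c in codons[atg:ci])
                            p0 = frame + 3 * atg
                            p1 = frame + 3 * ci + 2
                            if strand == "+":
                                out.add((p0 + 1, p1 + 1, "+", pep))
                            else:
                                out.add((n - p1, n - p0, "-", pep))
                    run = []
                elif codon == "ATG" and not run:
                    run.append(ci)
    return out
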