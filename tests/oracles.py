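"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or a
naive scan, never by calling the implementation under test.
"""

from __future__ import annotations

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T", "U"}


def brute_mems(read: str, ref: str) -> set[tuple[int, int, int, int]]:
    """All maximal exact matches (read_start, read_end, ref_start, ref_end)
    by exhaustive diagonal walking; N matches nothing."""
    out = set()
    n, m = len(read), len(ref)
    for diag in range(-(n - 1), m):
        i = max(0, -diag)
        while i < n:
            j = i + diag
            if j >= m:
                break
            if read[i] == ref[j] != "N":
                s = i
                while i < n and i + diag < m and read[i] == ref[i + diag] != "N":
                    i += 1
                out.add((s, i, s + diag, i + diag))
            else:
                i += 1
    return out


def _occurrences(needle: str, hay: str) -> list[int]:
    out = []
    start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def two_block_junctions(read: str, ref: str,
                        min_flank: int = 10) -> set[tuple[int, int, str]]:
    """All junctions (donor 1-based, acceptor 1-based, kind) from exact
    two-block decompositions of ``read`` against ``ref``, canonicalised to
    the leftmost placement.  A junction exists when some split point leaves
    >= ``min_flank`` exactly matching nt on each side."""
    out = set()
    n = len(read)
    for s in range(min_flank, n - min_flank + 1):
        ups, downs = read[:s], read[s:]
        for e in _occurrences(ups, ref):
            d0 = e + s - 1                     # donor last base, 0-based
            for f in _occurrences(downs, ref):
                a0 = f                          # acceptor first base
                if a0 == d0 + 1:
                    continue                    # contiguity, not a junction
                t = 0
                while d0 - t >= 0 and a0 - 1 - t >= 0 \
                        and ref[d0 - t] == ref[a0 - 1 - t]:
                    t += 1
                dd, aa = d0 - t, a0 - t
                if aa == dd + 1:
                    continue
                kind = "back" if aa <= dd else "forward"
                out.add((dd + 1, aa + 1, kind))
    return out


def naive_count(keyword: str, reads: list[str], rc: str | None = None) -> int:
    """Sliding-window count of reads containing ``keyword`` (or ``rc``)."""
    n = 0
    for seq in reads:
        hit = False
        for target in filter(None, (keyword, rc)):
            m = len(target)
            for i in range(len(seq) - m + 1):
                if seq[i:i + m] == target:
                    hit = True
                    break
            if hit:
                break
        if hit:
            n += 1
    return n


def hamming_count(keyword: str, reads: list[str], max_mismatches: int,
                  rc: str | None = None) -> int:
    """Reads containing the keyword within a Hamming distance."""
    n = 0
    for seq in reads:
        hit = False
        for target in filter(None, (keyword, rc)):
            m = len(target)
            for i in range(len(seq) - m + 1):
                if sum(a != b for a, b in zip(seq[i:i + m], target)) \
                        <= max_mismatches:
                    hit = True
                    break
            if hit:
                break
        if hit:
            n += 1
    return n


def degenerate_lcs(x: str, y: str, min_len: int = 4,
                   max_degenerate_frac: float = 0.3) -> int:
    """Length of the longest common substring of ``x`` and ``y`` where
    positions may mismatch within the purine or pyrimidine class, capped at
    ``max_degenerate_frac`` degenerate positions; 0 when below ``min_len``.
    Exhaustive over all (i, j, length) triples."""
    best = 0
    for i in range(len(x)):
        for j in range(len(y)):
            length = 0
            ndeg = 0
            k = 0
            while i + k < len(x) and j + k < len(y):
                a, b = x[i + k], y[j + k]
                if a == b and a in "ACGT":
                    pass
                elif a in PURINES and b in PURINES:
                    ndeg += 1
                elif a in PYRIMIDINES and b in PYRIMIDINES:
                    ndeg += 1
                else:
                    break
                k += 1
                # degenerate prefix counts are monotone: check every prefix
                if ndeg <= max_degenerate_frac * k and k >= min_len:
                    length = max(length, k)
            best = max(best, length)
    return best


def longest_a_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """(start, length) of maximal A-runs of length >= min_run, by scan."""
    out = []
    i = 0
    while i < len(seq):
        if seq[i] == "A":
            j = i
            while j < len(seq) and seq[j] == "A":
                j += 1
            if j - i >= min_run:
                out.append((i, j - i))
            i = j
        else:
            i += 1
    return out
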