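"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the most naive correct algorithm available
(per-base marking, exhaustive enumeration, direct summation) and share no
code with the package paths they verify.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom


def interval_union_components(
    intervals: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    """Union of overlapping-or-bookended half-open intervals via pairwise
    connectivity: intervals join iff a.start <= b.end and b.start <= a.end,
    and clusters are the transitive closure (brute-force BFS)."""
    n = len(intervals)
    seen = [False] * n
    out = []
    for i in range(n):
        if seen[i]:
            continue
        stack = [i]
        seen[i] = True
        members = []
        while stack:
            k = stack.pop()
            members.append(intervals[k])
            for j in range(n):
                if not seen[j]:
                    a, b = intervals[k], intervals[j]
                    if a[0] <= b[1] and b[0] <= a[1]:
                        seen[j] = True
                        stack.append(j)
        out.append((min(m[0] for m in members), max(m[1] for m in members)))
    return sorted(out)


def overlap_bp(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def perbase_te_fraction(
    sv: Tuple[int, int], tes: Sequence[Tuple[int, int]]
) -> float:
    """TE-covered fraction of an interval by marking each base."""
    lo, hi = sv
    if hi <= lo:
        return 0.0
    hits = np.zeros(hi - lo, dtype=bool)
    for t0, t1 in tes:
        a, b = max(lo, t0), min(hi, t1)
        if a < b:
            hits[a - lo : b - lo] = True
    return hits.mean()


def perbase_context(
    sv: Tuple[int, int],
    genes: Sequence[Tuple[str, int, int, str, Sequence[Tuple[int, int]]]],
    chrom: str,
    flank: int,
) -> str:
    """Context label by testing every base of the SV against every feature.

    ``genes``: (chrom, start, end, strand, exons).
    """
    lo, hi = sv
    if hi <= lo:
        hi = lo + 1
    bases = range(lo, hi)
    saw = set()
    for gchrom, gs, ge, strand, exons in genes:
        if gchrom != chrom:
            continue
        for b in bases:
            if gs <= b < ge:
                if any(e0 <= b < e1 for e0, e1 in exons):
                    saw.add("exon")
                else:
                    saw.add("intron")
            if strand == "+":
                if gs - flank <= b < gs:
                    saw.add("upstream")
                if ge <= b < ge + flank:
                    saw.add("downstream")
            else:
                if ge <= b < ge + flank:
                    saw.add("upstream")
                if gs - flank <= b < gs:
                    saw.add("downstream")
    for label in ("exon", "intron", "upstream", "downstream"):
        if label in saw:
            return label
    return "intergenic"


def fisher_enumeration(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    k_lo = max(0, col1 - (n - row1))
    k_hi = min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(k_lo, k_hi + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, float(total))


def naive_cpg_islands(seq: str, window: int = 200, min_gc: float = 0.5,
                      min_oe: float = 0.6) -> List[Tuple[int, int]]:
    """Exhaustive window enumeration: test every 200-bp window with plain
    loops, merge overlapping qualifiers, re-check merged spans."""
    s = seq.upper()
    n = len(s)

    def stats(lo: int, hi: int) -> Tuple[float, float]:
        sub = s[lo:hi]
        c = sub.count("C")
        g = sub.count("G")
        cpg = sum(1 for i in range(len(sub) - 1) if sub[i : i + 2] == "CG")
        gc = (c + g) / len(sub)
        oe = cpg * len(sub) / (c * g) if c * g > 0 else 0.0
        return gc, oe

    hits = []
    for i in range(0, n - window + 1):
        gc, oe = stats(i, i + window)
        if gc >= min_gc and oe >= min_oe:
            hits.append(i)
    islands = []
    idx = 0
    while idx < len(hits):
        start = hits[idx]
        end = hits[idx] + window
        while idx + 1 < len(hits) and hits[idx + 1] < end:
            idx += 1
            end = hits[idx] + window
        gc, oe = stats(start, end)
        if gc >= min_gc and oe >= min_oe:
            islands.append((start, end))
        idx += 1
    return islands


def naive_motif_hits(seq: str, consensus: str, iupac: Mapping[str, str]) -> int:
    """All-offset IUPAC matching on both strands without regex."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    s = seq.upper()

    def matches(motif: str) -> int:
        m = motif.upper()
        count = 0
        for off in range(len(s) - len(m) + 1):
            if all(s[off + i] in iupac[m[i]] for i in range(len(m))):
                count += 1
        return count

    rc = "".join(comp[ch] for ch in consensus.upper())[::-1]
    return matches(consensus) + matches(rc)


def nearest_gene_allpairs(
    sv: Tuple[int, int],
    chrom: str,
    genes: Sequence[Tuple[str, str, int, int]],
    radius: int,
):
    """Nearest gene by checking every pair; genes are (id, chrom, start, end)."""
    lo, hi = sv
    if hi <= lo:
        hi = lo + 1
    best = None
    for gid, gchrom, gs, ge in genes:
        if gchrom != chrom:
            continue
        if lo < ge and gs < hi:
            d = 0
        elif hi <= gs:
            d = gs - hi
        else:
            d = lo - ge
        if d > radius:
            continue
        if best is None or (d, gid) < best:
            best = (d, gid)
    return best
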