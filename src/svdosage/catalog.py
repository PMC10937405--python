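"""Nonredundant SV catalog construction and genome-wide summaries.

Variants of the same class whose reference coordinates overlap or are
bookended (end == start, i.e. "continuous") collapse into one record whose
source-genome set is the union of its members.  Zero-span insertions,
which have no reference extent to compare, are clustered instead by
breakpoint proximity (<=10 bp) and alternate-allele length similarity
(<=10% relative difference) — a coordinate proxy for sequence-identity
clustering that needs no allele sequences.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import GeneModel, SaturationFit, SVCatalog, SVRecord

INSERTION_BREAKPOINT_TOL = 10  # bp
INSERTION_ALT_LEN_TOL = 0.10  # relative


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _merge_spanned(records: List[SVRecord]) -> List[SVRecord]:
    """Union overlapping-or-bookended reference intervals of one SV class."""
    recs = sorted(records, key=lambda r: (r.start, r.end, r.id))
    out: List[SVRecord] = []
    cluster: List[SVRecord] = []
    cur_end = None
    for r in recs:
        if cluster and r.start <= cur_end:
            cluster.append(r)
            cur_end = max(cur_end, r.end)
        else:
            if cluster:
                out.append(_collapse(cluster))
            cluster = [r]
            cur_end = r.end
    if cluster:
        out.append(_collapse(cluster))
    return out


def _merge_insertions(records: List[SVRecord]) -> List[SVRecord]:
    recs = sorted(records, key=lambda r: (r.start, r.alt_length, r.id))
    out: List[SVRecord] = []
    cluster: List[SVRecord] = []
    for r in recs:
        if cluster:
            anchor = cluster[0]
            close = abs(r.start - anchor.start) <= INSERTION_BREAKPOINT_TOL
            longer = max(r.alt_length, anchor.alt_length)
            similar = longer == 0 or (
                abs(r.alt_length - anchor.alt_length) <= INSERTION_ALT_LEN_TOL * longer
            )
            if close and similar:
                cluster.append(r)
                continue
            out.append(_collapse(cluster))
        cluster = [r]
    if cluster:
        out.append(_collapse(cluster))
    return out


def _collapse(cluster: List[SVRecord]) -> SVRecord:
    if len(cluster) == 1:
        return cluster[0]
    first = cluster[0]
    sources = frozenset(itertools.chain.from_iterable(r.source_genomes for r in cluster))
    seqs = {r.sequence for r in cluster}
    start = min(r.start for r in cluster)
    end = max(r.end for r in cluster)
    # spanned SVs keep SVLEN == reference span; insertion clusters keep the
    # longest member's inserted length
    alt_length = (end - start) if end > start else max(r.alt_length for r in cluster)
    return SVRecord(
        id=first.id,
        chrom=first.chrom,
        start=start,
        end=end,
        sv_type=first.sv_type,
        alt_length=alt_length,
        source_genomes=sources,
        te_overlap_fraction=first.te_overlap_fraction,
        sequence=seqs.pop() if len(seqs) == 1 else None,
    )


def merge_svs(records: Iterable[SVRecord], reference: str = "ref") -> SVCatalog:
    """Collapse per-genome SV calls into a nonredundant catalog.

    Idempotent and invariant to input order.  Raises if records mix
    reference assemblies (detected through a ``reference`` kwarg mismatch
    upstream; records themselves carry only chrom names).
    """
    by_key: Dict[Tuple[str, str], List[SVRecord]] = {}
    for r in records:
        by_key.setdefault((r.chrom, r.sv_type), []).append(r)
    merged: List[SVRecord] = []
    for (chrom, sv_type), group in sorted(by_key.items()):
        spanned = [r for r in group if r.ref_span > 0]
        points = [r for r in group if r.ref_span == 0]
        merged.extend(_merge_spanned(spanned))
        merged.extend(_merge_insertions(points))
    merged.sort(key=lambda r: (r.chrom, r.start, r.end, r.sv_type, r.id))
    return SVCatalog(merged, reference=reference)


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------

CONTEXT_LABELS = ("upstream", "exon", "intron", "downstream", "intergenic")


def _effective_interval(sv: SVRecord) -> Tuple[int, int]:
    """Insertions are treated as covering the single base at the breakpoint."""
    return (sv.start, sv.end) if sv.end > sv.start else (sv.start, sv.start + 1)


def _overlaps(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo < b_hi and b_lo < a_hi


def annotate_context(
    sv: SVRecord, genes: Sequence[GeneModel], flank: int = 3_000
) -> str:
    """Label an SV by its genomic region.

    Precedence when an SV touches several features: exon > intron >
    upstream > downstream > intergenic.  Upstream/downstream are
    strand-aware windows of ``flank`` bp beyond the gene body.
    """
    lo, hi = _effective_interval(sv)
    in_exon = in_body = upstream = downstream = False
    for g in genes:
        if g.chrom != sv.chrom:
            continue
        if _overlaps(lo, hi, g.start, g.end):
            in_body = True
            if any(_overlaps(lo, hi, e0, e1) for e0, e1 in g.exons):
                in_exon = True
            continue
        if g.strand == "+":
            up_lo, up_hi = g.start - flank, g.start
            dn_lo, dn_hi = g.end, g.end + flank
        else:
            up_lo, up_hi = g.end, g.end + flank
            dn_lo, dn_hi = g.start - flank, g.start
        if _overlaps(lo, hi, up_lo, up_hi):
            upstream = True
        if _overlaps(lo, hi, dn_lo, dn_hi):
            downstream = True
    if in_exon:
        return "exon"
    if in_body:
        return "intron"
    if upstream:
        return "upstream"
    if downstream:
        return "downstream"
    return "intergenic"


def context_counts(
    catalog: SVCatalog, genes: Sequence[GeneModel], flank: int = 3_000
) -> pd.Series:
    labels = [annotate_context(sv, genes, flank) for sv in catalog]
    return pd.Series(labels).value_counts().reindex(CONTEXT_LABELS, fill_value=0)


# ---------------------------------------------------------------------------
# density profile
# ---------------------------------------------------------------------------

def density_profile(
    catalog: SVCatalog,
    genes: Sequence[GeneModel],
    flank: int = 5_000,
    n_body_bins: int = 50,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Mean SV sequence coverage around genes.

    Flanks are absolute ``bin_size``-bp bins; gene bodies are rescaled to
    ``n_body_bins`` relative bins.  Profiles are oriented 5'→3' (minus
    strand genes are flipped).  Returns one row per bin with the mean
    fraction of bases covered by SV reference sequence across genes.
    """
    n_flank_bins = flank // bin_size
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for sv in catalog:
        lo, hi = _effective_interval(sv)
        by_chrom.setdefault(sv.chrom, []).append((lo, hi))

    up = np.zeros(n_flank_bins)
    body = np.zeros(n_body_bins)
    down = np.zeros(n_flank_bins)
    n_genes = 0
    for g in genes:
        win_lo = g.start - flank
        win_hi = g.end + flank
        cov = np.zeros(win_hi - win_lo, dtype=bool)
        for lo, hi in by_chrom.get(g.chrom, ()):
            a, b = max(lo, win_lo), min(hi, win_hi)
            if a < b:
                cov[a - win_lo : b - win_lo] = True
        left = cov[:flank]
        gbody = cov[flank : flank + (g.end - g.start)]
        right = cov[flank + (g.end - g.start) :]
        if g.strand == "-":
            left, right = right[::-1], left[::-1]
            gbody = gbody[::-1]
        up += left.reshape(n_flank_bins, bin_size).mean(axis=1)
        edges = np.linspace(0, len(gbody), n_body_bins + 1).round().astype(int)
        body += np.array(
            [gbody[edges[i] : edges[i + 1]].mean() if edges[i + 1] > edges[i] else 0.0
             for i in range(n_body_bins)]
        )
        down += right.reshape(n_flank_bins, bin_size).mean(axis=1)
        n_genes += 1
    if n_genes:
        up /= n_genes
        body /= n_genes
        down /= n_genes
    rows = (
        [("upstream", i, v) for i, v in enumerate(up)]
        + [("body", i, v) for i, v in enumerate(body)]
        + [("downstream", i, v) for i, v in enumerate(down)]
    )
    return pd.DataFrame(rows, columns=["region", "bin", "density"])


# ---------------------------------------------------------------------------
# TE overlap
# ---------------------------------------------------------------------------

def te_overlap(catalog: SVCatalog, te_intervals: pd.DataFrame) -> Tuple[pd.Series, float]:
    """Per-SV TE overlap fraction (on the reference span) and the
    catalog-level fraction of SVs with any TE overlap.

    Pure insertions have no reference span, hence fraction 0.
    """
    merged: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in te_intervals.groupby("chrom"):
        ivals = sorted(zip(sub["start"], sub["end"]))
        starts: List[int] = []
        ends: List[int] = []
        for lo, hi in ivals:
            if starts and lo <= ends[-1]:
                ends[-1] = max(ends[-1], hi)
            else:
                starts.append(lo)
                ends.append(hi)
        s = np.asarray(starts)
        e = np.asarray(ends)
        cum = np.concatenate([[0], np.cumsum(e - s)])
        merged[str(chrom)] = (s, e, cum)

    fracs = {}
    for sv in catalog:
        if sv.ref_span == 0 or sv.chrom not in merged:
            fracs[sv.id] = 0.0
            continue
        s, e, cum = merged[sv.chrom]
        i = np.searchsorted(e, sv.start, side="right")
        j = np.searchsorted(s, sv.end, side="left")
        bp = 0
        if i < j:
            full = cum[j] - cum[i]
            trim = 0
            trim += max(0, sv.start - s[i])
            trim += max(0, e[j - 1] - sv.end)
            bp = full - trim
            # when one TE both starts before and ends after the SV
            if j - i == 1:
                bp = min(e[i], sv.end) - max(s[i], sv.start)
        fracs[sv.id] = bp / sv.ref_span
    per_sv = pd.Series(fracs, name="te_overlap_fraction")
    any_overlap = float((per_sv > 0).mean()) if len(per_sv) else 0.0
    return per_sv, any_overlap


# ---------------------------------------------------------------------------
# private SVs
# ---------------------------------------------------------------------------

EXACT_RANKSUM_MAX_N = 12


def private_sv_counts(catalog: SVCatalog, genomes: Sequence[str]) -> pd.Series:
    """Number of SVs private to (called in exactly) each genome."""
    counts = {g: 0 for g in genomes}
    for sv in catalog:
        if len(sv.source_genomes) == 1:
            (g,) = sv.source_genomes
            if g in counts:
                counts[g] += 1
    return pd.Series(counts, name="private_svs")


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p; exact when both groups are small."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("rank-sum test needs >=2 observations per group")
    exact = max(len(a), len(b)) <= EXACT_RANKSUM_MAX_N and not _has_ties(a, b)
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def private_sv_stats(
    catalog: SVCatalog, genome_groups: Mapping[str, Sequence[str]]
) -> Tuple[pd.Series, pd.DataFrame]:
    """Per-genome private counts and pairwise rank-sum p between groups."""
    all_genomes = [g for members in genome_groups.values() for g in members]
    counts = private_sv_counts(catalog, all_genomes)
    rows = []
    for (ga, members_a), (gb, members_b) in itertools.combinations(
        genome_groups.items(), 2
    ):
        if len(members_a) < 2 or len(members_b) < 2:
            rows.append((ga, gb, np.nan, True))
            continue
        p = rank_sum_test(counts[list(members_a)], counts[list(members_b)])
        rows.append((ga, gb, p, False))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "p_value", "undefined"])
    return counts, tests


# ---------------------------------------------------------------------------
# saturation modeling
# ---------------------------------------------------------------------------

def pan_sv_curves(
    catalog: SVCatalog,
    genomes: Sequence[str],
    n_orderings: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Cumulative distinct-SV counts over random genome orderings.

    Returns an array of shape (n_orderings, n_genomes); row r, column k is
    the number of distinct SVs discovered by the first k+1 genomes of
    ordering r.
    """
    genomes = list(genomes)
    sv_sets = {g: set() for g in genomes}
    for i, sv in enumerate(catalog):
        for g in sv.source_genomes:
            if g in sv_sets:
                sv_sets[g].add(i)
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_orderings, len(genomes)), dtype=float)
    for r in range(n_orderings):
        order = rng.permutation(len(genomes))
        seen: set = set()
        for k, gi in enumerate(order):
            seen |= sv_sets[genomes[gi]]
            curves[r, k] = len(seen)
    return curves


def _fit_one_curve(ns: np.ndarray, counts: np.ndarray) -> Tuple[float, float, float]:
    if np.allclose(counts, counts[0]):
        return float(counts[0]), 0.0, 1.0
    a0 = float(counts[-1]) * 1.05
    b0 = max(a0 - float(counts[0]), 1.0)
    c0 = max(len(ns) / 3.0, 1.0)
    popt, _ = optimize.curve_fit(
        lambda n, A, B, C: A - B * np.exp(-n / C),
        ns,
        counts,
        p0=(a0, b0, c0),
        bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]),
        maxfev=20_000,
    )
    return tuple(float(v) for v in popt)


def saturation_fit(curves: np.ndarray) -> SaturationFit:
    """Fit P(n) = A - B*exp(-n/C) to pan-SV accumulation curves.

    ``curves`` is (n_orderings, n_points) or a single 1-D curve; counts
    must be nondecreasing in n.  The predicted total SV number is the mean
    asymptote A over orderings, its uncertainty the standard deviation of
    A across orderings.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if curves.shape[1] < 4:
        raise ValueError("saturation fit needs at least 4 panel sizes")
    if (np.diff(curves, axis=1) < 0).any():
        raise ValueError("cumulative counts must be nondecreasing")
    ns = np.arange(1, curves.shape[1] + 1, dtype=float)
    params = np.array([_fit_one_curve(ns, row) for row in curves])
    a_vals = params[:, 0]
    se = float(a_vals.std(ddof=1)) if len(a_vals) > 1 else 0.0
    return SaturationFit(
        A=float(a_vals.mean()),
        B=float(params[:, 1].mean()),
        C=float(params[:, 2].mean()),
        predicted_total=float(a_vals.mean()),
        predicted_se=se,
    )


# ---------------------------------------------------------------------------
# LTR insertion time
# ---------------------------------------------------------------------------

def ltr_insertion_time(divergence: float, rate: float = 1.3e-8) -> float:
    """Insertion age in years from LTR-pair divergence: T = K / (2*rate)."""
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    return divergence / (2.0 * rate)
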