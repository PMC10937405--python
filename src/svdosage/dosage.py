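"""SV-gene linking and bidirectional dosage classification.

Each SV is assigned to its closest gene within a 10-kb radius (the "SV
gene"), genomes or accessions are split by the orientation-free
presence/absence genotype (the allele carrying more sequence is
"presence"), and the group mean TPMs decide the direction: presence mean
at least 1.5-fold above the absence mean is a *promoting* SV, the mirror
case a *suppressing* SV.  Panel mode (27 assemblies) uses the fold rule
alone; population mode additionally requires a significant two-sided
Mann-Whitney U test across genotype groups.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .models import (
    ABSENCE,
    DISTANCE_BINS,
    MISSING,
    PRESENCE,
    DosageCall,
    EligibilityError,
    GeneModel,
    GenotypeMatrix,
    SVCatalog,
    SVGeneLink,
    SVRecord,
)

FLANK_BINS = (("0-1.5kb", 1_500), ("1.5-3kb", 3_000), ("3-5kb", 5_000), ("5-10kb", 10_000))


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _interval(sv: SVRecord) -> Tuple[int, int]:
    return (sv.start, sv.end) if sv.end > sv.start else (sv.start, sv.start + 1)


def _edge_distance(lo: int, hi: int, g: GeneModel) -> int:
    """Unsigned edge-to-edge gap; 0 when the SV overlaps or abuts the gene."""
    if lo < g.end and g.start < hi:
        return 0
    return g.start - hi if hi <= g.start else lo - g.end


def _signed_distance(lo: int, hi: int, g: GeneModel) -> int:
    """Strand-aware signed distance: negative upstream, positive downstream."""
    d = _edge_distance(lo, hi, g)
    if d == 0:
        return 0
    left_of_gene = hi <= g.start
    upstream = left_of_gene if g.strand == "+" else not left_of_gene
    return -d if upstream else d


def link_sv_to_gene(
    sv: SVRecord, genes: Sequence[GeneModel], config: Optional[AnalysisConfig] = None
) -> Optional[SVGeneLink]:
    """Assign an SV to its closest gene within the linking radius.

    Returns None when no gene lies within ``link_radius_bp``.  Distance
    bins: CDS (overlaps coding sequence), intron (overlaps gene body but
    no CDS), then flank bins by unsigned distance.
    """
    config = config or AnalysisConfig()
    lo, hi = _interval(sv)
    best: Optional[Tuple[int, str, GeneModel]] = None
    for g in genes:
        if g.chrom != sv.chrom:
            continue
        d = _edge_distance(lo, hi, g)
        if d > config.link_radius_bp:
            continue
        key = (d, g.id)
        if best is None or key < (best[0], best[1]):
            best = (d, g.id, g)
    if best is None:
        return None
    d, _, gene = best
    overlaps_body = lo < gene.end and gene.start < hi
    if overlaps_body:
        in_cds = any(lo < c1 and c0 < hi for c0, c1 in gene.cds)
        bin_label = "CDS" if in_cds else "intron"
    else:
        bin_label = next(label for label, edge in FLANK_BINS if d <= edge)
    return SVGeneLink(
        sv_id=sv.id,
        gene_id=gene.id,
        distance=_signed_distance(lo, hi, gene),
        bin=bin_label,
    )


def link_catalog(
    catalog: SVCatalog, genes: Sequence[GeneModel], config: Optional[AnalysisConfig] = None
) -> List[SVGeneLink]:
    links = []
    for sv in catalog:
        link = link_sv_to_gene(sv, genes, config)
        if link is not None:
            links.append(link)
    return links


def unique_links(links: Iterable[SVGeneLink]) -> List[SVGeneLink]:
    """Keep only genes with exactly one linked SV in the radius."""
    per_gene: Dict[str, List[SVGeneLink]] = {}
    for ln in links:
        per_gene.setdefault(ln.gene_id, []).append(ln)
    return [lns[0] for lns in per_gene.values() if len(lns) == 1]


# ---------------------------------------------------------------------------
# genotype orientation
# ---------------------------------------------------------------------------

def orient_genotypes(
    ref_allele_len: int, alt_allele_len: int, carrier_calls: pd.Series
) -> pd.Series:
    """Convert carries-the-alt calls into presence/absence of the longer allele.

    ``carrier_calls`` holds 1 (carries alternate), 0 (reference) or -1
    (missing).  The result is reference-free: carriers of whichever allele
    is longer become PRESENCE.
    """
    if ref_allele_len == alt_allele_len:
        raise ValueError("equal allele lengths: not a presence/absence variant")
    alt_longer = alt_allele_len > ref_allele_len
    out = carrier_calls.copy()
    nonmissing = carrier_calls != MISSING
    if alt_longer:
        out[nonmissing] = np.where(carrier_calls[nonmissing] == 1, PRESENCE, ABSENCE)
    else:
        out[nonmissing] = np.where(carrier_calls[nonmissing] == 1, ABSENCE, PRESENCE)
    return out.astype("int8")


# ---------------------------------------------------------------------------
# expression filters
# ---------------------------------------------------------------------------

def expressed_filter(
    tpm_values: Sequence[float], mode: str, config: Optional[AnalysisConfig] = None
) -> bool:
    """Is a gene expressed?  Panel: TPM >= 1 in strictly more than 60% of
    samples.  Population: TPM >= 5 in strictly more than 30% of samples."""
    config = config or AnalysisConfig()
    vals = np.asarray(tpm_values, dtype=float)
    if vals.size == 0:
        raise ValueError("expressed_filter needs at least one value")
    if mode == "panel":
        tpm_min, frac_min = config.tpm_min_panel, config.frac_min_panel
    elif mode == "population":
        tpm_min, frac_min = config.tpm_min_pop, config.frac_min_pop
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (vals >= tpm_min).mean() > frac_min


# ---------------------------------------------------------------------------
# direction calls
# ---------------------------------------------------------------------------

def _fold_and_direction(
    mean_p: float, mean_a: float, fold_threshold: float
) -> Tuple[float, str]:
    if mean_a == 0.0 and mean_p == 0.0:
        return 1.0, "none"
    if mean_a == 0.0:
        return math.inf, "promoting"
    ratio = mean_p / mean_a
    if ratio >= fold_threshold:
        return ratio, "promoting"
    if mean_p == 0.0 or (1.0 / ratio) >= fold_threshold:
        return ratio, "suppressing"
    return ratio, "none"


def call_direction_panel(
    link: SVGeneLink,
    genotypes: pd.Series,
    expression: pd.Series,
    config: Optional[AnalysisConfig] = None,
) -> DosageCall:
    """Panel-mode dosage call from per-genome presence calls and TPMs.

    ``genotypes``: genome -> {PRESENCE, ABSENCE, MISSING}; ``expression``:
    genome -> TPM for the linked gene.  Raises
    :class:`EligibilityError` when the minority genotype group has fewer
    than ``min_genomes_per_group`` genomes or the gene is not expressed in
    either group.
    """
    config = config or AnalysisConfig()
    shared = genotypes.index.intersection(expression.index)
    gts = genotypes[shared]
    pres = expression[shared][gts == PRESENCE].to_numpy(dtype=float)
    abs_ = expression[shared][gts == ABSENCE].to_numpy(dtype=float)
    if min(len(pres), len(abs_)) < config.min_genomes_per_group:
        raise EligibilityError(
            f"{link.sv_id}: minority group has {min(len(pres), len(abs_))} genomes "
            f"(< {config.min_genomes_per_group})"
        )
    expressed = expressed_filter(pres, "panel", config) or expressed_filter(
        abs_, "panel", config
    )
    if not expressed:
        raise EligibilityError(f"{link.gene_id}: not expressed in either genotype group")
    mean_p = float(pres.mean())
    mean_a = float(abs_.mean())
    fold, direction = _fold_and_direction(mean_p, mean_a, config.fold_threshold)
    return DosageCall(
        sv_id=link.sv_id,
        gene_id=link.gene_id,
        n_presence=len(pres),
        n_absence=len(abs_),
        mean_tpm_presence=mean_p,
        mean_tpm_absence=mean_a,
        fold_ratio=fold,
        direction=direction,
        mode="panel",
        bin=link.bin,
    )


def mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U: exact for small tie-free groups, otherwise
    the tie-corrected normal approximation."""
    exact = max(len(a), len(b)) <= 8 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def call_direction_population(
    link: SVGeneLink,
    genotypes: pd.Series,
    expression: pd.Series,
    config: Optional[AnalysisConfig] = None,
) -> DosageCall:
    """Population-mode dosage call across accessions.

    Eligibility: >= ``min_genotyped`` non-missing calls, >=
    ``min_group_size`` accessions in each genotype group, and the gene
    expressed by the population rule.  Direction is assigned only when
    the Mann-Whitney p is below alpha AND the fold rule holds.
    """
    config = config or AnalysisConfig()
    shared = genotypes.index.intersection(expression.index)
    gts = genotypes[shared]
    nonmissing = gts != MISSING
    if int(nonmissing.sum()) < config.min_genotyped:
        raise EligibilityError(
            f"{link.sv_id}: only {int(nonmissing.sum())} genotyped accessions "
            f"(< {config.min_genotyped})"
        )
    pres = expression[shared][gts == PRESENCE].to_numpy(dtype=float)
    abs_ = expression[shared][gts == ABSENCE].to_numpy(dtype=float)
    if min(len(pres), len(abs_)) < config.min_group_size:
        raise EligibilityError(
            f"{link.sv_id}: genotype group with {min(len(pres), len(abs_))} accessions "
            f"(< {config.min_group_size})"
        )
    all_vals = np.concatenate([pres, abs_])
    if not expressed_filter(all_vals, "population", config):
        raise EligibilityError(f"{link.gene_id}: not expressed in the population")
    p = mann_whitney_p(pres, abs_)
    mean_p = float(pres.mean())
    mean_a = float(abs_.mean())
    fold, direction = _fold_and_direction(mean_p, mean_a, config.fold_threshold)
    if p >= config.alpha:
        direction = "none"
    return DosageCall(
        sv_id=link.sv_id,
        gene_id=link.gene_id,
        n_presence=len(pres),
        n_absence=len(abs_),
        mean_tpm_presence=mean_p,
        mean_tpm_absence=mean_a,
        fold_ratio=fold,
        direction=direction,
        mode="population",
        p_value=p,
        bin=link.bin,
    )


def dosage_pipeline(
    catalog: SVCatalog,
    genes: Sequence[GeneModel],
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame,
    mode: str = "panel",
    config: Optional[AnalysisConfig] = None,
) -> Tuple[List[DosageCall], pd.DataFrame]:
    """Link, filter and call directions for a whole catalog.

    Returns the calls plus a skip log (sv_id, gene_id, reason).
    """
    config = config or AnalysisConfig()
    caller = call_direction_panel if mode == "panel" else call_direction_population
    links = unique_links(link_catalog(catalog, genes, config))
    calls: List[DosageCall] = []
    skipped = []
    for link in links:
        if link.gene_id not in expression.index:
            skipped.append((link.sv_id, link.gene_id, "no expression data"))
            continue
        try:
            calls.append(
                caller(link, genotypes.calls[link.sv_id], expression.loc[link.gene_id], config)
            )
        except EligibilityError as exc:
            skipped.append((link.sv_id, link.gene_id, str(exc)))
    skip_log = pd.DataFrame(skipped, columns=["sv_id", "gene_id", "reason"])
    return calls, skip_log


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def asymmetry_binomial(n_suppressing: int, n_promoting: int) -> float:
    """Exact two-sided binomial test of suppression/promotion balance."""
    if n_suppressing < 0 or n_promoting < 0:
        raise ValueError("counts must be >= 0")
    n = n_suppressing + n_promoting
    if n == 0:
        raise ValueError("at least one call required")
    return float(stats.binomtest(n_suppressing, n, 0.5).pvalue)


def zscore_profile(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores (sample sd); constant rows map to all zeros."""
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    z = expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def fold_change_profile(
    calls: Sequence[DosageCall],
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Per-distance-bin distribution of log2 fold ratios.

    Infinite ratios (absence mean zero) are counted but excluded from the
    quantile summary.
    """
    rows = []
    for b in DISTANCE_BINS:
        in_bin = [c for c in calls if c.bin == b]
        finite = np.array(
            [c.fold_ratio for c in in_bin if np.isfinite(c.fold_ratio) and c.fold_ratio > 0]
        )
        log2f = np.log2(finite) if finite.size else np.array([])
        row = {"bin": b, "n_calls": len(in_bin), "n_infinite": len(in_bin) - finite.size}
        for q in quantiles:
            row[f"q{q:g}"] = float(np.quantile(log2f, q)) if log2f.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
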