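"""Population-scale SV association analyses.

Case-control SV-GWAS by two-tailed Fisher's exact test on accession-level
presence/absence tables (missing calls dropped per SV), Bonferroni
correction over the SVs tested, top-fraction signal selection, two-SV
haplotype grouping with expression comparisons, LD (r^2) between SVs and
SNPs, and cis/trans labeling of expression-association signals.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .models import ABSENCE, MISSING, PRESENCE, GeneModel, GenotypeMatrix

logger = logging.getLogger("svdosage")

HAPLOTYPE_LABELS = {
    (ABSENCE, ABSENCE): "hap1",  # neither SV
    (ABSENCE, PRESENCE): "hap2",  # SV2 only
    (PRESENCE, ABSENCE): "hap3",  # SV1 only
    (PRESENCE, PRESENCE): "hap4",  # both SVs
}


# ---------------------------------------------------------------------------
# Fisher case-control GWAS
# ---------------------------------------------------------------------------

def fisher_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p: sum of hypergeometric outcomes whose
    point probability does not exceed the observed table's."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def case_control_fisher(
    genotypes: GenotypeMatrix,
    case_label: str,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Per-SV case-control association between one morphotype and the rest.

    Counts accessions (not alleles) with presence/absence calls; missing
    calls are excluded per SV.  SVs with an empty margin (no usable case
    or control calls) are skipped and logged.  Bonferroni correction uses
    the number of SVs actually tested.
    """
    config = config or AnalysisConfig()
    morphs = genotypes.morphotypes()
    is_case = (morphs == case_label).to_numpy()
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValueError(f"need >=1 case and >=1 control accession for {case_label!r}")
    calls = genotypes.calls.to_numpy()
    rows = []
    for j, sv_id in enumerate(genotypes.sv_ids):
        col = calls[:, j]
        usable = col != MISSING
        case_p = int(((col == PRESENCE) & is_case & usable).sum())
        case_a = int(((col == ABSENCE) & is_case & usable).sum())
        ctrl_p = int(((col == PRESENCE) & ~is_case & usable).sum())
        ctrl_a = int(((col == ABSENCE) & ~is_case & usable).sum())
        if case_p + case_a == 0 or ctrl_p + ctrl_a == 0:
            logger.warning("SV %s skipped: empty case or control margin", sv_id)
            continue
        p = fisher_two_tailed([[case_p, case_a], [ctrl_p, ctrl_a]])
        case_freq = case_p / (case_p + case_a)
        ctrl_freq = ctrl_p / (ctrl_p + ctrl_a)
        rows.append(
            (sv_id, case_p, case_a, ctrl_p, ctrl_a, p,
             "case" if case_freq > ctrl_freq else "control")
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "sv_id", "case_presence", "case_absence",
            "control_presence", "control_absence", "p_raw", "enriched_in",
        ],
    ).set_index("sv_id")
    n_tests = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * n_tests)
    return out


def select_signals(
    results: pd.DataFrame,
    top_fraction: Optional[float] = None,
    alpha: Optional[float] = None,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[pd.Index, pd.Index]:
    """Bonferroni-significant SVs and the smallest-p top-fraction set.

    Ties at the top-fraction cutoff p-value are all included.
    """
    config = config or AnalysisConfig()
    top_fraction = config.top_fraction if top_fraction is None else top_fraction
    alpha = config.alpha if alpha is None else alpha
    if results.empty:
        raise ValueError("empty result table")
    bonf = results.index[results["p_bonferroni"] < alpha]
    k = int(np.ceil(top_fraction * len(results)))
    if k == 0:
        return bonf, results.index[:0]
    cut = results["p_raw"].nsmallest(k).iloc[-1]
    top = results.index[results["p_raw"] <= cut]
    return bonf, top


# ---------------------------------------------------------------------------
# haplotype groups
# ---------------------------------------------------------------------------

def haplotype_groups(
    sv1_calls: pd.Series,
    sv2_calls: pd.Series,
    expression: Optional[pd.Series] = None,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Partition accessions by joint genotype at two SVs.

    hap1 = neither SV, hap2 = SV2 only, hap3 = SV1 only, hap4 = both.
    Accessions missing either call are excluded.  When expression values
    are supplied, all non-empty group pairs with >= 2 accessions each are
    compared by a two-sided Student's t test.
    """
    shared = sv1_calls.index.intersection(sv2_calls.index)
    g1 = sv1_calls[shared]
    g2 = sv2_calls[shared]
    ok = (g1 != MISSING) & (g2 != MISSING)
    labels = pd.Series(
        [HAPLOTYPE_LABELS[(a, b)] for a, b in zip(g1[ok], g2[ok])],
        index=shared[ok],
        name="haplotype",
    )
    comparisons = pd.DataFrame(
        columns=["group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b", "p_value"]
    )
    if expression is not None:
        groups = {
            h: expression.reindex(labels.index[labels == h]).dropna()
            for h in ("hap1", "hap2", "hap3", "hap4")
        }
        nonempty = {h: v for h, v in groups.items() if len(v) >= 2}
        rows = []
        for (ha, va), (hb, vb) in itertools.combinations(nonempty.items(), 2):
            p = float(stats.ttest_ind(va, vb).pvalue)
            rows.append((ha, hb, len(va), len(vb), float(va.mean()), float(vb.mean()), p))
        if rows:
            comparisons = pd.DataFrame(rows, columns=comparisons.columns)
    return labels, comparisons


# ---------------------------------------------------------------------------
# LD with SNPs
# ---------------------------------------------------------------------------

def _r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_r2(
    sv_dosages: pd.DataFrame,
    snp_dosages: pd.DataFrame,
    weak_threshold: float = 0.5,
) -> pd.DataFrame:
    """Best r^2 of each SV with any supplied SNP.

    Dosage frames are accessions x variants with NaN for missing; pairs
    with missing values are dropped pairwise.  SNP columns should already
    be restricted to the window of interest.  ``weak_ld`` flags SVs whose
    best r^2 falls below the threshold.
    """
    shared = sv_dosages.index.intersection(snp_dosages.index)
    svm = sv_dosages.loc[shared].to_numpy(dtype=float)
    snm = snp_dosages.loc[shared].to_numpy(dtype=float)
    rows = []
    for j, sv_id in enumerate(sv_dosages.columns):
        best = np.nan
        for k in range(snm.shape[1]):
            r2 = _r2(svm[:, j], snm[:, k])
            if not np.isnan(r2) and (np.isnan(best) or r2 > best):
                best = r2
        rows.append((sv_id, best, bool(best < weak_threshold) if not np.isnan(best) else True))
    return pd.DataFrame(rows, columns=["sv_id", "best_r2", "weak_ld"]).set_index("sv_id")


def dosage_from_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence/missing codes -> numeric dosages with NaN missing."""
    return calls.replace(MISSING, np.nan).astype(float)


# ---------------------------------------------------------------------------
# cis/trans labeling
# ---------------------------------------------------------------------------

def classify_cis_trans(
    assoc_table: pd.DataFrame,
    genes: Mapping[str, GeneModel],
    sv_positions: Mapping[str, Tuple[str, int, int]],
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Label significant expression-association signals cis or trans.

    ``assoc_table`` columns: gene_id, sv_id, p (from an external
    mixed-model eGWAS).  Signals with p below ``egwas_alpha`` are kept; a
    same-chromosome SV within ``cis_window_bp`` of the gene span is cis,
    everything else (including interchromosomal) is trans.
    """
    config = config or AnalysisConfig()
    rows = []
    for _, row in assoc_table.iterrows():
        gene_id, sv_id, p = row["gene_id"], row["sv_id"], float(row["p"])
        if gene_id not in genes:
            raise KeyError(f"unknown gene id {gene_id!r}")
        if sv_id not in sv_positions:
            raise KeyError(f"unknown SV id {sv_id!r}")
        if p >= config.egwas_alpha:
            continue
        g = genes[gene_id]
        chrom, lo, hi = sv_positions[sv_id]
        if hi <= lo:
            hi = lo + 1
        if chrom == g.chrom:
            dist = 0 if (lo < g.end and g.start < hi) else max(g.start - hi + 1, lo - g.end)
            label = "cis" if dist <= config.cis_window_bp else "trans"
        else:
            label = "trans"
        rows.append((gene_id, sv_id, p, label))
    return pd.DataFrame(rows, columns=["gene_id", "sv_id", "p", "label"])
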