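"""Regulatory signatures separating suppressing from promoting SVs.

Suppressing SV sequences are characterized by dense, highly methylated
CpG islands; promoting SVs by transcription-factor binding motifs.  This
module provides the weighted methylation level (total methylated reads /
total reads over CpG sites with depth >= 3), a sliding-window CpG-island
detector (length >= 200 bp, GC >= 50%, observed/expected CpG >= 0.6),
label-permutation tests, and an IUPAC consensus motif scanner with
per-kb enrichment testing between SV classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig

CPG_WINDOW = 200
CPG_MIN_GC = 0.50
CPG_MIN_OBS_EXP = 0.60

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


# ---------------------------------------------------------------------------
# weighted methylation
# ---------------------------------------------------------------------------

def weighted_methylation(
    sites: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    config: Optional[AnalysisConfig] = None,
) -> Optional[float]:
    """Reads-weighted CpG methylation level of an interval.

    Restricts to sites on ``chrom`` in [start, end) with total reads >=
    ``min_cpg_depth`` and returns sum(methylated)/sum(total), or None when
    no site qualifies.
    """
    config = config or AnalysisConfig()
    sel = sites[
        (sites["chrom"] == chrom)
        & (sites["pos"] >= start)
        & (sites["pos"] < end)
        & (sites["total"] >= config.min_cpg_depth)
    ]
    total = int(sel["total"].sum())
    if total == 0:
        return None
    return float(sel["methylated"].sum() / total)


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpGIsland:
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    weighted_methylation: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _gc_obs_exp(c: int, g: int, cpg: int, length: int) -> Tuple[float, float]:
    gc = (c + g) / length
    obs_exp = (cpg * length) / (c * g) if c * g > 0 else 0.0
    return gc, obs_exp


def detect_cpg_islands(sequence: str) -> List[CpGIsland]:
    """CpG islands by the classical criteria.

    200-bp windows (step 1) qualifying on all of GC >= 0.50 and
    observed/expected CpG >= 0.60 are merged when they overlap; a merged
    interval is retained only if it still satisfies both criteria when
    recomputed over its full span.  Output intervals are sorted and
    disjoint.
    """
    s = sequence.upper()
    n = len(s)
    if n < CPG_WINDOW:
        return []
    arr = np.frombuffer(s.encode(), dtype="S1")
    is_c = (arr == b"C").astype(np.int32)
    is_g = (arr == b"G").astype(np.int32)
    is_cpg = np.zeros(n, dtype=np.int32)
    is_cpg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

    starts = np.arange(0, n - CPG_WINDOW + 1)
    c = cum_c[starts + CPG_WINDOW] - cum_c[starts]
    g = cum_g[starts + CPG_WINDOW] - cum_g[starts]
    # dinucleotides fully inside the window: positions start .. start+198
    cpg = cum_cpg[starts + CPG_WINDOW - 1] - cum_cpg[starts]
    gc = (c + g) / CPG_WINDOW
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(c * g > 0, cpg * CPG_WINDOW / np.maximum(c * g, 1), 0.0)
    ok = (gc >= CPG_MIN_GC) & (obs_exp >= CPG_MIN_OBS_EXP)

    islands: List[CpGIsland] = []
    i = 0
    idx = np.flatnonzero(ok)
    while i < len(idx):
        j = i
        end_window = idx[i]
        # chain windows that overlap the current merged interval
        while j + 1 < len(idx) and idx[j + 1] < end_window + CPG_WINDOW:
            j += 1
            end_window = idx[j]
        lo = int(idx[i])
        hi = int(end_window) + CPG_WINDOW
        cc = int(cum_c[hi] - cum_c[lo])
        gg = int(cum_g[hi] - cum_g[lo])
        pp = int(cum_cpg[hi - 1] - cum_cpg[lo])
        gc_m, oe_m = _gc_obs_exp(cc, gg, pp, hi - lo)
        if gc_m >= CPG_MIN_GC and oe_m >= CPG_MIN_OBS_EXP:
            islands.append(CpGIsland(lo, hi, gc_m, oe_m))
        i = j + 1
    return islands


def island_stats(
    sv_sequences: Mapping[str, str],
    methylation: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Per-SV CpG-island density and ratio of highly methylated islands.

    Methylation sites are addressed by SV id (``chrom`` column) with
    positions in SV-sequence coordinates.  Density is islands per kb of
    SV sequence; an island is highly methylated when its weighted level
    reaches ``high_methylation_threshold``.  The ratio is NaN for SVs
    without islands or without measurable islands.
    """
    config = config or AnalysisConfig()
    rows = []
    for sv_id, seq in sv_sequences.items():
        islands = detect_cpg_islands(seq)
        kb = len(seq) / 1_000
        density = len(islands) / kb if kb > 0 else 0.0
        n_meas = n_high = 0
        for isl in islands:
            level = weighted_methylation(methylation, sv_id, isl.start, isl.end, config)
            if level is None:
                continue
            n_meas += 1
            if level >= config.high_methylation_threshold:
                n_high += 1
        ratio = n_high / n_meas if n_meas else np.nan
        rows.append((sv_id, len(seq), len(islands), density, n_meas, n_high, ratio))
    return pd.DataFrame(
        rows,
        columns=[
            "sv_id", "seq_length", "n_islands", "island_density_per_kb",
            "n_measured", "n_highly_methylated", "high_methylation_ratio",
        ],
    ).set_index("sv_id")


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
) -> float:
    """Two-sided label-permutation p for a difference between two groups.

    Default statistic is the difference of means.  Uses the add-one
    estimator p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm), so p is
    bounded below by 1/(n_perm+1) and never zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    stat = statistic or (lambda x, y: float(x.mean() - y.mean()))
    t_obs = abs(stat(a, b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(stat(perm[: a.size], perm[a.size :])) >= t_obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# TF-binding sites
# ---------------------------------------------------------------------------

def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in {consensus!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences all count
    return re.compile(f"(?={''.join(parts)})")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_tfbs(sequence: str, motifs: Mapping[str, str]) -> Dict[str, int]:
    """Count motif matches on both strands (overlaps allowed).

    The reverse strand is scanned by matching the reverse-complemented
    consensus against the given sequence, so a palindromic site counts
    once per strand.
    """
    s = sequence.upper()
    counts: Dict[str, int] = {}
    for name, consensus in motifs.items():
        fwd = len(_iupac_regex(consensus).findall(s))
        rev = len(_iupac_regex(reverse_complement(consensus)).findall(s))
        counts[name] = fwd + rev
    return counts


def tfbs_hit_matrix(
    sequences: Mapping[str, str], motifs: Mapping[str, str], per_kb: bool = True
) -> pd.DataFrame:
    rows = {}
    for sv_id, seq in sequences.items():
        counts = scan_tfbs(seq, motifs)
        if per_kb:
            kb = max(len(seq) / 1_000, 1e-9)
            counts = {k: v / kb for k, v in counts.items()}
        rows[sv_id] = counts
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(motifs))


def tfbs_enrichment(
    promoting_seqs: Mapping[str, str],
    suppressing_seqs: Mapping[str, str],
    motifs: Mapping[str, str],
    config: Optional[AnalysisConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-motif permutation test of TFBS density between SV classes.

    Observed statistic per motif: difference in mean per-kb hit count
    (promoting - suppressing); SV-set labels are permuted
    ``perm_n_tfbs`` times.
    """
    config = config or AnalysisConfig()
    if not promoting_seqs or not suppressing_seqs:
        raise ValueError("both SV sets must be nonempty")
    hits_p = tfbs_hit_matrix(promoting_seqs, motifs).to_numpy()
    hits_s = tfbs_hit_matrix(suppressing_seqs, motifs).to_numpy()
    n_p = hits_p.shape[0]
    pooled = np.vstack([hits_p, hits_s])
    obs = hits_p.mean(axis=0) - hits_s.mean(axis=0)
    rng = np.random.default_rng(seed)
    n_perm = config.perm_n_tfbs
    hits = np.zeros(len(obs), dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        diff = pooled[idx[:n_p]].mean(axis=0) - pooled[idx[n_p:]].mean(axis=0)
        hits += np.abs(diff) >= np.abs(obs)
    p = (1 + hits) / (1 + n_perm)
    return pd.DataFrame(
        {
            "motif": list(motifs),
            "mean_per_kb_promoting": hits_p.mean(axis=0),
            "mean_per_kb_suppressing": hits_s.mean(axis=0),
            "difference": obs,
            "p_value": p,
        }
    ).set_index("motif")
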