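"""Synthetic pan-genome, population and multi-omics data with planted truth.

The generator emulates the statistical structure of a crucifer pan-genome
study: a panel of 27 assembled genomes and a ~700-accession population
genotyped for presence/absence SVs, leaf expression matrices, CpG
methylation counts over SV sequences, and promoter/SV sequences.  Every
SV carries a planted ground truth: its direction (suppressing, promoting
or none), its expression fold, and optionally a morphotype association.
Suppressing SVs receive CpG-island-rich sequences with high planted
methylation; promoting SVs receive TF-binding-motif-rich sequences;
null SVs receive CpG-depleted background, so the downstream dosage,
regulatory-signature and association modules can be validated against
the truth table.

Genes sit on a regular slot layout (one gene per 26-kb slot) so that each
planted SV's nearest gene is its target by construction and no gene has
two SVs within the 10-kb linking radius.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as svio
from .models import (
    ABSENCE,
    DISTANCE_BINS,
    MISSING,
    PRESENCE,
    GeneModel,
    GenotypeMatrix,
    SVCatalog,
    SVRecord,
)
from .regsig import IUPAC, detect_cpg_islands

# --- layout constants -------------------------------------------------------
SLOT_BP = 26_000  # one gene per slot; flanks stay unambiguous within 10 kb
GENE_OFFSET = 10_500  # gene start within its slot
N_CHROMS = 3
GENE_LEN_RANGE = (2_000, 5_000)
SV_LEN_RANGE = (50, 2_000)
MEAN_CPG_DEPTH = 30
ISLAND_METH_TARGET = 0.90
BACKGROUND_METH = 0.10

DEFAULT_MOTIFS: Dict[str, str] = {
    "TCP": "GGNCCCAC",
    "MYB": "CNGTTR",
    "NAC": "CACGCAA",
    "ERF": "GCCGCC",
    "GRAS": "GTTAAGR",
}

#: population morphotype composition (counts for 704 accessions)
MORPHOTYPE_704: Dict[str, int] = {
    "wild": 36,
    "cabbage": 310,
    "cauliflower": 153,
    "broccoli": 63,
    "kohlrabi": 46,
    "curly_kale": 21,
    "ornamental_kale": 18,
    "chinese_kale": 24,
    "brussels_sprout": 20,
    "tronchuda_kale": 7,
    "collard_green": 6,
}

LINEAGE: Dict[str, str] = {
    "wild": "wild",
    "curly_kale": "wild",
    "ornamental_kale": "wild",
    "chinese_kale": "AIL",
    "cauliflower": "AIL",
    "broccoli": "AIL",
    "kohlrabi": "AIL",
    "cabbage": "LHL",
    "brussels_sprout": "LHL",
    "tronchuda_kale": "LHL",
    "collard_green": "LHL",
}

#: panel genome morphotypes (27 assemblies; wild relatives included)
PANEL_MORPHOTYPES: Tuple[str, ...] = (
    "cabbage", "cabbage", "cabbage", "cabbage", "kohlrabi", "brussels_sprout",
    "wild", "wild", "chinese_kale", "curly_kale", "cabbage", "curly_kale",
    "tronchuda_kale", "collard_green", "collard_green", "ornamental_kale",
    "chinese_kale", "cauliflower", "broccoli", "cauliflower", "curly_kale",
    "kohlrabi", "cabbage", "broccoli", "cabbage", "cauliflower", "cabbage",
)


def default_morphotype_spec(n_accessions: int) -> Dict[str, int]:
    """Scale the reference 704-accession composition to ``n_accessions``."""
    if n_accessions == 704:
        return dict(MORPHOTYPE_704)
    total = sum(MORPHOTYPE_704.values())
    spec = {m: max(1, round(c * n_accessions / total)) for m, c in MORPHOTYPE_704.items()}
    # fix rounding drift on the largest class
    drift = n_accessions - sum(spec.values())
    spec["cabbage"] += drift
    if spec["cabbage"] < 1:
        raise ValueError(f"n_accessions={n_accessions} too small for the default spec")
    return spec


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study's scale and effect structure: a
    27-genome panel, a 704-accession population, expression folds between
    1.5x and 10x, log-normal TPM noise with CV 0.3, and a roughly
    balanced suppression/promotion split with a slight excess of
    suppressing SVs.
    """

    n_genomes: int = 27
    n_accessions: int = 704
    n_genes: int = 2_000
    n_svs: int = 600
    morphotype_spec: Optional[Dict[str, int]] = None
    frac_suppressing: float = 0.35
    frac_promoting: float = 0.30
    effect_fold_range: Tuple[float, float] = (1.5, 10.0)
    noise_cv: float = 0.30
    missing_rate: float = 0.05
    n_assoc_svs: int = 4
    assoc_gap: float = 0.8
    exclusive_morphotype: str = "ornamental_kale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morphotype_spec is None:
            self.morphotype_spec = default_morphotype_spec(self.n_accessions)
        self.validate()

    def validate(self) -> None:
        for name in ("frac_suppressing", "frac_promoting", "missing_rate", "assoc_gap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.frac_suppressing + self.frac_promoting > 1.0 + 1e-12:
            raise ConfigurationError("frac_suppressing + frac_promoting must be <= 1")
        lo, hi = self.effect_fold_range
        if lo < 1.0 or hi < lo:
            raise ConfigurationError("effect_fold_range must satisfy 1 <= low <= high")
        if self.n_svs > self.n_genes:
            raise ConfigurationError("n_svs must not exceed n_genes (one SV per gene)")
        if sum(self.morphotype_spec.values()) != self.n_accessions:
            raise ConfigurationError(
                f"morphotype_spec sums to {sum(self.morphotype_spec.values())}, "
                f"expected n_accessions={self.n_accessions}"
            )
        if self.exclusive_morphotype not in self.morphotype_spec:
            raise ConfigurationError(
                f"exclusive morphotype {self.exclusive_morphotype!r} not in spec"
            )
        if any(c < 0 for c in (self.n_genomes, self.n_accessions, self.n_genes, self.n_svs)):
            raise ConfigurationError("counts must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_fold_range"] = list(self.effect_fold_range)
        return d


@dataclass
class SyntheticBundle:
    """Everything a downstream analysis needs, plus the planted truth."""

    config: SimConfig
    genes: List[GeneModel]
    truth: pd.DataFrame
    catalog: SVCatalog
    panel_genotypes: GenotypeMatrix
    expression_panel: pd.DataFrame
    population_genotypes: Optional[GenotypeMatrix] = None
    expression_population: Optional[pd.DataFrame] = None
    methylation: Optional[pd.DataFrame] = None
    sv_sequences: Dict[str, str] = field(default_factory=dict)
    promoters: Dict[str, str] = field(default_factory=dict)
    motifs: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    te_intervals: Optional[pd.DataFrame] = None
    family_matrix: Optional[pd.DataFrame] = None
    family_meta: Optional[pd.DataFrame] = None


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


def _noise_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _background_seq(rng: np.random.Generator, length: int) -> str:
    """AT-leaning random DNA with CpG dinucleotides depleted."""
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length, p=[0.3, 0.2, 0.2, 0.3]))
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and rng.random() < 0.9:
            seq[i + 1] = "A"
    return "".join(seq)


def _island_seq(rng: np.random.Generator, length: int = 300) -> str:
    """CG-dense segment that satisfies the CpG-island criteria."""
    out: List[str] = []
    while len(out) < length:
        if rng.random() < 0.75:
            out.extend("CG")
        else:
            out.extend(rng.choice(list("GCAT"), size=2, p=[0.4, 0.4, 0.1, 0.1]))
    return "".join(out[:length])


def _instantiate_motif(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(list(IUPAC[ch])) for ch in consensus.upper())


def _sv_sequence(
    rng: np.random.Generator, direction: str, length: int, motifs: Mapping[str, str]
) -> str:
    seq = _background_seq(rng, length)
    if direction == "suppressing":
        island_len = min(300, max(200, length - 20))
        if length >= island_len:
            pos = int(rng.integers(0, length - island_len + 1))
            seq = seq[:pos] + _island_seq(rng, island_len) + seq[pos + island_len :]
    elif direction == "promoting":
        names = list(motifs)
        n_sites = max(3, length // 250)
        for _ in range(n_sites):
            site = _instantiate_motif(rng, motifs[names[int(rng.integers(len(names)))]])
            if len(site) >= length:
                continue
            pos = int(rng.integers(0, length - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site) :]
    return seq


# ---------------------------------------------------------------------------
# pan-genome generation
# ---------------------------------------------------------------------------

def _make_genes(config: SimConfig) -> List[GeneModel]:
    rng = _rng(config.seed, 0)
    genes: List[GeneModel] = []
    per_chrom = int(np.ceil(config.n_genes / N_CHROMS))
    gi = 0
    for c in range(N_CHROMS):
        chrom = f"chr{c + 1}"
        for slot in range(per_chrom):
            if gi >= config.n_genes:
                break
            start = slot * SLOT_BP + GENE_OFFSET
            length = int(rng.integers(*GENE_LEN_RANGE))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            b1 = start + int(0.25 * length)
            b2 = start + int(0.45 * length)
            b3 = start + int(0.70 * length)
            b4 = start + int(0.80 * length)
            exons = ((start, b1), (b2, b3), (b4, end))
            genes.append(
                GeneModel(
                    id=f"gene{gi:05d}", chrom=chrom, start=start, end=end,
                    strand=strand, exons=exons, cds=exons,
                )
            )
            gi += 1
    return genes


_FLANK_BIN_EDGES = {"0-1.5kb": (1, 1_500), "1.5-3kb": (1_501, 3_000),
                    "3-5kb": (3_001, 5_000), "5-10kb": (5_001, 10_000)}


def _place_sv(
    rng: np.random.Generator,
    gene: GeneModel,
    bin_label: str,
    is_insertion: bool,
    min_len: int = SV_LEN_RANGE[0],
) -> Tuple[int, int, int]:
    """Return (start, end, alt_length) for an SV in the requested bin.

    ``min_len`` raises the variable-sequence floor (suppressing SVs need
    room for a CpG island).
    """
    length = int(rng.integers(min_len, max(SV_LEN_RANGE[1], min_len + 1)))
    if bin_label in ("CDS", "intron"):
        if bin_label == "CDS":
            feats = list(gene.exons)
        else:
            feats = [
                (gene.exons[i][1], gene.exons[i + 1][0])
                for i in range(len(gene.exons) - 1)
            ]
        if is_insertion:
            f0, f1 = feats[int(rng.integers(len(feats)))]
            pos = int(rng.integers(f0 + 1, f1 - 1))
            return pos, pos, length
        # deletions must fit inside the feature: prefer ones with room
        roomy = [f for f in feats if (f[1] - f[0]) - 4 >= min_len] or [
            max(feats, key=lambda f: f[1] - f[0])
        ]
        f0, f1 = roomy[int(rng.integers(len(roomy)))]
        length = min(length, max(min_len, (f1 - f0) - 4))
        length = min(length, (f1 - f0) - 4)
        lo = int(rng.integers(f0 + 1, f1 - length - 1)) if f1 - length - 1 > f0 + 1 else f0 + 1
        return lo, lo + length, length
    d_lo, d_hi = _FLANK_BIN_EDGES[bin_label]
    d = int(rng.integers(d_lo, d_hi + 1))
    upstream = rng.random() < 0.5
    left = upstream if gene.strand == "+" else not upstream
    length = min(length, 11_000 - d - 50)
    if left and gene.start - d - length - 1 < 1:
        left = False  # first slot on the chromosome: keep coordinates positive
    if is_insertion:
        pos = gene.start - d - 1 if left else gene.end + d
        return pos, pos, length
    if left:
        hi = gene.start - d  # gap to the gene start == d
        return hi - length, hi, length
    lo = gene.end + d
    return lo, lo + length, length


def gen_pangenome(config: SimConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle for a configuration.

    Deterministic for a fixed seed.  Planted suppressing SVs divide the
    carrier-group mean TPM by their fold; promoting SVs multiply it;
    null SVs leave expression untouched.
    """
    config.validate()
    genes = _make_genes(config)
    rng = _rng(config.seed, 1)

    genome_ids = [f"G{i + 1:02d}" for i in range(config.n_genomes)]
    n_sup = int(round(config.frac_suppressing * config.n_svs))
    n_pro = int(round(config.frac_promoting * config.n_svs))
    directions = np.array(
        ["suppressing"] * n_sup
        + ["promoting"] * n_pro
        + ["none"] * (config.n_svs - n_sup - n_pro)
    )
    rng.shuffle(directions)
    lo_f, hi_f = config.effect_fold_range
    folds = np.where(
        directions == "none",
        1.0,
        np.exp(rng.uniform(np.log(lo_f), np.log(hi_f), size=config.n_svs)),
    )

    target_idx = rng.choice(config.n_genes, size=config.n_svs, replace=False)
    records: List[SVRecord] = []
    rows = []
    presence_panel = np.zeros((config.n_genomes, config.n_svs), dtype=np.int8)
    for i in range(config.n_svs):
        gene = genes[int(target_idx[i])]
        bin_label = DISTANCE_BINS[int(rng.integers(len(DISTANCE_BINS)))]
        is_ins = rng.random() < 0.5
        # suppressing SVs need room for a >=200 bp CpG island in their sequence
        min_len = 300 if directions[i] == "suppressing" else SV_LEN_RANGE[0]
        start, end, alt_len = _place_sv(rng, gene, bin_label, is_ins, min_len)
        sv_id = f"sv{i:04d}"
        sv_type = "presence-PAV" if is_ins else "absence-PAV"
        freq = rng.uniform(0.25, 0.75)
        pres = (rng.random(config.n_genomes) < freq).astype(np.int8)
        if pres.all():
            pres[int(rng.integers(config.n_genomes))] = 0
        if not pres.any():
            pres[int(rng.integers(config.n_genomes))] = 1
        presence_panel[:, i] = pres
        sources = frozenset(g for g, p in zip(genome_ids, pres) if p)
        records.append(
            SVRecord(
                id=sv_id, chrom=gene.chrom, start=start,
                end=start if is_ins else end, sv_type=sv_type,
                alt_length=alt_len if is_ins else end - start,
                source_genomes=sources,
            )
        )
        rows.append(
            (sv_id, gene.chrom, start, start if is_ins else end, sv_type,
             alt_len if is_ins else end - start, gene.id, bin_label,
             directions[i], float(folds[i]), None, False)
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "sv_id", "chrom", "start", "end", "sv_type", "alt_length",
            "gene_id", "bin", "direction", "fold", "assoc_morphotype", "exclusive",
        ],
    ).set_index("sv_id")

    # morphotype associations: the exclusive SV plus frequency-contrast SVs
    effect_ids = truth.index[truth["direction"] != "none"].tolist()
    assoc_morphs = [m for m in ("cauliflower", "cabbage", "broccoli", "kohlrabi")
                    if m in config.morphotype_spec]
    if effect_ids and config.n_assoc_svs >= 0:
        excl = effect_ids[0]
        truth.loc[excl, "assoc_morphotype"] = config.exclusive_morphotype
        truth.loc[excl, "exclusive"] = True
        others = effect_ids[1 : 1 + config.n_assoc_svs]
        for k, sv_id in enumerate(others):
            truth.loc[sv_id, "assoc_morphotype"] = assoc_morphs[k % len(assoc_morphs)]

    catalog = SVCatalog(records)
    panel_gm = GenotypeMatrix(
        pd.DataFrame(presence_panel, index=pd.Index(genome_ids, name="accession"),
                     columns=truth.index),
        pd.DataFrame(
            {"morphotype": [PANEL_MORPHOTYPES[i % len(PANEL_MORPHOTYPES)]
                            for i in range(config.n_genomes)]},
            index=pd.Index(genome_ids, name="accession"),
        ),
    )

    # sequences
    rng_seq = _rng(config.seed, 2)
    motifs = dict(DEFAULT_MOTIFS)
    sv_sequences = {
        sv_id: _sv_sequence(rng_seq, truth.at[sv_id, "direction"],
                            int(truth.at[sv_id, "alt_length"]), motifs)
        for sv_id in truth.index
    }
    promoters = {g.id: _background_seq(rng_seq, 1_000) for g in genes[: min(len(genes), 500)]}

    # panel expression: one leaf sample per assembled genome
    rng_exp = _rng(config.seed, 3)
    baselines = 10 ** rng_exp.uniform(0.7, 2.3, size=config.n_genes)
    sigma = _noise_sigma(config.noise_cv)
    gene_pos = {g.id: k for k, g in enumerate(genes)}
    expected = np.tile(baselines[:, None], (1, config.n_genomes))
    for i, sv_id in enumerate(truth.index):
        d = truth.at[sv_id, "direction"]
        if d == "none":
            continue
        gi = gene_pos[truth.at[sv_id, "gene_id"]]
        fold = truth.at[sv_id, "fold"]
        carriers = presence_panel[:, i] == 1
        expected[gi, carriers] *= fold if d == "promoting" else 1.0 / fold
    noise = np.exp(rng_exp.normal(-sigma * sigma / 2, sigma, size=expected.shape))
    expression_panel = pd.DataFrame(
        expected * noise,
        index=pd.Index([g.id for g in genes], name="gene_id"),
        columns=genome_ids,
    )

    # TE intervals: most spanned SVs overlap a TE, plus background TEs
    rng_te = _rng(config.seed, 6)
    te_rows = []
    for sv in records:
        if sv.ref_span > 0 and rng_te.random() < 0.75:
            pad = int(rng_te.integers(0, 200))
            te_rows.append((sv.chrom, max(0, sv.start - pad),
                            sv.start + max(1, sv.ref_span // 2)))
    for _ in range(max(1, config.n_svs // 2)):
        chrom = f"chr{int(rng_te.integers(N_CHROMS)) + 1}"
        lo = int(rng_te.integers(0, SLOT_BP * max(1, config.n_genes // N_CHROMS)))
        te_rows.append((chrom, lo, lo + int(rng_te.integers(100, 3_000))))
    te_intervals = pd.DataFrame(te_rows, columns=["chrom", "start", "end"])

    bundle = SyntheticBundle(
        config=config, genes=genes, truth=truth, catalog=catalog,
        panel_genotypes=panel_gm, expression_panel=expression_panel,
        sv_sequences=sv_sequences, promoters=promoters, motifs=motifs,
        te_intervals=te_intervals,
    )
    gen_population(bundle, config)
    gen_methylome(bundle, config)
    gen_family_matrix(bundle, config)
    return bundle


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def gen_population(
    bundle: SyntheticBundle, config: Optional[SimConfig] = None
) -> GenotypeMatrix:
    """Genotype the SVs in the accession population and simulate expression.

    Morphotype-associated SVs get a planted case/control carrier-frequency
    contrast of ``assoc_gap``; the exclusive SV is present in every
    accession of its morphotype and absent elsewhere.  Observed calls are
    masked to missing at ``missing_rate``; expression is driven by the
    true (unmasked) genotype.
    """
    config = config or bundle.config
    rng = _rng(config.seed, 4)
    morphs: List[str] = []
    for m, count in config.morphotype_spec.items():
        morphs.extend([m] * count)
    accession_ids = [f"acc{i + 1:04d}" for i in range(config.n_accessions)]
    morph_arr = np.array(morphs)

    truth = bundle.truth
    n_svs = len(truth)
    true_calls = np.zeros((config.n_accessions, n_svs), dtype=np.int8)
    for i, sv_id in enumerate(truth.index):
        assoc = truth.at[sv_id, "assoc_morphotype"]
        if truth.at[sv_id, "exclusive"]:
            true_calls[:, i] = (morph_arr == assoc).astype(np.int8)
        elif assoc is not None and not (isinstance(assoc, float) and np.isnan(assoc)):
            hi = min(0.95, 0.1 + config.assoc_gap)
            freq = np.where(morph_arr == assoc, hi, hi - config.assoc_gap)
            true_calls[:, i] = (rng.random(config.n_accessions) < freq).astype(np.int8)
        else:
            freq = rng.uniform(0.1, 0.9)
            true_calls[:, i] = (rng.random(config.n_accessions) < freq).astype(np.int8)

    observed = true_calls.copy()
    if config.missing_rate > 0:
        mask = rng.random(observed.shape) < config.missing_rate
        observed[mask] = MISSING

    metadata = pd.DataFrame(
        {"morphotype": morphs, "lineage": [LINEAGE.get(m, "wild") for m in morphs]},
        index=pd.Index(accession_ids, name="accession"),
    )
    gm = GenotypeMatrix(
        pd.DataFrame(observed, index=metadata.index, columns=truth.index), metadata
    )

    # population expression from the true genotypes
    baselines = 10 ** _rng(config.seed, 3).uniform(0.7, 2.3, size=config.n_genes)
    sigma = _noise_sigma(config.noise_cv)
    gene_ids = [g.id for g in bundle.genes]
    gene_pos = {gid: k for k, gid in enumerate(gene_ids)}
    expected = np.tile(baselines[:, None], (1, config.n_accessions))
    for i, sv_id in enumerate(truth.index):
        d = truth.at[sv_id, "direction"]
        if d == "none":
            continue
        gi = gene_pos[truth.at[sv_id, "gene_id"]]
        fold = truth.at[sv_id, "fold"]
        carriers = true_calls[:, i] == 1
        expected[gi, carriers] *= fold if d == "promoting" else 1.0 / fold
    noise = np.exp(rng.normal(-sigma * sigma / 2, sigma, size=expected.shape))
    bundle.expression_population = pd.DataFrame(
        expected * noise, index=pd.Index(gene_ids, name="gene_id"), columns=accession_ids
    )
    bundle.population_genotypes = gm
    return gm


# ---------------------------------------------------------------------------
# methylome generation
# ---------------------------------------------------------------------------

def gen_methylome(
    bundle: SyntheticBundle,
    config: Optional[SimConfig] = None,
    mean_depth: int = MEAN_CPG_DEPTH,
) -> pd.DataFrame:
    """Per-CpG methylation counts over the SV sequences.

    CpG sites inside the planted islands of suppressing SVs draw their
    methylated-read fraction around 0.9; all other sites around 0.1.
    Read depth is Poisson with the given mean.  Site coordinates are in
    SV-sequence space with the SV id as the chrom key.
    """
    config = config or bundle.config
    rng = _rng(config.seed, 5)
    rows = []
    for sv_id, seq in bundle.sv_sequences.items():
        cpg_pos = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        if not cpg_pos:
            continue
        direction = bundle.truth.at[sv_id, "direction"]
        islands = detect_cpg_islands(seq) if direction == "suppressing" else []
        for p in cpg_pos:
            in_island = any(isl.start <= p < isl.end for isl in islands)
            target = ISLAND_METH_TARGET if in_island else BACKGROUND_METH
            level = float(np.clip(rng.normal(target, 0.03), 0.0, 1.0))
            depth = int(rng.poisson(mean_depth))
            meth = int(rng.binomial(depth, level)) if depth > 0 else 0
            rows.append((sv_id, p, meth, depth))
    meth = pd.DataFrame(rows, columns=["chrom", "pos", "methylated", "total"])
    bundle.methylation = meth
    return meth


# ---------------------------------------------------------------------------
# family matrix generation
# ---------------------------------------------------------------------------

FAMILY_CLASS_FRACS = {"core": 0.232, "softcore": 0.115, "dispensable": 0.632, "private": 0.021}


def gen_family_matrix(
    bundle: SyntheticBundle,
    config: Optional[SimConfig] = None,
    n_families: int = 600,
) -> pd.DataFrame:
    """Syntenic-family copy counts with a planted pan-class composition
    and homoeolog triplets linked across the three subgenomes."""
    config = config or bundle.config
    rng = _rng(config.seed, 7)
    n = config.n_genomes
    genome_ids = list(bundle.panel_genotypes.accessions)
    soft_lo = int(np.ceil(0.90 * n))
    classes = []
    for cls, frac in FAMILY_CLASS_FRACS.items():
        classes.extend([cls] * int(round(frac * n_families)))
    classes = classes[:n_families] + ["dispensable"] * (n_families - len(classes))
    counts = np.zeros((n_families, n), dtype=int)
    for i, cls in enumerate(classes):
        if cls == "core":
            k = n
        elif cls == "softcore":
            k = int(rng.integers(soft_lo, n))
        elif cls == "private":
            k = 1
        else:
            k = int(rng.integers(2, soft_lo))
        present = rng.choice(n, size=k, replace=False)
        counts[i, present] = rng.integers(1, 3, size=k)
    fam_ids = [f"fam{i:05d}" for i in range(n_families)]
    subgenomes = [("LF", "MF1", "MF2")[i % 3] for i in range(n_families)]
    triplet_ids: List[Optional[str]] = [None] * n_families
    for t in range(n_families // 6):
        for j in range(3):
            triplet_ids[3 * t + j] = f"trip{t:04d}"
    fm = pd.DataFrame(counts, index=pd.Index(fam_ids, name="family_id"), columns=genome_ids)
    meta = pd.DataFrame(
        {"subgenome": subgenomes, "triplet_id": triplet_ids}, index=fm.index
    )
    bundle.family_matrix = fm
    bundle.family_meta = meta
    return fm


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the complete fixture directory in standard formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "sim_config.yaml").write_text(yaml.safe_dump(bundle.config.to_dict()))
    svio.write_gff3(out / "genes.gff3", bundle.genes)
    svio.write_sv_vcf(out / "svs_panel.vcf", bundle.catalog, bundle.panel_genotypes)
    svio.write_expression(out / "expression_panel.tsv", bundle.expression_panel)
    if bundle.population_genotypes is not None:
        svio.write_sv_vcf(out / "svs_population.vcf", bundle.catalog, bundle.population_genotypes)
        svio.write_metadata(out / "accessions.tsv", bundle.population_genotypes.metadata)
    if bundle.expression_population is not None:
        svio.write_expression(out / "expression_population.tsv", bundle.expression_population)
    if bundle.methylation is not None:
        svio.write_methylation(out / "methylation.tsv", bundle.methylation)
    svio.write_fasta(out / "sv_sequences.fasta", bundle.sv_sequences)
    svio.write_fasta(out / "promoters.fasta", bundle.promoters)
    svio.write_motifs(out / "motifs.tsv", bundle.motifs)
    if bundle.te_intervals is not None:
        svio.write_bed(out / "te.bed", bundle.te_intervals)
    if bundle.family_matrix is not None:
        svio.write_family_matrix(out / "families.tsv", bundle.family_matrix, bundle.family_meta)
    truth = bundle.truth.copy()
    truth.to_csv(out / "truth.tsv", sep="\t")
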