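"""Readers and writers for every on-disk format the pipeline touches.

VCF (pysam), GFF3 (gffutils), FASTA (Biopython) and TSV tables (pandas).
External files follow the conventions of their formats (VCF/GFF3 are
1-based); everything in memory is 0-based half-open.  Genotypes in VCFs
are stored per accession as 0/0, 1/1 or ./. against the reference allele;
on read they are binarized and oriented so that the longer allele is
"presence", independent of which genome served as reference.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import gffutils

from .models import (
    ABSENCE,
    MISSING,
    PRESENCE,
    GeneModel,
    GenotypeMatrix,
    SVCatalog,
    SVRecord,
    SVTYPE_TO_SYMBOL,
    SYMBOL_TO_SVTYPE,
)

logger = logging.getLogger("svdosage")

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A format-level problem in an input file."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header_lines(catalog: SVCatalog, samples: List[str]) -> List[str]:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=svdosage",
        "##coordinates=VCF 1-based; internal representation 0-based half-open",
        '##ALT=<ID=INS,Description="Insertion (presence-PAV)">',
        '##ALT=<ID=DEL,Description="Deletion (absence-PAV)">',
        '##ALT=<ID=DUP,Description="Copy-number gain (CNV)">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=TRA,Description="Translocation">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Half-open end on the reference (POS for insertions)">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Alternate allele length in bp">',
        '##INFO=<ID=SOURCES,Number=.,Type=String,Description="Panel genomes carrying the variant">',
        '##INFO=<ID=TEFRAC,Number=1,Type=String,Description="Fraction of reference span overlapping TEs (exact decimal)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    extent: Dict[str, int] = {}
    for rec in catalog:
        extent[rec.chrom] = max(extent.get(rec.chrom, 0), rec.end + rec.alt_length + 1)
    for chrom, length in extent.items():
        lines.append(f"##contig=<ID={chrom},length={length + 10_000}>")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT"] + samples
    lines.append("\t".join(cols))
    return lines


def _alt_is_longer(sv_type: str) -> bool:
    """Whether the alternate allele is the longer ('presence') allele."""
    return sv_type in ("presence-PAV", "CNV")


def write_sv_vcf(
    path: PathLike,
    catalog: SVCatalog,
    genotypes: Optional[GenotypeMatrix] = None,
) -> None:
    """Write a catalog (and optional oriented genotypes) as VCFv4.2.

    The record body is emitted directly rather than through htslib's
    writer, which silently re-derives END from SVLEN under the
    padding-base convention and would shift deletion ends by one.
    """
    samples = [str(s) for s in genotypes.accessions] if genotypes is not None else []
    lines = _vcf_header_lines(catalog, samples)
    for sv in catalog:
        pos = sv.start + 1
        end = sv.end if sv.end > sv.start else pos
        info = (
            f"SVTYPE={SVTYPE_TO_SYMBOL[sv.sv_type]};END={end};SVLEN={sv.alt_length}"
        )
        if sv.source_genomes:
            info += f";SOURCES={','.join(sorted(sv.source_genomes))}"
        info += f";TEFRAC={float(sv.te_overlap_fraction)!r}"
        fields = [
            sv.chrom, str(pos), sv.id, "N",
            f"<{SVTYPE_TO_SYMBOL[sv.sv_type]}>", ".", ".", info,
        ]
        if samples:
            alt_presence = _alt_is_longer(sv.sv_type)
            col = genotypes.calls[sv.id]
            fields.append("GT")
            for acc, call in zip(genotypes.accessions, col):
                if call == MISSING:
                    fields.append("./.")
                elif (call == PRESENCE) == alt_presence:
                    fields.append("1/1")
                else:
                    fields.append("0/0")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sv_vcf(path: PathLike) -> Tuple[SVCatalog, Optional[GenotypeMatrix]]:
    """Parse a structural-variant VCF into a catalog and oriented genotypes.

    Raises :class:`ParseError` naming the offending record when a symbolic
    allele lacks SVLEN.
    """
    records: List[SVRecord] = []
    calls: Dict[str, np.ndarray] = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for lineno, rec in enumerate(vf, start=1):
            alt = rec.alts[0] if rec.alts else ""
            symbolic = alt.startswith("<")
            symbol = rec.info.get("SVTYPE") or (alt.strip("<>") if symbolic else None)
            if symbol is None or symbol not in SYMBOL_TO_SVTYPE:
                raise ParseError(
                    f"{path}: record {lineno} ({rec.chrom}:{rec.pos}): "
                    f"unrecognized SV type {symbol!r}"
                )
            if "SVLEN" not in rec.info:
                if symbolic:
                    raise ParseError(
                        f"{path}: record {lineno} ({rec.chrom}:{rec.pos}): "
                        "symbolic allele without SVLEN"
                    )
                svlen = abs(len(alt) - len(rec.ref))
            else:
                svlen = rec.info["SVLEN"]
                if isinstance(svlen, tuple):
                    svlen = svlen[0]
                svlen = abs(int(svlen))
            sv_type = SYMBOL_TO_SVTYPE[symbol]
            # POS is the first affected base; for spanned SVs the reference
            # span equals SVLEN, so the half-open end is derived from it
            # (htslib's computed stop is convention-dependent and unreliable
            # when both END and SVLEN are present)
            start = rec.start
            end = start if symbol == "INS" else start + svlen
            try:  # optional annotations; absent from externally produced VCFs
                sources = rec.info.get("SOURCES", ())
            except ValueError:
                sources = ()
            if isinstance(sources, str):
                sources = (sources,)
            source_set = frozenset(g for part in sources for g in part.split(",") if g)
            try:
                tefrac = float(rec.info.get("TEFRAC", "0.0"))
            except ValueError:
                tefrac = 0.0
            sv = SVRecord(
                id=rec.id or f"sv{lineno}",
                chrom=rec.chrom,
                start=start,
                end=end,
                sv_type=sv_type,
                alt_length=int(svlen),
                source_genomes=source_set,
                te_overlap_fraction=tefrac,
            )
            records.append(sv)
            if samples:
                alt_presence = _alt_is_longer(sv_type)
                col = np.empty(len(samples), dtype=np.int8)
                for i, s in enumerate(samples):
                    gt = rec.samples[s].get("GT", (None,))
                    if gt is None or all(a is None for a in gt):
                        col[i] = MISSING
                    else:
                        carries_alt = any(a not in (0, None) for a in gt)
                        col[i] = PRESENCE if carries_alt == alt_presence else ABSENCE
                calls[sv.id] = col
    catalog = SVCatalog(records)
    gm = None
    if calls:
        gm = GenotypeMatrix(pd.DataFrame(calls, index=pd.Index(samples, name="accession")))
    return catalog, gm


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(path: PathLike, genes: Iterable[GeneModel], source: str = "svdosage") -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.id)):
        # GFF3 is 1-based inclusive
        lines.append(
            f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}"
        )
        mrna = f"{g.id}.t1"
        lines.append(
            f"{g.chrom}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.id}"
        )
        for lo, hi in g.exons:
            lines.append(
                f"{g.chrom}\t{source}\texon\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tParent={mrna}"
            )
        for lo, hi in g.cds:
            lines.append(
                f"{g.chrom}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t{g.strand}\t0\tParent={mrna}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: PathLike) -> List[GeneModel]:
    """Parse gene models (gene/mRNA/exon/CDS) from GFF3 via gffutils."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        cds = []
        for mrna in db.children(g, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
            for c in db.children(mrna, featuretype="CDS"):
                cds.append((c.start - 1, c.end))
        # also accept exons/CDS attached directly to the gene
        for ex in db.children(g, featuretype="exon", level=1):
            exons.append((ex.start - 1, ex.end))
        for c in db.children(g, featuretype="CDS", level=1):
            cds.append((c.start - 1, c.end))
        gene = GeneModel(
            id=g.id,
            chrom=g.seqid,
            start=g.start - 1,
            end=g.end,
            strand=g.strand if g.strand in ("+", "-") else "+",
            exons=tuple(sorted(set(exons))),
            cds=tuple(sorted(set(cds))),
        )
        genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_expression(path: PathLike) -> pd.DataFrame:
    """Genes x samples TPM matrix; duplicate gene ids and non-numeric cells rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated gene ids {dups[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            bad = df.index[coerced.isna() & df[col].notna()][0]
            raise ParseError(f"{path}: non-numeric TPM at gene {bad!r}, sample {col!r}")
        df[col] = coerced
    df.index.name = "gene_id"
    return df


def write_expression(path: PathLike, expr: pd.DataFrame) -> None:
    out = expr.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_methylation(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "methylated", "total"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: methylation table needs columns {sorted(required)}")
    if (df["methylated"] > df["total"]).any():
        raise ParseError(f"{path}: methylated reads exceed total reads")
    return df


def write_methylation(path: PathLike, sites: pd.DataFrame) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_metadata(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "morphotype" not in df.columns:
        raise ParseError(f"{path}: metadata needs a 'morphotype' column")
    df.index.name = "accession"
    return df


def write_metadata(path: PathLike, meta: pd.DataFrame) -> None:
    out = meta.copy()
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def read_motifs(path: PathLike) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "consensus"}.issubset(df.columns):
        raise ParseError(f"{path}: motif table needs 'name' and 'consensus' columns")
    return dict(zip(df["name"], df["consensus"]))


def write_motifs(path: PathLike, motifs: Dict[str, str]) -> None:
    pd.DataFrame({"name": list(motifs), "consensus": list(motifs.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_family_matrix(path: PathLike) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Family x genome copy counts plus (subgenome, triplet_id) metadata."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicated family ids")
    meta_cols = [c for c in ("subgenome", "triplet_id") if c in df.columns]
    meta = df[meta_cols].copy() if meta_cols else pd.DataFrame(index=df.index)
    counts = df.drop(columns=meta_cols)
    counts = counts.astype(int)
    if (counts.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative copy counts")
    counts.index.name = "family_id"
    return counts, meta


def write_family_matrix(
    path: PathLike, counts: pd.DataFrame, meta: Optional[pd.DataFrame] = None
) -> None:
    out = counts.copy()
    if meta is not None and len(meta.columns):
        out = pd.concat([meta, counts], axis=1)
    out.index.name = "family_id"
    out.to_csv(path, sep="\t")


def read_bed(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    if (df["end"] < df["start"]).any():
        raise ParseError(f"{path}: BED interval with end < start")
    return df


def write_bed(path: PathLike, intervals: pd.DataFrame) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, seqs: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------

def log_stage(stage: str, config_digest: str = "-", **fields) -> None:
    """One structured log line per pipeline stage."""
    parts = [f"stage={stage}", f"config={config_digest}"]
    parts += [f"{k}={v}" for k, v in fields.items()]
    logger.info(" ".join(parts))
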