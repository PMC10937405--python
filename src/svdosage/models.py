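"""Core in-memory containers shared across the pipeline.

Coordinates are uniformly 0-based half-open; insertions are zero-span
reference intervals whose variable sequence lives in ``alt_length`` /
``sequence``.  Genotype calls are accession-level presence/absence of the
longer ("presence") allele, never allele dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

#: genotype codes used throughout the package
PRESENCE = 1
ABSENCE = 0
MISSING = -1

#: recognized SV classes and their VCF symbolic alleles
SV_TYPES = ("presence-PAV", "absence-PAV", "CNV", "inversion", "translocation")
SVTYPE_TO_SYMBOL = {
    "presence-PAV": "INS",
    "absence-PAV": "DEL",
    "CNV": "DUP",
    "inversion": "INV",
    "translocation": "TRA",
}
SYMBOL_TO_SVTYPE = {v: k for k, v in SVTYPE_TO_SYMBOL.items()}


@dataclass(frozen=True)
class SVRecord:
    """One structural variant on the reference.

    ``start``/``end`` delimit the reference span (equal for insertions);
    ``alt_length`` is the length of the alternate (non-reference) sequence,
    so ``span`` — the amount of sequence that differs between the two
    alleles — is ``max(end - start, alt_length)``.
    """

    id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    alt_length: int = 0
    source_genomes: frozenset = frozenset()
    te_overlap_fraction: float = 0.0
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.end < self.start:
            raise ValueError(f"{self.id}: end < start")
        if not 0.0 <= self.te_overlap_fraction <= 1.0:
            raise ValueError(f"{self.id}: te_overlap_fraction outside [0,1]")

    @property
    def ref_span(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> int:
        return max(self.ref_span, self.alt_length)

    @property
    def is_insertion(self) -> bool:
        return self.ref_span == 0

    def with_te_fraction(self, frac: float) -> "SVRecord":
        return replace(self, te_overlap_fraction=frac)


class SVCatalog:
    """An ordered collection of :class:`SVRecord` on one reference."""

    def __init__(self, records: Iterable[SVRecord], reference: str = "ref"):
        self.records = list(records)
        self.reference = reference
        self._by_id = {r.id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate SV ids in catalog")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def __getitem__(self, sv_id: str) -> SVRecord:
        return self._by_id[sv_id]

    def __contains__(self, sv_id: str) -> bool:
        return sv_id in self._by_id

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SVCatalog) and self.records == other.records

    def ids(self) -> list:
        return [r.id for r in self.records]

    def chroms(self) -> list:
        seen: dict = {}
        for r in self.records:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sv_id": [r.id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "start": [r.start for r in self.records],
                "end": [r.end for r in self.records],
                "sv_type": [r.sv_type for r in self.records],
                "alt_length": [r.alt_length for r in self.records],
                "n_source_genomes": [len(r.source_genomes) for r in self.records],
                "te_overlap_fraction": [r.te_overlap_fraction for r in self.records],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, body interval and exon/CDS structure."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = ()
    cds: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        for lo, hi in self.cds:
            if lo < self.start or hi > self.end:
                raise ValueError(f"{self.id}: CDS [{lo},{hi}) outside gene span")

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware)."""
        return self.start if self.strand == "+" else self.end


class GenotypeMatrix:
    """Accessions x SVs presence/absence/missing calls plus metadata.

    ``calls`` is an int8 DataFrame (index = accession ids, columns = SV ids)
    with values PRESENCE/ABSENCE/MISSING.  ``metadata`` is indexed by
    accession and carries at least a ``morphotype`` column.
    """

    def __init__(self, calls: pd.DataFrame, metadata: Optional[pd.DataFrame] = None):
        if calls.size:
            bad = ~calls.isin([PRESENCE, ABSENCE, MISSING]).to_numpy(dtype=bool)
            if bad.any():
                raise ValueError("genotype calls must be in {1, 0, -1}")
        self.calls = calls.astype("int8")
        if metadata is None:
            metadata = pd.DataFrame(index=calls.index)
        if not calls.index.equals(metadata.index):
            metadata = metadata.reindex(calls.index)
        self.metadata = metadata

    @property
    def accessions(self) -> pd.Index:
        return self.calls.index

    @property
    def sv_ids(self) -> pd.Index:
        return self.calls.columns

    def morphotypes(self) -> pd.Series:
        if "morphotype" not in self.metadata.columns:
            raise KeyError("metadata has no 'morphotype' column")
        return self.metadata["morphotype"]

    def non_missing(self, sv_id: str) -> pd.Series:
        col = self.calls[sv_id]
        return col[col != MISSING]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.calls.equals(other.calls)
            and self.metadata.equals(other.metadata)
        )


@dataclass(frozen=True)
class SVGeneLink:
    """An SV assigned to its closest gene within the linking radius."""

    sv_id: str
    gene_id: str
    distance: int  # signed, strand-aware: negative upstream, 0 overlapping
    bin: str  # one of DISTANCE_BINS

    def __post_init__(self) -> None:
        if self.bin not in DISTANCE_BINS:
            raise ValueError(f"unknown distance bin {self.bin!r}")


DISTANCE_BINS = ("CDS", "intron", "0-1.5kb", "1.5-3kb", "3-5kb", "5-10kb")


@dataclass(frozen=True)
class DosageCall:
    """Direction call for one SV-gene pair."""

    sv_id: str
    gene_id: str
    n_presence: int
    n_absence: int
    mean_tpm_presence: float
    mean_tpm_absence: float
    fold_ratio: float  # presence / absence; inf when absence mean is zero
    direction: str  # suppressing | promoting | none
    mode: str  # panel | population
    p_value: Optional[float] = None
    bin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in ("suppressing", "promoting", "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.mode not in ("panel", "population"):
            raise ValueError(f"bad mode {self.mode!r}")


class EligibilityError(Exception):
    """Raised when an SV-gene pair fails the stated eligibility filters."""


@dataclass(frozen=True)
class SaturationFit:
    """Fit of the pan-SV accumulation curve P(n) = A - B*exp(-n/C)."""

    A: float
    B: float
    C: float
    predicted_total: float
    predicted_se: float


def calls_to_dataframe(calls: Sequence[DosageCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sv_id": [c.sv_id for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "bin": [c.bin for c in calls],
            "n_presence": [c.n_presence for c in calls],
            "n_absence": [c.n_absence for c in calls],
            "mean_tpm_presence": [c.mean_tpm_presence for c in calls],
            "mean_tpm_absence": [c.mean_tpm_absence for c in calls],
            "fold_ratio": [c.fold_ratio for c in calls],
            "direction": [c.direction for c in calls],
            "p_value": [c.p_value for c in calls],
            "mode": [c.mode for c in calls],
        }
    )
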