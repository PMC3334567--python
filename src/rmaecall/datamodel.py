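"""Domain types for allele-specific expression calling from SNP genotype arrays.

The experimental design: clonal cell lines derived from F1 hybrid mice are
hybridized to a SNP genotyping array twice — once with genomic DNA (gDNA) and
twice with double-stranded cDNA made from nuclear RNA ("transcriptome
genotypes"). At a SNP called heterozygous in gDNA, a homozygous cDNA call is
evidence that only one allele is transcribed. Alleles are abstract array
channels A/B; a per-SNP map assigns each channel to the maternal or paternal
haplotype of the cross.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional


class RmaecallError(Exception):
    """Base class for all package errors."""


class ParseError(RmaecallError):
    """Malformed input row; carries the 1-based line number when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(RmaecallError):
    """Duplicate or self-contradictory records."""


class ValidationError(RmaecallError):
    """Structurally valid input violating a design invariant."""


class UndefinedEvidenceError(RmaecallError):
    """A score was requested for a gene/clone with no informative data."""


class Call(str, enum.Enum):
    """A genotype call emitted by the array-calling algorithm."""

    AA = "AA"
    AB = "AB"
    BB = "BB"
    NOCALL = "NoCall"

    @property
    def is_hom(self) -> bool:
        return self in (Call.AA, Call.BB)


class Parent(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"

    @property
    def other(self) -> "Parent":
        return Parent.PATERNAL if self is Parent.MATERNAL else Parent.MATERNAL


class AllelicState(str, enum.Enum):
    """Consensus allelic expression state of a SNP (or gene) in one clone."""

    MONO_MATERNAL = "MonoMaternal"
    MONO_PATERNAL = "MonoPaternal"
    BIALLELIC = "Biallelic"
    UNINFORMATIVE = "Uninformative"

    @property
    def is_mono(self) -> bool:
        return self in (AllelicState.MONO_MATERNAL, AllelicState.MONO_PATERNAL)

    @property
    def parent(self) -> Optional[Parent]:
        if self is AllelicState.MONO_MATERNAL:
            return Parent.MATERNAL
        if self is AllelicState.MONO_PATERNAL:
            return Parent.PATERNAL
        return None


#: Single-character tokens used in per-clone state serializations.
STATE_TOKEN = {
    AllelicState.MONO_MATERNAL: "M",
    AllelicState.MONO_PATERNAL: "P",
    AllelicState.BIALLELIC: "B",
    AllelicState.UNINFORMATIVE: "·",
}


@dataclass(frozen=True)
class GenotypeCall:
    """A call plus its confidence score (lower = more confident, per the
    array-genotyping convention); NoCall carries no confidence."""

    call: Call
    confidence: Optional[float] = None

    def __post_init__(self):
        if self.call is not Call.NOCALL:
            if self.confidence is None:
                raise ValidationError(f"{self.call.value} call requires a confidence")
            if not (0.0 <= self.confidence <= 1.0):
                raise ValidationError(f"confidence {self.confidence} outside [0, 1]")


NOCALL = GenotypeCall(Call.NOCALL)


@dataclass(frozen=True)
class ArrayMeta:
    array_id: str
    line_id: str
    line_kind: str  # "clonal" | "nonclonal"
    material: str  # "gDNA" | "cDNA"
    replicate_index: int = 1
    cross_id: str = "cross1"
    sex: str = "unknown"  # "F" | "M" | "unknown"

    def __post_init__(self):
        if self.line_kind not in ("clonal", "nonclonal"):
            raise ValidationError(f"unknown line_kind {self.line_kind!r}")
        if self.material not in ("gDNA", "cDNA"):
            raise ValidationError(f"unknown material {self.material!r}")
        if self.sex not in ("F", "M", "unknown"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")


@dataclass
class CallMatrix:
    """Genotype calls indexed by (snp_id, array_id); absent pairs read NoCall.

    A valid analysis set has exactly one non-clonal line, at least two clonal
    lines, and for every line one gDNA array plus two replicate cDNA arrays.
    """

    arrays: list[ArrayMeta]
    snps: list[str]
    calls: dict[tuple[str, str], GenotypeCall] = field(default_factory=dict)

    def get(self, snp_id: str, array_id: str) -> GenotypeCall:
        return self.calls.get((snp_id, array_id), NOCALL)

    def set(self, snp_id: str, array_id: str, call: GenotypeCall) -> None:
        self.calls[(snp_id, array_id)] = call

    # -- metadata accessors -------------------------------------------------

    @property
    def line_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.arrays:
            seen.setdefault(a.line_id, None)
        return list(seen)

    @property
    def clonal_line_ids(self) -> list[str]:
        return [l for l in self.line_ids if self.line_meta(l).line_kind == "clonal"]

    @property
    def nonclonal_line_id(self) -> str:
        ids = [l for l in self.line_ids if self.line_meta(l).line_kind == "nonclonal"]
        if len(ids) != 1:
            raise ValidationError(
                f"analysis set must contain exactly one non-clonal line, found {len(ids)}"
            )
        return ids[0]

    def line_meta(self, line_id: str) -> ArrayMeta:
        for a in self.arrays:
            if a.line_id == line_id:
                return a
        raise KeyError(line_id)

    def gdna_array(self, line_id: str) -> ArrayMeta:
        hits = [a for a in self.arrays if a.line_id == line_id and a.material == "gDNA"]
        if not hits:
            raise ValidationError(f"line {line_id!r} has no gDNA array")
        return hits[0]

    def cdna_arrays(self, line_id: str) -> list[ArrayMeta]:
        hits = [a for a in self.arrays if a.line_id == line_id and a.material == "cDNA"]
        return sorted(hits, key=lambda a: a.replicate_index)

    def all_cdna_arrays(self) -> list[ArrayMeta]:
        return [a for a in self.arrays if a.material == "cDNA"]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Enforce analysis-set cardinality: per line 1 gDNA + 2 cDNA
        replicates; exactly one non-clonal line; >= 2 clonal lines."""
        ids = [a.array_id for a in self.arrays]
        if len(ids) != len(set(ids)):
            raise IntegrityError("duplicate array_id in metadata")
        for line_id in self.line_ids:
            n_g = len([a for a in self.arrays
                       if a.line_id == line_id and a.material == "gDNA"])
            n_c = len(self.cdna_arrays(line_id))
            if n_g != 1:
                raise ValidationError(
                    f"line {line_id!r}: expected exactly 1 gDNA array, found {n_g}"
                )
            if n_c != 2:
                raise ValidationError(
                    f"line {line_id!r}: expected exactly 2 cDNA replicate arrays, found {n_c}"
                )
        n_nonclonal = len([l for l in self.line_ids
                           if self.line_meta(l).line_kind == "nonclonal"])
        if n_nonclonal != 1:
            raise ValidationError(
                f"analysis set must contain exactly one non-clonal line, found {n_nonclonal}"
            )
        n_clonal = len(self.clonal_line_ids)
        if n_clonal < 2:
            raise ValidationError(
                f"analysis set requires at least two clonal lines, found {n_clonal}"
            )


@dataclass(frozen=True)
class SnpAnnotation:
    """A SNP's genomic placement plus its allele-channel → parent map."""

    snp_id: str
    chromosome: str
    position: int  # 0-based
    gene_id: Optional[str]  # None = intergenic
    context: str  # "exon" | "intron" | "intergenic"
    allele_A_parent: Parent
    allele_B_parent: Parent

    def __post_init__(self):
        if self.allele_A_parent == self.allele_B_parent:
            raise ValidationError(
                f"SNP {self.snp_id}: allele A and allele B map to the same parent"
            )
        if self.context not in ("exon", "intron", "intergenic"):
            raise ValidationError(f"unknown context {self.context!r}")
        if self.context != "intergenic" and self.gene_id is None:
            raise ValidationError(f"genic SNP {self.snp_id} lacks a gene_id")

    def swapped(self) -> "SnpAnnotation":
        """Annotation with the allele→parent map flipped (cross orientation)."""
        return SnpAnnotation(
            self.snp_id, self.chromosome, self.position, self.gene_id,
            self.context, self.allele_B_parent, self.allele_A_parent,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(f"gene {self.gene_id}: start must be < end")


@dataclass
class OrthologMap:
    """One-to-one ortholog pairs between two species."""

    pairs: list[tuple[str, str]]

    def __post_init__(self):
        g1 = [a for a, _ in self.pairs]
        g2 = [b for _, b in self.pairs]
        if len(g1) != len(set(g1)) or len(g2) != len(set(g2)):
            raise IntegrityError("ortholog map is not one-to-one")


def annotation_index(annotations: Iterable[SnpAnnotation]) -> dict[str, SnpAnnotation]:
    idx: dict[str, SnpAnnotation] = {}
    for ann in annotations:
        if ann.snp_id in idx:
            raise IntegrityError(f"duplicate SNP annotation {ann.snp_id}")
        idx[ann.snp_id] = ann
    return idx
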