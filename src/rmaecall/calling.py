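"""The filter cascade turning raw genotype calls into per-SNP, per-clone
allelic states.

A SNP reports monoallelic expression in a clone when the clone's gDNA is
robustly heterozygous but the cDNA consensus is homozygous. Before that
comparison the data pass four filters: (i) agreement between the two cDNA
replicate hybridizations, (ii) a stringent confidence-score threshold on every
call, (iii) evidence that the array can detect both alleles of the SNP in cDNA
somewhere in the analysis set, and (iv) the non-clonal control — the pooled
non-clonal line's cDNA must read biallelic or NoCall at the SNP, which screens
out imprinting, strong cis-acting skew, and annotation or loss-of-
heterozygosity artifacts (cell-autonomous random choice averages out in a
polyclonal pool; parent- or haplotype-fixed expression does not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .datamodel import (
    AllelicState,
    Call,
    CallMatrix,
    GenotypeCall,
    NOCALL,
    SnpAnnotation,
    ValidationError,
    annotation_index,
)


@dataclass(frozen=True)
class FilterConfig:
    """Tunable filter parameters.

    confidence_threshold: calls with confidence above this are discarded
        (lower confidence score = better call).
    require_replicate_agreement: when True a single passing replicate is not
        enough; both cDNA replicates must agree.
    min_informative_clones_for_bae: minimum informative clones for a gene with
        no monoallelic evidence to be classified as biallelic.
    """

    confidence_threshold: float = 0.05
    require_replicate_agreement: bool = True
    nonclonal_rule: str = "biallelic_or_nocall"
    min_informative_clones_for_bae: int = 2

    def __post_init__(self):
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValidationError("confidence_threshold outside [0, 1]")
        if self.min_informative_clones_for_bae < 2:
            raise ValidationError("min_informative_clones_for_bae must be >= 2")
        if self.nonclonal_rule != "biallelic_or_nocall":
            raise ValidationError(f"unknown nonclonal_rule {self.nonclonal_rule!r}")

    def passes(self, g: GenotypeCall) -> bool:
        """A usable call: non-NoCall with confidence at or below threshold."""
        return g.call is not Call.NOCALL and g.confidence <= self.confidence_threshold


@dataclass(frozen=True)
class ConsensusCall:
    """Replicate-consensus cDNA call; ``filtered`` marks replicate discordance
    (two confident calls that disagree), as opposed to plain missingness."""

    call: Call
    filtered: bool = False


@dataclass(frozen=True)
class SnpCloneState:
    snp_id: str
    line_id: str
    state: AllelicState
    provenance: str  # het_gdna_hom_cdna | het_gdna_het_cdna | filtered | nocall


@dataclass
class AllelicStateTable:
    """Per-SNP and aggregated per-gene allelic states across lines."""

    snp_states: list[SnpCloneState]
    snp_to_gene: dict[str, Optional[str]]
    snp_chromosome: dict[str, str]
    clonal_lines: list[str]
    nonclonal_line: Optional[str] = None
    gene_clone: dict[tuple[str, str], AllelicState] = field(default_factory=dict)

    def states_for(self, gene_id: str, line_id: str) -> list[SnpCloneState]:
        return [s for s in self.snp_states
                if self.snp_to_gene.get(s.snp_id) == gene_id and s.line_id == line_id]

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.snp_states:
            g = self.snp_to_gene.get(s.snp_id)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)


def call_heterozygous_snps(matrix: CallMatrix, cfg: FilterConfig,
                           lines: Optional[Iterable[str]] = None) -> set[tuple[str, str]]:
    """(snp, line) pairs robustly called heterozygous in the line's own gDNA."""
    result: set[tuple[str, str]] = set()
    for line_id in (lines if lines is not None else matrix.line_ids):
        gdna = matrix.gdna_array(line_id)  # raises ValidationError if absent
        for snp_id in matrix.snps:
            g = matrix.get(snp_id, gdna.array_id)
            if g.call is Call.AB and cfg.passes(g):
                result.add((snp_id, line_id))
    return result


def consensus_cdna_call(rep1: GenotypeCall, rep2: GenotypeCall,
                        cfg: FilterConfig) -> ConsensusCall:
    """Merge two replicate cDNA calls conservatively.

    Identical confident calls keep the call; a lone confident call is not
    trusted (NoCall) under replicate agreement; confident calls that disagree
    are flagged ``filtered``.
    """
    c1 = rep1.call if cfg.passes(rep1) else None
    c2 = rep2.call if cfg.passes(rep2) else None
    if c1 is not None and c2 is not None:
        if c1 is c2:
            return ConsensusCall(c1)
        return ConsensusCall(Call.NOCALL, filtered=True)
    if c1 is not None or c2 is not None:
        if cfg.require_replicate_agreement:
            return ConsensusCall(Call.NOCALL)
        return ConsensusCall(c1 if c1 is not None else c2)
    return ConsensusCall(Call.NOCALL)


def line_cdna_consensus(matrix: CallMatrix, snp_id: str, line_id: str,
                        cfg: FilterConfig) -> ConsensusCall:
    reps = matrix.cdna_arrays(line_id)
    if len(reps) != 2:
        raise ValidationError(
            f"line {line_id!r}: expected exactly 2 cDNA replicate arrays, "
            f"found {len(reps)}")
    return consensus_cdna_call(matrix.get(snp_id, reps[0].array_id),
                               matrix.get(snp_id, reps[1].array_id), cfg)


def both_alleles_detectable(snp_id: str, matrix: CallMatrix,
                            cfg: FilterConfig) -> bool:
    """True iff allele A and allele B each appear in at least one passing cDNA
    call anywhere in the analysis set (an AB call evidences both)."""
    if snp_id not in matrix.snps:
        raise KeyError(snp_id)
    seen_a = seen_b = False
    for arr in matrix.all_cdna_arrays():
        g = matrix.get(snp_id, arr.array_id)
        if not cfg.passes(g):
            continue
        if g.call in (Call.AA, Call.AB):
            seen_a = True
        if g.call in (Call.BB, Call.AB):
            seen_b = True
        if seen_a and seen_b:
            return True
    return seen_a and seen_b


def nonclonal_admissible(nonclonal_cdna: ConsensusCall) -> bool:
    """The non-clonal control: admit the SNP only when the pooled cDNA reads
    AB or NoCall; homozygous pooled expression flags imprinting/cis-skew."""
    return nonclonal_cdna.call in (Call.AB, Call.NOCALL)


def snp_clone_state(gdna: GenotypeCall, cdna_consensus: ConsensusCall,
                    ann: SnpAnnotation, admissible: bool, cfg: FilterConfig,
                    line_id: str = "") -> SnpCloneState:
    """Combine a clone's gDNA call and cDNA consensus into an allelic state."""
    snp = ann.snp_id
    if not admissible:
        return SnpCloneState(snp, line_id, AllelicState.UNINFORMATIVE, "filtered")
    if gdna.call is not Call.AB or not cfg.passes(gdna):
        return SnpCloneState(snp, line_id, AllelicState.UNINFORMATIVE, "nocall")
    if cdna_consensus.call is Call.NOCALL:
        prov = "filtered" if cdna_consensus.filtered else "nocall"
        return SnpCloneState(snp, line_id, AllelicState.UNINFORMATIVE, prov)
    if cdna_consensus.call is Call.AB:
        return SnpCloneState(snp, line_id, AllelicState.BIALLELIC,
                             "het_gdna_het_cdna")
    parent = (ann.allele_A_parent if cdna_consensus.call is Call.AA
              else ann.allele_B_parent)
    state = (AllelicState.MONO_MATERNAL if parent.value == "maternal"
             else AllelicState.MONO_PATERNAL)
    return SnpCloneState(snp, line_id, state, "het_gdna_hom_cdna")


def _aggregate_gene_clone(states: list[AllelicState]) -> AllelicState:
    """Consensus state of a gene in a clone from its SNP states: direction of
    the monoallelic majority; exact direction tie → Uninformative; otherwise
    Biallelic if any biallelic SNP; else Uninformative."""
    n_mat = sum(1 for s in states if s is AllelicState.MONO_MATERNAL)
    n_pat = sum(1 for s in states if s is AllelicState.MONO_PATERNAL)
    n_bi = sum(1 for s in states if s is AllelicState.BIALLELIC)
    if n_mat > n_pat:
        return AllelicState.MONO_MATERNAL
    if n_pat > n_mat:
        return AllelicState.MONO_PATERNAL
    if n_mat > 0:  # tied directions
        return AllelicState.UNINFORMATIVE
    if n_bi > 0:
        return AllelicState.BIALLELIC
    return AllelicState.UNINFORMATIVE


def build_state_table(matrix: CallMatrix, annotations: Iterable[SnpAnnotation],
                      cfg: FilterConfig, apply_nonclonal_filter: bool = True,
                      apply_detectability_filter: bool = True,
                      include_nonclonal_line: bool = False) -> AllelicStateTable:
    """Run the full cascade over every genic SNP × line.

    Intergenic SNPs are excluded (the analysis is restricted to SNPs within
    annotated genes). Disabling the non-clonal and detectability filters with
    ``include_nonclonal_line=True`` gives the pre-filter view the imprinting
    screen needs — a consistently imprinted gene only ever shows one allele in
    cDNA, so both filters would hide it by design.
    """
    matrix.validate()
    idx = annotation_index(annotations)
    nonclonal = matrix.nonclonal_line_id
    lines = list(matrix.clonal_line_ids)
    if include_nonclonal_line:
        lines.append(nonclonal)

    states: list[SnpCloneState] = []
    for snp_id in matrix.snps:
        ann = idx.get(snp_id)
        if ann is None or ann.gene_id is None:
            continue
        detectable = (both_alleles_detectable(snp_id, matrix, cfg)
                      or not apply_detectability_filter)
        nc_consensus = line_cdna_consensus(matrix, snp_id, nonclonal, cfg)
        nc_ok = nonclonal_admissible(nc_consensus)
        for line_id in lines:
            admissible = detectable and (nc_ok or not apply_nonclonal_filter)
            gdna = matrix.get(snp_id, matrix.gdna_array(line_id).array_id)
            consensus = line_cdna_consensus(matrix, snp_id, line_id, cfg)
            states.append(snp_clone_state(gdna, consensus, ann, admissible,
                                          cfg, line_id))

    table = AllelicStateTable(
        snp_states=states,
        snp_to_gene={s: idx[s].gene_id for s in matrix.snps if s in idx},
        snp_chromosome={s: idx[s].chromosome for s in matrix.snps if s in idx},
        clonal_lines=list(matrix.clonal_line_ids),
        nonclonal_line=nonclonal if include_nonclonal_line else None,
    )
    by_gene_clone: dict[tuple[str, str], list[AllelicState]] = {}
    for s in states:
        gene = table.snp_to_gene.get(s.snp_id)
        if gene is not None:
            by_gene_clone.setdefault((gene, s.line_id), []).append(s.state)
    table.gene_clone = {key: _aggregate_gene_clone(vals)
                        for key, vals in by_gene_clone.items()}
    return table
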