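"""Gene-level aggregation: the G-score and RMAE / BAE classification.

Evidence for monoallelic expression is aggregated within each clone and then
across clones. Per clone, let m+ be the number of informative SNPs monoallelic
in the majority direction, m− the number monoallelic in the opposite
direction, and b the number biallelic. The clone score is

    0                         if m+ = 0
    m+                        if the SNPs agree perfectly (m− = b = 0)
    m+ · m+ / (m+ + m− + b)   otherwise (agreement-weighted)
    m+ / (m+ + m− + b)        on a direction tie (m+ = m−): at most 1/2

The tie rule keeps tied evidence strictly below the class II threshold
(the quadratic form would otherwise cross 1 at m+ = m− ≥ 2).

and the gene's G-score is the maximum clone score. Thresholds: G > 1 → RMAE
class I (multiple concordant SNPs); G = 1 → class II (a single informative
monoallelic SNP per clone); 0 < G < 1 → class III, inconclusive; G = 0 with at
least two informative clones → biallelic (BAE); anything else is unassessed.
The maximum (rather than a sum) keeps a gene whose single SNP is monoallelic
in several clones at exactly G = 1, as class II requires.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .datamodel import AllelicState, RmaecallError, UndefinedEvidenceError
from .calling import AllelicStateTable, SnpCloneState


class GeneClass(str, enum.Enum):
    RMAE_I = "RMAE_I"
    RMAE_II = "RMAE_II"
    RMAE_III = "RMAE_III"
    BAE = "BAE"
    UNASSESSED = "unassessed"

    @property
    def is_rmae(self) -> bool:
        return self in (GeneClass.RMAE_I, GeneClass.RMAE_II)

    @property
    def is_assessed(self) -> bool:
        """A gene counts as assessed when it lands in class I, II or BAE."""
        return self in (GeneClass.RMAE_I, GeneClass.RMAE_II, GeneClass.BAE)


@dataclass(frozen=True)
class CloneGeneEvidence:
    """SNP-state tallies for one gene in one clone."""

    gene_id: str
    line_id: str
    n_mono_major: int
    n_mono_minor: int
    n_biallelic: int
    direction: str  # maternal | paternal | tied | none

    def __post_init__(self):
        if (self.direction == "none") != (self.n_mono_major == 0):
            raise RmaecallError("direction 'none' iff no monoallelic SNPs")

    @property
    def n_informative(self) -> int:
        return self.n_mono_major + self.n_mono_minor + self.n_biallelic

    @property
    def consensus_state(self) -> AllelicState:
        if self.direction == "maternal":
            return AllelicState.MONO_MATERNAL
        if self.direction == "paternal":
            return AllelicState.MONO_PATERNAL
        if self.direction == "tied":
            return AllelicState.UNINFORMATIVE
        if self.n_biallelic > 0:
            return AllelicState.BIALLELIC
        return AllelicState.UNINFORMATIVE

    @classmethod
    def from_states(cls, gene_id: str, line_id: str,
                    states: Sequence[SnpCloneState]) -> "CloneGeneEvidence":
        n_mat = sum(1 for s in states if s.state is AllelicState.MONO_MATERNAL)
        n_pat = sum(1 for s in states if s.state is AllelicState.MONO_PATERNAL)
        n_bi = sum(1 for s in states if s.state is AllelicState.BIALLELIC)
        if n_mat > n_pat:
            direction = "maternal"
        elif n_pat > n_mat:
            direction = "paternal"
        elif n_mat > 0:
            direction = "tied"
        else:
            direction = "none"
        return cls(gene_id=gene_id, line_id=line_id,
                   n_mono_major=max(n_mat, n_pat),
                   n_mono_minor=min(n_mat, n_pat),
                   n_biallelic=n_bi, direction=direction)


def clone_score(ev: CloneGeneEvidence) -> float:
    if ev.n_informative == 0:
        raise UndefinedEvidenceError(
            f"gene {ev.gene_id}, clone {ev.line_id}: no informative SNPs")
    m_plus, m_minus, b = ev.n_mono_major, ev.n_mono_minor, ev.n_biallelic
    if m_plus == 0:
        return 0.0
    if m_minus == 0 and b == 0:
        return float(m_plus)
    if m_plus == m_minus:
        # tied directions are the weakest evidence: keep only the agreement
        # fraction (<= 1/2), never reaching 1
        return m_plus / (m_plus + m_minus + b)
    return m_plus * m_plus / (m_plus + m_minus + b)


def g_score(per_clone: Sequence[CloneGeneEvidence]) -> float:
    informative = [ev for ev in per_clone if ev.n_informative > 0]
    if not informative:
        raise UndefinedEvidenceError("no clone carries informative evidence")
    return max(clone_score(ev) for ev in informative)


def classify_gene(G: float, n_informative_clones: int) -> GeneClass:
    if G < 0:
        raise RmaecallError(f"negative G-score {G}")
    if G > 1:
        return GeneClass.RMAE_I
    if G == 1:
        return GeneClass.RMAE_II
    if G > 0:
        return GeneClass.RMAE_III
    if n_informative_clones >= 2:
        return GeneClass.BAE
    return GeneClass.UNASSESSED


@dataclass
class GeneClassification:
    gene_id: str
    G: float
    klass: GeneClass
    n_informative_clones: int
    n_snps_assessed: int
    per_clone: list[CloneGeneEvidence] = field(default_factory=list)


@dataclass
class ClassSummary:
    """Cohort-level counts with the derived percentages the report prints.

    Percentages are relative to assessed genes (class I + class II + BAE);
    ``mean_snps_per_gene`` divides the assessed SNP count by assessed genes.
    """

    n_assessed: int
    n_class_i: int
    n_class_ii: int
    n_class_iii: int = 0
    n_bae: int = 0
    n_unassessed: int = 0
    n_snps_assessed: int = 0
    agreement_fraction: Optional[float] = None

    @property
    def n_rmae(self) -> int:
        return self.n_class_i + self.n_class_ii

    @property
    def pct_class_i(self) -> float:
        return 100.0 * self.n_class_i / self.n_assessed

    @property
    def pct_class_ii(self) -> float:
        return 100.0 * self.n_class_ii / self.n_assessed

    @property
    def pct_rmae(self) -> float:
        return 100.0 * self.n_rmae / self.n_assessed

    @property
    def mean_snps_per_gene(self) -> float:
        return self.n_snps_assessed / self.n_assessed


def percent(k: int, n: int) -> float:
    """Plain percentage helper (e.g. overlap as a share of one species' RMAE set)."""
    return 100.0 * k / n


def snp_agreement_fraction(table: AllelicStateTable,
                           rmae_only: bool = False) -> Optional[float]:
    """Fraction of multi-SNP gene×clone observations whose informative SNP
    states agree perfectly; None when no such observation exists."""
    by_gc: dict[tuple[str, str], list[AllelicState]] = {}
    for s in table.snp_states:
        gene = table.snp_to_gene.get(s.snp_id)
        if gene is None or s.state is AllelicState.UNINFORMATIVE:
            continue
        by_gc.setdefault((gene, s.line_id), []).append(s.state)
    multi = [v for v in by_gc.values() if len(v) >= 2]
    if not multi:
        return None
    agree = sum(1 for v in multi if len(set(v)) == 1)
    return agree / len(multi)


def classify_all(table: AllelicStateTable) -> tuple[list[GeneClassification], ClassSummary]:
    """Classify every gene with at least one informative SNP×clone state and
    summarize the cohort."""
    by_gene: dict[str, dict[str, list[SnpCloneState]]] = {}
    for s in table.snp_states:
        gene = table.snp_to_gene.get(s.snp_id)
        if gene is None:
            continue
        by_gene.setdefault(gene, {}).setdefault(s.line_id, []).append(s)

    results: list[GeneClassification] = []
    assessed_snps: set[str] = set()
    for gene_id in sorted(by_gene):
        per_clone = []
        for line_id in sorted(by_gene[gene_id]):
            if table.nonclonal_line is not None and line_id == table.nonclonal_line:
                continue
            per_clone.append(CloneGeneEvidence.from_states(
                gene_id, line_id, by_gene[gene_id][line_id]))
        informative = [ev for ev in per_clone if ev.n_informative > 0]
        if not informative:
            continue
        G = g_score(per_clone)
        klass = classify_gene(G, len(informative))
        snps = {s.snp_id for states in by_gene[gene_id].values() for s in states
                if s.state is not AllelicState.UNINFORMATIVE}
        results.append(GeneClassification(
            gene_id=gene_id, G=G, klass=klass,
            n_informative_clones=len(informative),
            n_snps_assessed=len(snps), per_clone=per_clone))
        if klass.is_assessed:
            assessed_snps |= snps

    counts = {k: sum(1 for r in results if r.klass is k) for k in GeneClass}
    summary = ClassSummary(
        n_assessed=counts[GeneClass.RMAE_I] + counts[GeneClass.RMAE_II]
        + counts[GeneClass.BAE],
        n_class_i=counts[GeneClass.RMAE_I],
        n_class_ii=counts[GeneClass.RMAE_II],
        n_class_iii=counts[GeneClass.RMAE_III],
        n_bae=counts[GeneClass.BAE],
        n_unassessed=counts[GeneClass.UNASSESSED],
        n_snps_assessed=len(assessed_snps),
        agreement_fraction=snp_agreement_fraction(table),
    )
    return results, summary
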