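"""Synthetic genotype-call datasets with the statistical structure the
pipeline assumes, plus the ground truth needed to test every stage.

The generator emulates the study design: F1-hybrid clonal cell lines (one
gDNA array and two replicate cDNA arrays each) plus one polyclonal non-clonal
line of the same genotype. Each gene carries one allelic regime:

* ``BAE`` — both alleles expressed in every cell;
* ``RMAE_balanced`` — each clonal lineage independently either biallelic or
  monoallelic (probability ``rmae_mono_prob``), choosing the allele by a fair
  coin;
* ``RMAE_skewed`` — as above, but a gene-level preferred allele (drawn once)
  is chosen with probability ``skew_p``;
* ``imprinted`` — monoallelic with a parent-fixed direction in every cell of
  every line;
* ``cis_skewed`` — monoallelic with a strain/haplotype-fixed allele in every
  cell of every line.

Within a clone, every SNP of a gene shares the clone's state (stable mitotic
inheritance); X-linked genes are fully coordinated per female clone. The
non-clonal line's cDNA call is the majority call of a simulated pool of cells.
Calls are corrupted by symmetric miscalls and NoCall dropout per replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .datamodel import (
    AllelicState,
    ArrayMeta,
    Call,
    CallMatrix,
    GeneAnnotation,
    GenotypeCall,
    NOCALL,
    Parent,
    RmaecallError,
    SnpAnnotation,
)
from .scoring import CloneGeneEvidence, GeneClassification, GeneClass
from .stats import SkewCounts

REGIMES = ("BAE", "RMAE_balanced", "RMAE_skewed", "imprinted", "cis_skewed")

#: SNPs-per-gene mixture: mode 1, mean 1.53 (matching the assessed-SNP density
#: of a sparse genotyping array restricted to genic SNPs).
DEFAULT_SNPS_PER_GENE = {1: 0.65, 2: 0.21, 3: 0.10, 4: 0.04}

DEFAULT_REGIME_FRACTIONS = {
    "BAE": 0.80,
    "RMAE_balanced": 0.06,
    "RMAE_skewed": 0.09,
    "imprinted": 0.02,
    "cis_skewed": 0.03,
}


@dataclass
class SimConfig:
    n_autosomal_genes: int = 1000
    n_x_genes: int = 30
    n_clones: int = 7
    snps_per_gene_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SNPS_PER_GENE))
    regime_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGIME_FRACTIONS))
    rmae_mono_prob: float = 0.35
    skew_f: float = 0.8  # used by the skew-recovery simulator, not the regimes
    skew_p: float = 0.85
    call_error_rate: float = 0.02
    nocall_rate: float = 0.05
    nonclonal_pool_size: int = 1000
    nonclonal_ab_threshold: float = 0.10
    maternal_strain: int = 1  # which strain's alleles came from the dam
    cross_id: str = "cross1"
    n_autosomes: int = 5
    chromosome_length: int = 100_000_000
    snp_desert_fraction: float = 0.0
    gene_length: int = 20_000
    seed: int = 0

    def __post_init__(self):
        total = sum(self.regime_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise RmaecallError(f"regime fractions sum to {total}, expected 1")
        for name in self.regime_fractions:
            if name not in REGIMES:
                raise RmaecallError(f"unknown regime {name!r}")
        for p in (self.rmae_mono_prob, self.call_error_rate, self.nocall_rate,
                  self.skew_p, self.snp_desert_fraction):
            if not (0.0 <= p <= 1.0):
                raise RmaecallError(f"probability {p} outside [0, 1]")
        if abs(sum(self.snps_per_gene_distribution.values()) - 1.0) > 1e-9:
            raise RmaecallError("snps_per_gene_distribution must sum to 1")
        if self.maternal_strain not in (1, 2):
            raise RmaecallError("maternal_strain must be 1 or 2")


@dataclass
class TruthTable:
    gene_regime: dict[str, str]
    gene_clone_state: dict[tuple[str, str], AllelicState]
    clone_active_x: dict[str, Parent]
    gene_preferred_parent: dict[str, Parent]  # skewed/imprinted/cis genes


def _parent_of_allele(allele: str, cfg: SimConfig) -> Parent:
    """Allele A is always the strain-1 allele; its parent follows the cross."""
    strain = 1 if allele == "A" else 2
    return Parent.MATERNAL if strain == cfg.maternal_strain else Parent.PATERNAL


def _allele_of_parent(parent: Parent, cfg: SimConfig) -> str:
    return "A" if _parent_of_allele("A", cfg) == parent else "B"


def _mono_call(parent: Parent, cfg: SimConfig) -> Call:
    return Call.AA if _allele_of_parent(parent, cfg) == "A" else Call.BB


def _corrupt(call: Call, rng: np.random.Generator, cfg: SimConfig) -> GenotypeCall:
    if rng.random() < cfg.nocall_rate:
        return NOCALL
    if rng.random() < cfg.call_error_rate:
        others = [c for c in (Call.AA, Call.AB, Call.BB) if c is not call]
        call = others[rng.integers(len(others))]
    return GenotypeCall(call, confidence=float(rng.uniform(0.001, 0.04)))


def _clean(call: Call, rng: np.random.Generator) -> GenotypeCall:
    return GenotypeCall(call, confidence=float(rng.uniform(0.001, 0.04)))


def simulate_dataset(cfg: SimConfig) -> tuple[
        CallMatrix, list[SnpAnnotation], list[GeneAnnotation], TruthTable]:
    """Draw a full analysis set (call matrix + annotation + ground truth)."""
    rng = np.random.default_rng(cfg.seed)

    # --- lines and arrays --------------------------------------------------
    clone_ids = [f"clone{i + 1}" for i in range(cfg.n_clones)]
    nonclonal_id = "nonclonal1"
    arrays: list[ArrayMeta] = []
    for line_id in clone_ids + [nonclonal_id]:
        kind = "nonclonal" if line_id == nonclonal_id else "clonal"
        arrays.append(ArrayMeta(f"{line_id}_g", line_id, kind, "gDNA", 1,
                                cfg.cross_id, "F"))
        for rep in (1, 2):
            arrays.append(ArrayMeta(f"{line_id}_c{rep}", line_id, kind, "cDNA",
                                    rep, cfg.cross_id, "F"))

    # --- genes, SNPs, annotation ------------------------------------------
    gene_ann: list[GeneAnnotation] = []
    snp_ann: list[SnpAnnotation] = []
    gene_snps: dict[str, list[str]] = {}
    snps_k = sorted(cfg.snps_per_gene_distribution)
    snps_p = [cfg.snps_per_gene_distribution[k] for k in snps_k]

    def place_genes(n_genes: int, chroms: list[str], prefix: str):
        per_chrom = {c: [] for c in chroms}
        for i in range(n_genes):
            per_chrom[chroms[i % len(chroms)]].append(f"{prefix}{i + 1:05d}")
        lo, hi = 0, cfg.chromosome_length - cfg.gene_length
        desert = None
        if cfg.snp_desert_fraction > 0:
            d0 = int(0.4 * cfg.chromosome_length)
            desert = (d0, d0 + int(cfg.snp_desert_fraction * cfg.chromosome_length))
        for chrom, ids in per_chrom.items():
            starts: list[int] = []
            while len(starts) < len(ids):
                s = int(rng.integers(lo, hi))
                if desert and desert[0] <= s < desert[1]:
                    continue
                starts.append(s)
            starts.sort()
            for gid, start in zip(ids, starts):
                gene_ann.append(GeneAnnotation(gid, chrom, start,
                                               start + cfg.gene_length))
                n_snps = int(rng.choice(snps_k, p=snps_p))
                positions = sorted(int(p) for p in rng.integers(
                    start, start + cfg.gene_length, size=n_snps))
                ids_for_gene = []
                for j, pos in enumerate(positions):
                    sid = f"{gid}_s{j + 1}"
                    context = "exon" if rng.random() < 0.05 else "intron"
                    snp_ann.append(SnpAnnotation(
                        sid, chrom, pos, gid, context,
                        _parent_of_allele("A", cfg), _parent_of_allele("B", cfg)))
                    ids_for_gene.append(sid)
                gene_snps[gid] = ids_for_gene

    autosomes = [f"chr{i + 1}" for i in range(cfg.n_autosomes)]
    place_genes(cfg.n_autosomal_genes, autosomes, "gA")
    if cfg.n_x_genes:
        place_genes(cfg.n_x_genes, ["chrX"], "gX")

    # --- regimes and truth states ------------------------------------------
    regimes = list(cfg.regime_fractions)
    regime_p = [cfg.regime_fractions[r] for r in regimes]
    gene_regime: dict[str, str] = {}
    preferred: dict[str, Parent] = {}
    for g in gene_ann:
        if g.chromosome == "chrX":
            gene_regime[g.gene_id] = "X_linked"
            continue
        regime = str(rng.choice(regimes, p=regime_p))
        gene_regime[g.gene_id] = regime
        if regime == "RMAE_skewed":
            preferred[g.gene_id] = (Parent.MATERNAL if rng.random() < 0.5
                                    else Parent.PATERNAL)
        elif regime == "imprinted":
            preferred[g.gene_id] = (Parent.MATERNAL if rng.random() < 0.5
                                    else Parent.PATERNAL)
        elif regime == "cis_skewed":
            # strain-fixed allele; parental direction follows the cross
            allele = "A" if rng.random() < 0.5 else "B"
            preferred[g.gene_id] = _parent_of_allele(allele, cfg)

    clone_active_x = {c: (Parent.MATERNAL if rng.random() < 0.5
                          else Parent.PATERNAL) for c in clone_ids}

    def clone_state(gene_id: str, line_id: str) -> AllelicState:
        regime = gene_regime[gene_id]
        if regime == "X_linked":
            p = clone_active_x[line_id]
            return (AllelicState.MONO_MATERNAL if p is Parent.MATERNAL
                    else AllelicState.MONO_PATERNAL)
        if regime == "BAE":
            return AllelicState.BIALLELIC
        if regime in ("imprinted", "cis_skewed"):
            p = preferred[gene_id]
            return (AllelicState.MONO_MATERNAL if p is Parent.MATERNAL
                    else AllelicState.MONO_PATERNAL)
        # RMAE regimes
        if rng.random() >= cfg.rmae_mono_prob:
            return AllelicState.BIALLELIC
        if regime == "RMAE_balanced":
            p = Parent.MATERNAL if rng.random() < 0.5 else Parent.PATERNAL
        else:
            pref = preferred[gene_id]
            p = pref if rng.random() < cfg.skew_p else pref.other
        return (AllelicState.MONO_MATERNAL if p is Parent.MATERNAL
                else AllelicState.MONO_PATERNAL)

    gene_clone_state: dict[tuple[str, str], AllelicState] = {}
    for g in gene_ann:
        for line_id in clone_ids:
            gene_clone_state[(g.gene_id, line_id)] = clone_state(g.gene_id, line_id)

    # --- non-clonal pool consensus per gene --------------------------------
    def nonclonal_call(gene_id: str) -> Call:
        regime = gene_regime[gene_id]
        pool = cfg.nonclonal_pool_size
        if regime == "BAE":
            n_bi, n_a, n_b = pool, 0, 0
        elif regime == "X_linked":
            n_a = int(rng.binomial(pool, 0.5))
            n_b, n_bi = pool - n_a, 0
        elif regime in ("imprinted", "cis_skewed"):
            allele = _allele_of_parent(preferred[gene_id], cfg)
            n_a = pool if allele == "A" else 0
            n_b, n_bi = pool - n_a, 0
        else:
            n_mono = int(rng.binomial(pool, cfg.rmae_mono_prob))
            n_bi = pool - n_mono
            if regime == "RMAE_balanced":
                n_first = int(rng.binomial(n_mono, 0.5))
                n_a, n_b = n_first, n_mono - n_first
            else:
                pref_allele = _allele_of_parent(preferred[gene_id], cfg)
                n_pref = int(rng.binomial(n_mono, cfg.skew_p))
                n_a = n_pref if pref_allele == "A" else n_mono - n_pref
                n_b = n_mono - n_a
        frac_a = (n_bi + n_a) / pool
        frac_b = (n_bi + n_b) / pool
        thr = cfg.nonclonal_ab_threshold
        if frac_a >= thr and frac_b >= thr:
            return Call.AB
        return Call.AA if frac_a >= frac_b else Call.BB

    nonclonal_gene_call = {g.gene_id: nonclonal_call(g.gene_id) for g in gene_ann}

    # --- emit calls ---------------------------------------------------------
    matrix = CallMatrix(arrays=arrays,
                        snps=[a.snp_id for a in snp_ann], calls={})
    state_to_call = {
        AllelicState.BIALLELIC: lambda: Call.AB,
        AllelicState.MONO_MATERNAL: lambda: _mono_call(Parent.MATERNAL, cfg),
        AllelicState.MONO_PATERNAL: lambda: _mono_call(Parent.PATERNAL, cfg),
    }
    for g in gene_ann:
        for sid in gene_snps[g.gene_id]:
            for line_id in clone_ids + [nonclonal_id]:
                matrix.set(sid, f"{line_id}_g", _clean(Call.AB, rng))
                if line_id == nonclonal_id:
                    true_call = nonclonal_gene_call[g.gene_id]
                else:
                    state = gene_clone_state[(g.gene_id, line_id)]
                    true_call = state_to_call[state]()
                for rep in (1, 2):
                    matrix.set(sid, f"{line_id}_c{rep}",
                               _corrupt(true_call, rng, cfg))

    truth = TruthTable(gene_regime=gene_regime,
                       gene_clone_state=gene_clone_state,
                       clone_active_x=clone_active_x,
                       gene_preferred_parent=preferred)
    return matrix, snp_ann, gene_ann, truth


# ---------------------------------------------------------------------------
# lightweight simulators for specific statistics


def simulate_skew_counts(n_genes: int, f: float, p: float, n_clones: int,
                         mono_prob: float,
                         rng: np.random.Generator) -> SkewCounts:
    """Directional outcomes only, for skew-grid parameter recovery: fraction f
    of genes draw a preferred allele chosen with probability p; the rest
    choose fairly. Returns the unidirectionality tallies for n ∈ {2, 3, 4}."""
    totals = {n: 0 for n in SkewCounts.N_MONO}
    unis = {n: 0 for n in SkewCounts.N_MONO}
    for _ in range(n_genes):
        skewed = rng.random() < f
        prob_first = p if skewed else 0.5
        n_mono = int(rng.binomial(n_clones, mono_prob))
        if n_mono not in totals:
            continue
        n_first = int(rng.binomial(n_mono, prob_first))
        totals[n_mono] += 1
        if n_first in (0, n_mono):
            unis[n_mono] += 1
    expected = {n: 0.5 ** (n - 1) for n in SkewCounts.N_MONO}
    return SkewCounts(n_genes_total=totals, n_genes_unidirectional=unis,
                      expected_fraction=expected,
                      p_value={n: None for n in SkewCounts.N_MONO})


def simulate_independent_choice(n_genes: int, rng: np.random.Generator,
                                chromosome: str = "chr1",
                                spacing: int = 100_000) -> tuple[
        list[GeneClassification], list[GeneAnnotation]]:
    """A chromosome of monoallelic genes whose directions are independent fair
    coins, in one clone — the null for the neighbor-coordination statistic."""
    classifications = []
    gene_ann = []
    for i in range(n_genes):
        gid = f"g{i + 1:05d}"
        start = i * spacing
        gene_ann.append(GeneAnnotation(gid, chromosome, start, start + 1000))
        direction = "maternal" if rng.random() < 0.5 else "paternal"
        ev = CloneGeneEvidence(gene_id=gid, line_id="clone1", n_mono_major=1,
                               n_mono_minor=0, n_biallelic=0,
                               direction=direction)
        classifications.append(GeneClassification(
            gene_id=gid, G=1.0, klass=GeneClass.RMAE_II,
            n_informative_clones=1, n_snps_assessed=1, per_clone=[ev]))
    return classifications, gene_ann


def tissue_imbalance_ratio(biallelic_fraction: float,
                           expression_per_active_allele: float = 1.0) -> float:
    """Aggregate allelic ratio (preferred : other) in a tissue where a
    fraction β of cells express both alleles and the rest express only the
    preferred allele, at a fixed expression level per active allele.

    The preferred allele contributes β + (1 − β) = 1 unit-share, the other β,
    so the ratio is 1 : β — e.g. 2:1 at β = 0.5 — independent of the per-
    allele level. Returns ``inf`` when no cell is biallelic.
    """
    beta = biallelic_fraction
    if not (0.0 <= beta <= 1.0):
        raise RmaecallError(f"biallelic fraction {beta} outside [0, 1]")
    if expression_per_active_allele <= 0:
        raise RmaecallError("expression level must be positive")
    if beta == 0.0:
        return math.inf
    return 1.0 / beta
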