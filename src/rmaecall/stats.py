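"""Downstream inference on the classified gene set.

Covers: coordination between neighboring monoallelic genes (chi-square against
a 50:50 agree/disagree split), cross-species ortholog overlap (upper-tail
hypergeometric), enrichment of unidirectional allelic choice and the
two-parameter skew model grid, X-inactivation concordance as a positive
control, and the parent-of-origin imprinting screen run on pre-filter states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .datamodel import (
    AllelicState,
    GeneAnnotation,
    IntegrityError,
    OrthologMap,
    Parent,
    RmaecallError,
)
from .calling import AllelicStateTable
from .scoring import GeneClass, GeneClassification


# ---------------------------------------------------------------------------
# neighbor-pair coordination


def equal_split_chi2(n1: int, n2: int) -> tuple[float, float]:
    """1-df goodness of fit of two counts against a 50:50 expectation, with no
    continuity correction."""
    if n1 < 0 or n2 < 0 or n1 + n2 == 0:
        raise RmaecallError("counts must be non-negative and not both zero")
    chi2, p = sps.chisquare([n1, n2])
    return float(chi2), float(p)


@dataclass
class NeighborPairResult:
    n_agree: int
    n_disagree: int
    chi2: Optional[float]
    p_value: Optional[float]
    mean_dist_agree: Optional[float]
    mean_dist_disagree: Optional[float]
    window: Optional[float]  # None = unbounded


def neighbor_coordination(classifications: Sequence[GeneClassification],
                          gene_annotations: Sequence[GeneAnnotation],
                          window: Optional[float] = None,
                          rmae_only: bool = True,
                          exclude_chromosomes: Sequence[str] = ()) -> NeighborPairResult:
    """Within each clone and chromosome, walk monoallelic genes in start-
    coordinate order; each adjacent pair (start-to-start distance within
    ``window``) agrees when both express the same parental allele. Pairs are
    pooled across clones.

    ``exclude_chromosomes`` drops chromosomes whose coordination is expected
    a priori (the X: inactivation coordinates the whole chromosome).
    """
    coords = {g.gene_id: (g.chromosome, g.start) for g in gene_annotations
              if g.chromosome not in set(exclude_chromosomes)}
    rmae = {c.gene_id: c for c in classifications
            if (not rmae_only) or c.klass.is_rmae}
    # per clone: chromosome -> [(start, parent)]
    lines = sorted({ev.line_id for c in classifications for ev in c.per_clone})
    agree_d: list[float] = []
    disagree_d: list[float] = []
    for line_id in lines:
        per_chrom: dict[str, list[tuple[int, Parent]]] = {}
        for c in rmae.values():
            if c.gene_id not in coords:
                continue
            for ev in c.per_clone:
                if ev.line_id != line_id:
                    continue
                parent = ev.consensus_state.parent
                if parent is None:
                    continue
                chrom, start = coords[c.gene_id]
                per_chrom.setdefault(chrom, []).append((start, parent))
        for chrom, entries in per_chrom.items():
            entries.sort()
            for (s1, p1), (s2, p2) in zip(entries, entries[1:]):
                dist = float(s2 - s1)
                if window is not None and dist > window:
                    continue
                (agree_d if p1 == p2 else disagree_d).append(dist)

    n_agree, n_disagree = len(agree_d), len(disagree_d)
    if n_agree + n_disagree > 0:
        chi2, p = equal_split_chi2(n_agree, n_disagree)
    else:
        chi2 = p = None
    return NeighborPairResult(
        n_agree=n_agree, n_disagree=n_disagree, chi2=chi2, p_value=p,
        mean_dist_agree=float(np.mean(agree_d)) if agree_d else None,
        mean_dist_disagree=float(np.mean(disagree_d)) if disagree_d else None,
        window=window)


# ---------------------------------------------------------------------------
# ortholog overlap


@dataclass
class OverlapResult:
    n_orthologs_assessed: int  # N
    n_rmae_species1: int  # K
    n_rmae_species2: int  # n
    n_overlap: int  # k
    expected_overlap: float
    p_hypergeometric: float


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def overlap_test(N: int, K: int, n: int, k: int) -> OverlapResult:
    if k > min(K, n):
        raise IntegrityError(f"overlap {k} exceeds min({K}, {n})")
    return OverlapResult(
        n_orthologs_assessed=N, n_rmae_species1=K, n_rmae_species2=n,
        n_overlap=k, expected_overlap=K * n / N,
        p_hypergeometric=hypergeom_upper_tail(k, N, K, n))


def ortholog_overlap(ortho: OrthologMap,
                     calls1: dict[str, GeneClass],
                     calls2: dict[str, GeneClass]) -> OverlapResult:
    """Overlap of RMAE labels across one-to-one orthologs assessed (class I,
    class II, or BAE) in both species."""
    assessed = [(g1, g2) for g1, g2 in ortho.pairs
                if g1 in calls1 and calls1[g1].is_assessed
                and g2 in calls2 and calls2[g2].is_assessed]
    N = len(assessed)
    if N == 0:
        raise RmaecallError("no ortholog assessed in both species")
    K = sum(1 for g1, _ in assessed if calls1[g1].is_rmae)
    n = sum(1 for _, g2 in assessed if calls2[g2].is_rmae)
    k = sum(1 for g1, g2 in assessed
            if calls1[g1].is_rmae and calls2[g2].is_rmae)
    return overlap_test(N, K, n, k)


# ---------------------------------------------------------------------------
# skewed allelic choice


@dataclass
class SkewCounts:
    """Per monoallelic-clone count n ∈ {2, 3, 4}: total genes, genes whose
    monoallelic clones all share one direction, the null expectation
    0.5^(n−1), and a one-sided exact binomial p-value for the excess."""

    n_genes_total: dict[int, int]
    n_genes_unidirectional: dict[int, int]
    expected_fraction: dict[int, float]
    p_value: dict[int, Optional[float]]

    N_MONO = (2, 3, 4)


def gene_directions(c: GeneClassification) -> Optional[list[Parent]]:
    """Per-clone monoallelic directions; None if any clone's direction is tied
    (no direction assignable, gene excluded from the skew analysis)."""
    dirs: list[Parent] = []
    for ev in c.per_clone:
        if ev.direction == "tied":
            return None
        if ev.direction == "maternal":
            dirs.append(Parent.MATERNAL)
        elif ev.direction == "paternal":
            dirs.append(Parent.PATERNAL)
    return dirs


def skew_counts(classifications: Sequence[GeneClassification],
                rmae_only: bool = True) -> SkewCounts:
    totals = {n: 0 for n in SkewCounts.N_MONO}
    unis = {n: 0 for n in SkewCounts.N_MONO}
    for c in classifications:
        if rmae_only and not c.klass.is_rmae:
            continue
        dirs = gene_directions(c)
        if dirs is None:
            continue
        n_mono = len(dirs)
        if n_mono in totals:
            totals[n_mono] += 1
            if len(set(dirs)) == 1:
                unis[n_mono] += 1
    expected = {n: 0.5 ** (n - 1) for n in SkewCounts.N_MONO}
    pvals: dict[int, Optional[float]] = {}
    for n in SkewCounts.N_MONO:
        if totals[n] == 0:
            pvals[n] = None
        else:
            pvals[n] = float(sps.binomtest(
                unis[n], totals[n], expected[n], alternative="greater").pvalue)
    return SkewCounts(n_genes_total=totals, n_genes_unidirectional=unis,
                      expected_fraction=expected, p_value=pvals)


@dataclass
class SkewModelGrid:
    f_values: list[float]
    p_values: list[float]
    ssd: np.ndarray  # shape (len(f_values), len(p_values))
    best_f: float
    best_p: float
    best_ssd: float


DEFAULT_F_GRID = tuple(round(0.1 * i, 10) for i in range(11))
DEFAULT_P_GRID = tuple(round(0.5 + 0.05 * i, 10) for i in range(11))


def skew_model_probability(n: int, f: float, p: float) -> float:
    """Probability that all n monoallelic clones of a gene share one direction
    under a mixture: fraction f of genes choose a preferred allele with
    probability p, the rest choose fairly."""
    if not (0.0 <= f <= 1.0):
        raise RmaecallError(f"fraction skewed {f} outside [0, 1]")
    if not (0.5 <= p <= 1.0):
        raise RmaecallError(f"skew probability {p} outside [0.5, 1]")
    return (1 - f) * 0.5 ** (n - 1) + f * (p ** n + (1 - p) ** n)


def skew_model_grid(counts: SkewCounts,
                    f_grid: Iterable[float] = DEFAULT_F_GRID,
                    p_grid: Iterable[float] = DEFAULT_P_GRID) -> SkewModelGrid:
    """Sum-of-squares misfit between observed and model-expected numbers of
    all-one-direction genes at n ∈ {2, 3, 4}, over an (f, p) grid."""
    f_values = list(f_grid)
    p_values = list(p_grid)
    ssd = np.zeros((len(f_values), len(p_values)))
    for i, f in enumerate(f_values):
        for j, p in enumerate(p_values):
            total = 0.0
            for n in SkewCounts.N_MONO:
                q = skew_model_probability(n, f, p)
                expected = counts.n_genes_total[n] * q
                total += (counts.n_genes_unidirectional[n] - expected) ** 2
            ssd[i, j] = total
    i_best, j_best = np.unravel_index(int(np.argmin(ssd)), ssd.shape)
    return SkewModelGrid(f_values=f_values, p_values=p_values, ssd=ssd,
                         best_f=f_values[i_best], best_p=p_values[j_best],
                         best_ssd=float(ssd[i_best, j_best]))


# ---------------------------------------------------------------------------
# X-inactivation concordance (positive control)


@dataclass
class XCloneConcordance:
    line_id: str
    n_mono_snps: int
    concordance: float
    active_parent: Parent
    flagged: bool  # concordance < 1


def x_concordance(table: AllelicStateTable,
                  x_chrom_id: str = "chrX") -> list[XCloneConcordance]:
    """Per clone: agreement of X-linked monoallelic SNP directions with the
    clone's majority direction, and the inferred active parental X. Clones
    with no informative X-linked SNP (e.g. males) are omitted."""
    out: list[XCloneConcordance] = []
    for line_id in table.clonal_lines:
        dirs = [s.state.parent for s in table.snp_states
                if s.line_id == line_id and s.state.is_mono
                and table.snp_chromosome.get(s.snp_id) == x_chrom_id]
        if not dirs:
            continue
        n_mat = sum(1 for d in dirs if d is Parent.MATERNAL)
        n_pat = len(dirs) - n_mat
        major = Parent.MATERNAL if n_mat >= n_pat else Parent.PATERNAL
        conc = max(n_mat, n_pat) / len(dirs)
        out.append(XCloneConcordance(line_id=line_id, n_mono_snps=len(dirs),
                                     concordance=conc, active_parent=major,
                                     flagged=conc < 1.0))
    return out


# ---------------------------------------------------------------------------
# imprinting screen


@dataclass
class ImprintingCandidate:
    gene_id: str
    direction: Parent
    n_mono_samples: int
    crosses: list[str]
    single_cross: bool  # True = cis-skew cannot be excluded


def imprinting_screen(prefilter_table: AllelicStateTable,
                      line_cross: Optional[dict[str, str]] = None,
                      min_mono_samples: int = 2) -> list[ImprintingCandidate]:
    """Screen for parent-of-origin monoallelic expression.

    Run on the pre-filter state table (non-clonal filter off, non-clonal line
    included): candidates are genes monoallelic with one parental direction in
    every informative sample. When the table spans reciprocal crosses, genes
    whose direction tracks the strain rather than the parent show opposite
    parental directions in the two crosses (each cross carries its own
    allele→parent map) and are rejected; single-cross candidates are flagged.
    """
    line_cross = line_cross or {}
    by_gene: dict[str, list] = {}
    for s in prefilter_table.snp_states:
        gene = prefilter_table.snp_to_gene.get(s.snp_id)
        if gene is not None and s.state is not AllelicState.UNINFORMATIVE:
            by_gene.setdefault(gene, []).append(s)

    candidates: list[ImprintingCandidate] = []
    for gene_id in sorted(by_gene):
        states = by_gene[gene_id]
        if any(not s.state.is_mono for s in states):
            continue  # a biallelic observation anywhere disqualifies
        dirs = {s.state.parent for s in states}
        if len(dirs) != 1:
            continue
        samples = {s.line_id for s in states}
        if len(samples) < min_mono_samples:
            continue
        crosses = sorted({line_cross.get(l, "cross1") for l in samples})
        candidates.append(ImprintingCandidate(
            gene_id=gene_id, direction=next(iter(dirs)),
            n_mono_samples=len(samples), crosses=crosses,
            single_cross=len(crosses) < 2))
    return candidates
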