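"""Shared fixtures: tiny hand-built analysis sets.

The standard toy design: lines ``c1``, ``c2`` (clonal) and ``nc`` (non-clonal),
each with one gDNA array (``<line>_g``) and two cDNA replicates
(``<line>_c1``, ``<line>_c2``).
"""

import pytest

from rmaecall.datamodel import (
    ArrayMeta,
    Call,
    CallMatrix,
    GenotypeCall,
    Parent,
    SnpAnnotation,
)

GOOD_CONF = 0.01


def make_arrays(clonal=("c1", "c2"), nonclonal="nc"):
    arrays = []
    for line in list(clonal) + [nonclonal]:
        kind = "nonclonal" if line == nonclonal else "clonal"
        arrays.append(ArrayMeta(f"{line}_g", line, kind, "gDNA", 1))
        arrays.append(ArrayMeta(f"{line}_c1", line, kind, "cDNA", 1))
        arrays.append(ArrayMeta(f"{line}_c2", line, kind, "cDNA", 2))
    return arrays


def gcall(call, conf=GOOD_CONF):
    call = Call(call)
    if call is Call.NOCALL:
        return GenotypeCall(call)
    return GenotypeCall(call, conf)


def make_matrix(snp_calls, clonal=("c1", "c2"), nonclonal="nc"):
    """Build a CallMatrix from {snp_id: {line: (gdna, cdna1, cdna2)}}; call
    values are strings, absent lines read NoCall."""
    arrays = make_arrays(clonal, nonclonal)
    matrix = CallMatrix(arrays=arrays, snps=list(snp_calls), calls={})
    for snp_id, per_line in snp_calls.items():
        for line, (g, r1, r2) in per_line.items():
            matrix.set(snp_id, f"{line}_g", gcall(g))
            matrix.set(snp_id, f"{line}_c1", gcall(r1))
            matrix.set(snp_id, f"{line}_c2", gcall(r2))
    return matrix


def make_ann(snp_id, gene_id="gene1", chrom="chr1", pos=100,
             a_parent=Parent.MATERNAL, context="intron"):
    b_parent = a_parent.other
    return SnpAnnotation(snp_id, chrom, pos, gene_id, context, a_parent, b_parent)


@pytest.fixture
def two_clone_arrays():
    return make_arrays()
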