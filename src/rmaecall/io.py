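"""Readers and writers for the pipeline's plain-text TSV/BED formats.

All outputs start with ``#``-prefixed provenance header lines (tool version,
parameters, seed); readers skip such lines. Files are deterministic: the same
inputs produce byte-identical outputs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, TextIO

from . import __version__
from .datamodel import (
    AllelicState,
    ArrayMeta,
    Call,
    CallMatrix,
    GeneAnnotation,
    GenotypeCall,
    IntegrityError,
    OrthologMap,
    ParseError,
    Parent,
    SnpAnnotation,
    STATE_TOKEN,
)

CALL_HEADER = ["snp_id", "array_id", "call", "confidence"]
META_HEADER = ["array_id", "line_id", "line_kind", "material",
               "replicate_index", "cross_id", "sex"]


def _rows(handle: TextIO):
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def _provenance(out: TextIO, params: Optional[Mapping] = None) -> None:
    out.write(f"# rmaecall {__version__}\n")
    for key, val in (params or {}).items():
        out.write(f"# {key}={val}\n")


def read_array_meta(path) -> list[ArrayMeta]:
    metas: list[ArrayMeta] = []
    with open(path) as fh:
        rows = _rows(fh)
        for lineno, fields in rows:
            if fields == META_HEADER:
                continue
            if len(fields) != len(META_HEADER):
                raise ParseError(
                    f"expected {len(META_HEADER)} columns, got {len(fields)}", lineno)
            try:
                metas.append(ArrayMeta(
                    array_id=fields[0], line_id=fields[1], line_kind=fields[2],
                    material=fields[3], replicate_index=int(fields[4]),
                    cross_id=fields[5], sex=fields[6]))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    return metas


def read_call_matrix(path, meta_path) -> CallMatrix:
    """Load a genotype-call table plus its array metadata and validate the
    analysis-set design (1 gDNA + 2 cDNA arrays per line, one non-clonal line).
    """
    metas = read_array_meta(meta_path)
    known_arrays = {m.array_id for m in metas}
    calls: dict[tuple[str, str], GenotypeCall] = {}
    snps: dict[str, None] = {}
    with open(path) as fh:
        for lineno, fields in _rows(fh):
            if fields == CALL_HEADER:
                continue
            if len(fields) != 4:
                raise ParseError(f"expected 4 columns, got {len(fields)}", lineno)
            snp_id, array_id, call_str, conf_str = fields
            try:
                call = Call(call_str)
            except ValueError:
                raise ParseError(f"unknown call {call_str!r}", lineno) from None
            if array_id not in known_arrays:
                raise ParseError(f"array {array_id!r} absent from metadata", lineno)
            if (snp_id, array_id) in calls:
                raise IntegrityError(
                    f"duplicate call for SNP {snp_id!r} on array {array_id!r}")
            if call is Call.NOCALL:
                gcall = GenotypeCall(call)
            else:
                try:
                    gcall = GenotypeCall(call, float(conf_str))
                except ValueError:
                    raise ParseError(f"bad confidence {conf_str!r}", lineno) from None
            calls[(snp_id, array_id)] = gcall
            snps.setdefault(snp_id, None)
    matrix = CallMatrix(arrays=metas, snps=list(snps), calls=calls)
    matrix.validate()
    return matrix


def write_call_matrix(matrix: CallMatrix, path, meta_path,
                      params: Optional[Mapping] = None) -> None:
    with open(meta_path, "w") as out:
        _provenance(out, params)
        out.write("\t".join(META_HEADER) + "\n")
        for m in matrix.arrays:
            out.write("\t".join([m.array_id, m.line_id, m.line_kind, m.material,
                                 str(m.replicate_index), m.cross_id, m.sex]) + "\n")
    with open(path, "w") as out:
        _provenance(out, params)
        out.write("\t".join(CALL_HEADER) + "\n")
        for (snp_id, array_id) in sorted(matrix.calls):
            g = matrix.calls[(snp_id, array_id)]
            conf = "" if g.confidence is None else f"{g.confidence:.6g}"
            out.write(f"{snp_id}\t{array_id}\t{g.call.value}\t{conf}\n")


def read_snp_annotation(path) -> list[SnpAnnotation]:
    """BED-like 8 columns: chrom, start(0-based), end, snp_id, gene_id(or "."),
    context, allele_A_parent, allele_B_parent."""
    anns: list[SnpAnnotation] = []
    with open(path) as fh:
        for lineno, fields in _rows(fh):
            if len(fields) != 8:
                raise ParseError(f"expected 8 columns, got {len(fields)}", lineno)
            chrom, start, _end, snp_id, gene, context, pa, pb = fields
            gene_id = None if gene == "." else gene
            try:
                ann = SnpAnnotation(
                    snp_id=snp_id, chromosome=chrom, position=int(start),
                    gene_id=gene_id, context=context,
                    allele_A_parent=Parent(pa), allele_B_parent=Parent(pb))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            anns.append(ann)
    return anns


def write_snp_annotation(anns: Sequence[SnpAnnotation], path,
                         params: Optional[Mapping] = None) -> None:
    with open(path, "w") as out:
        _provenance(out, params)
        for a in anns:
            gene = "." if a.gene_id is None else a.gene_id
            out.write("\t".join([a.chromosome, str(a.position), str(a.position + 1),
                                 a.snp_id, gene, a.context,
                                 a.allele_A_parent.value, a.allele_B_parent.value]) + "\n")


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """4-column BED: chrom, start, end, gene_id."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, fields in _rows(fh):
            if len(fields) != 4:
                raise ParseError(f"expected 4 columns, got {len(fields)}", lineno)
            try:
                genes.append(GeneAnnotation(
                    gene_id=fields[3], chromosome=fields[0],
                    start=int(fields[1]), end=int(fields[2])))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path,
                          params: Optional[Mapping] = None) -> None:
    with open(path, "w") as out:
        _provenance(out, params)
        for g in genes:
            out.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_ortholog_map(path) -> OrthologMap:
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, fields in _rows(fh):
            if len(fields) != 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", lineno)
            pairs.append((fields[0], fields[1]))
    return OrthologMap(pairs)


def write_report(classifications, path, gene_annotations=None,
                 params: Optional[Mapping] = None) -> None:
    """Write the per-gene classification report.

    Rows are sorted by (chromosome, gene start) when gene annotations are
    supplied, else by gene_id; per-clone states are serialized as M/P/B/·
    tokens in sorted line_id order.
    """
    classifications = list(classifications)
    lines = sorted({ev.line_id for c in classifications for ev in c.per_clone})
    coords = {g.gene_id: (g.chromosome, g.start)
              for g in (gene_annotations or [])}

    def sort_key(c):
        if c.gene_id in coords:
            chrom, start = coords[c.gene_id]
            return (0, chrom, start, c.gene_id)
        return (1, "", 0, c.gene_id)

    with open(path, "w") as out:
        _provenance(out, params)
        out.write("gene_id\tn_snps_assessed\tG_score\tclass\tclone_states\n")
        for c in sorted(classifications, key=sort_key):
            states = {ev.line_id: ev.consensus_state for ev in c.per_clone}
            uninf = STATE_TOKEN[AllelicState.UNINFORMATIVE]
            tokens = ",".join(
                STATE_TOKEN[states[l]] if l in states else uninf for l in lines)
            out.write(f"{c.gene_id}\t{c.n_snps_assessed}\t{c.G:.6g}\t"
                      f"{c.klass.value}\t{tokens}\n")
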