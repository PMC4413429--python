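"""Readers and writers for the text formats the pipeline touches.

Supported: coverage as bedGraph and WIG (fixedStep / variableStep, with
span), annotations as BED6 and GFF3, expression matrices and sample
metadata as TSV, gene sets as GMT.

All writers emit deterministic output (no timestamps) so that reports are
byte-identical across reruns; writers prepend a ``#`` comment header with
the tool version.
"""

from __future__ import annotations

import io
import re
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import __version__
from .model import (
    RAW_SCALE,
    CoverageTrack,
    ExpressionMatrix,
    FormatError,
    Gene,
    GeneSetCollection,
    GenomeAnnotation,
    RunLengthSignal,
    SampleInfo,
)

PathLike = Union[str, "io.IOBase"]

_CHROM_SIZE_RE = re.compile(r"^#\s*chrom_size\s+(\S+)\s+(\d+)\s*$")


def _header_comment(extra: str = "") -> str:
    line = f"# generated by deprof {__version__}"
    if extra:
        line += f" {extra}"
    return line + "\n"


# ---------------------------------------------------------------------------
# coverage: bedGraph and WIG


def read_coverage(
    path: str,
    dialect: str,
    *,
    sample_id: str = "sample",
    assay: str = "H3ac",
    genotype: str = "WT",
    annotation: Optional[GenomeAnnotation] = None,
    permissive: bool = False,
) -> CoverageTrack:
    """Read a coverage track from a bedGraph or WIG file.

    Unspecified bases are 0. When ``annotation`` is given, chromosome names
    are checked against it and coordinates beyond the chromosome length are
    an error; unknown chromosomes are an error unless ``permissive``.
    """
    if dialect not in ("bedgraph", "wig"):
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "bedgraph":
        per_chrom = _parse_bedgraph(lines, path)
    else:
        per_chrom = _parse_wig(lines, path)

    signal: Dict[str, RunLengthSignal] = {}
    for chrom, intervals in per_chrom.items():
        if not intervals:
            continue
        if annotation is not None:
            if chrom not in annotation.chrom_lengths:
                if permissive:
                    continue
                raise FormatError(
                    f"{path}: chromosome {chrom!r} not present in annotation "
                    "(pass permissive=True to skip)"
                )
            length = annotation.chrom_lengths[chrom]
            beyond = [(s, e) for s, e, _ in intervals if e > length]
            if beyond:
                raise FormatError(
                    f"{path}: interval [{beyond[0][0]}, {beyond[0][1]}) on "
                    f"{chrom} exceeds chromosome length {length}"
                )
        else:
            length = max(e for _, e, _ in intervals)
        signal[chrom] = RunLengthSignal.from_intervals(
            intervals, length, context=f"{path}: {chrom}: "
        )
    if annotation is not None:
        for chrom, length in annotation.chrom_lengths.items():
            signal.setdefault(chrom, RunLengthSignal.zeros(length))
    return CoverageTrack(sample_id=sample_id, assay=assay, genotype=genotype, signal=signal)


def _parse_value(token: str, path: str, lineno: int) -> float:
    try:
        v = float(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric value {token!r}") from None
    if not np.isfinite(v):
        raise FormatError(f"{path}:{lineno}: non-finite value {token!r}")
    if v < 0:
        raise FormatError(f"{path}:{lineno}: negative value {v}")
    return v


def _parse_bedgraph(lines: Sequence[str], path: str) -> Dict[str, List[Tuple[int, int, float]]]:
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        value = _parse_value(parts[3], path, lineno)
        if start < 0 or end <= start:
            raise FormatError(f"{path}:{lineno}: bad interval [{start}, {end})")
        per_chrom.setdefault(chrom, []).append((start, end, value))
    return per_chrom


def _parse_wig(lines: Sequence[str], path: str) -> Dict[str, List[Tuple[int, int, float]]]:
    """Parse WIG fixedStep/variableStep sections into 0-based intervals.

    WIG coordinates are 1-based; ``start=11`` covers 0-based base 10.
    """
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    mode: Optional[str] = None
    chrom = ""
    span = 1
    step = 1
    pos = 0  # next 0-based start for fixedStep
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith(("fixedStep", "variableStep")):
            fields = dict(
                kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
            )
            if "chrom" not in fields:
                raise FormatError(f"{path}:{lineno}: declaration lacks chrom=")
            chrom = fields["chrom"]
            span = int(fields.get("span", 1))
            if span < 1:
                raise FormatError(f"{path}:{lineno}: span must be >= 1")
            if line.startswith("fixedStep"):
                mode = "fixed"
                if "start" not in fields:
                    raise FormatError(f"{path}:{lineno}: fixedStep lacks start=")
                start1 = int(fields["start"])
                if start1 < 1:
                    raise FormatError(f"{path}:{lineno}: WIG start is 1-based, got {start1}")
                pos = start1 - 1
                step = int(fields.get("step", 1))
                if step < 1:
                    raise FormatError(f"{path}:{lineno}: step must be >= 1")
            else:
                mode = "variable"
            per_chrom.setdefault(chrom, [])
            continue
        if mode is None:
            raise FormatError(f"{path}:{lineno}: data line before any WIG declaration")
        parts = line.split()
        if mode == "fixed":
            if len(parts) != 1:
                raise FormatError(f"{path}:{lineno}: fixedStep data line must have 1 field")
            value = _parse_value(parts[0], path, lineno)
            if value != 0.0:
                per_chrom[chrom].append((pos, pos + span, value))
            pos += step
        else:
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: variableStep data line must have 2 fields")
            try:
                start1 = int(parts[0])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position") from None
            if start1 < 1:
                raise FormatError(f"{path}:{lineno}: WIG positions are 1-based, got {start1}")
            value = _parse_value(parts[1], path, lineno)
            if value != 0.0:
                per_chrom[chrom].append((start1 - 1, start1 - 1 + span, value))
    return per_chrom


def write_coverage(track: CoverageTrack, path: str, dialect: str = "bedgraph") -> None:
    """Write a track; re-reading the file yields an identical track.

    bedGraph output merges runs of equal value and omits zero runs; WIG
    output uses one variableStep declaration per run so arbitrary run
    lengths round-trip via the span attribute.
    """
    if dialect not in ("bedgraph", "wig"):
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(_header_comment(f"sample={track.sample_id} assay={track.assay} genotype={track.genotype}"))
        for chrom in sorted(track.signal):
            sig = track.signal[chrom]
            if dialect == "bedgraph":
                for s, e, v in sig.iter_intervals():
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")
            else:
                for s, e, v in sig.iter_intervals():
                    fh.write(f"variableStep chrom={chrom} span={e - s}\n")
                    fh.write(f"{s + 1} {v!r}\n")


# ---------------------------------------------------------------------------
# annotations: BED6 and GFF3


def read_annotation(
    path: str,
    dialect: str,
    *,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    feature_type: str = "gene",
) -> GenomeAnnotation:
    """Read gene anchors from BED6 or GFF3.

    TSS convention: BED6 (0-based half-open) uses chromStart for ``+`` and
    chromEnd - 1 for ``-``; GFF3 (1-based inclusive) uses start - 1 for
    ``+`` and end - 1 for ``-``.

    Chromosome lengths come from, in order of precedence: the
    ``chrom_lengths`` argument, ``# chrom_size <name> <len>`` comment lines
    (emitted by :func:`write_annotation`) or GFF3 ``##sequence-region``
    pragmas, else the maximum feature end per chromosome.
    """
    if dialect not in ("bed6", "gff3"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    declared: Dict[str, int] = {}
    genes: List[Gene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            m = _CHROM_SIZE_RE.match(line)
            if m:
                declared[m.group(1)] = int(m.group(2))
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    declared[parts[1]] = int(parts[3])
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            if dialect == "bed6":
                genes.append(_parse_bed6_line(line, path, lineno))
            else:
                g = _parse_gff3_line(line, path, lineno, feature_type)
                if g is not None:
                    genes.append(g)
    seen: Dict[str, int] = {}
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen[g.gene_id] = 1
    lengths: Dict[str, int] = dict(chrom_lengths) if chrom_lengths else dict(declared)
    for g in genes:
        if g.chrom not in lengths:
            lengths[g.chrom] = g.tss + 1
        else:
            lengths[g.chrom] = max(lengths[g.chrom], g.tss + 1)
    return GenomeAnnotation(chrom_lengths=lengths, genes=genes)


def _parse_bed6_line(line: str, path: str, lineno: int) -> Gene:
    parts = line.split("\t") if "\t" in line else line.split()
    if len(parts) < 6:
        raise FormatError(f"{path}:{lineno}: BED6 needs 6 fields, got {len(parts)}")
    chrom, name, strand = parts[0], parts[3], parts[5]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
    if not 0 <= start < end:
        raise FormatError(f"{path}:{lineno}: bad interval [{start}, {end})")
    tss = start if strand == "+" else end - 1
    return Gene(gene_id=name, chrom=chrom, tss=tss, strand=strand, name=name)


_GFF_ATTR_RE = re.compile(r"(?:^|;)\s*(ID|gene_id|Name)=([^;]+)")


def _parse_gff3_line(line: str, path: str, lineno: int, feature_type: str) -> Optional[Gene]:
    parts = line.split("\t")
    if len(parts) != 9:
        raise FormatError(f"{path}:{lineno}: GFF3 needs 9 tab-separated fields")
    chrom, _, ftype, start_s, end_s, _, strand, _, attrs = parts
    if ftype != feature_type:
        return None
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
    if not 1 <= start <= end:
        raise FormatError(f"{path}:{lineno}: bad 1-based interval [{start}, {end}]")
    found = dict(_GFF_ATTR_RE.findall(attrs))
    gene_id = found.get("ID") or found.get("gene_id")
    if gene_id is None:
        raise FormatError(f"{path}:{lineno}: no ID= or gene_id= attribute")
    tss = start - 1 if strand == "+" else end - 1
    return Gene(
        gene_id=gene_id,
        chrom=chrom,
        tss=tss,
        strand=strand,
        name=found.get("Name", gene_id),
    )


def write_annotation(annotation: GenomeAnnotation, path: str) -> None:
    """Write BED6 (1-bp features anchored at the TSS) plus chrom_size comments."""
    with open(path, "w") as fh:
        fh.write(_header_comment())
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(f"# chrom_size {chrom} {annotation.chrom_lengths[chrom]}\n")
        for g in annotation.genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# expression matrices and metadata


def read_expression(
    path: str,
    metadata: Union[str, Mapping[str, Tuple[str, int]]],
    *,
    scale: str = RAW_SCALE,
) -> ExpressionMatrix:
    """Read a feature x sample TSV (header row of sample ids, first column
    feature ids) plus sample metadata mapping sample_id -> (genotype, replicate).

    ``metadata`` may be a dict or a path to a TSV with columns
    ``sample_id  genotype  replicate``.
    """
    meta = read_sample_metadata(metadata) if isinstance(metadata, str) else dict(metadata)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty expression matrix")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}: header has no sample columns")
    samples = []
    for sid in sample_ids:
        if sid not in meta:
            raise FormatError(f"{path}: no metadata for sample column {sid!r}")
        genotype, replicate = meta[sid]
        samples.append(SampleInfo(sample_id=sid, genotype=genotype, replicate=int(replicate)))
    feature_ids: List[str] = []
    rows: List[List[float]] = []
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        feature_ids.append(parts[0])
        row = []
        for sid, tok in zip(sample_ids, parts[1:]):
            try:
                row.append(float(tok))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {tok!r} in column {sid!r}"
                ) from None
        rows.append(row)
    return ExpressionMatrix(
        feature_ids=feature_ids,
        samples=samples,
        values=np.array(rows, dtype=np.float64).reshape(len(rows), len(sample_ids)),
        scale=scale,
    )


def read_sample_metadata(path: str) -> Dict[str, Tuple[str, int]]:
    meta: Dict[str, Tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: need sample_id, genotype, replicate")
            try:
                rep = int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer replicate {parts[2]!r}") from None
            meta[parts[0]] = (parts[1], rep)
    return meta


def write_expression(matrix: ExpressionMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(f"scale={matrix.scale}"))
        fh.write("feature_id\t" + "\t".join(s.sample_id for s in matrix.samples) + "\n")
        for i, fid in enumerate(matrix.feature_ids):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in matrix.values[i]) + "\n")


def write_sample_metadata(samples: Sequence[SampleInfo], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgenotype\treplicate\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.genotype}\t{s.replicate}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str) -> GeneSetCollection:
    terms: Dict[str, Tuple[str, List[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: term {parts[0]!r} needs a description and >= 1 member"
                )
            term, desc = parts[0], parts[1]
            members = [m for m in parts[2:] if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = (desc, members)
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.terms):
            desc, members = collection.terms[term]
            fh.write("\t".join([term, desc] + list(members)) + "\n")
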