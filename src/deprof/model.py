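"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; 1-based
external conventions (WIG, GFF3) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "RunLengthSignal",
    "Gene",
    "GenomeAnnotation",
    "CoverageTrack",
    "SampleInfo",
    "ExpressionMatrix",
    "GeneSetCollection",
    "RAW_SCALE",
    "TRANSFORMED_SCALE",
]

RAW_SCALE = "raw-intensity"
TRANSFORMED_SCALE = "transformed"

ASSAYS = ("H3ac", "input")
GENOTYPES = ("WT", "KO")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Domain-type invariant violated."""


class RunLengthSignal:
    """Nonnegative per-base signal over one chromosome, run-length encoded.

    Stored as run start positions (``starts[0] == 0``, strictly increasing)
    and one value per run; the last run extends to ``length``. Runs are
    canonical: adjacent runs never carry equal values.
    """

    __slots__ = ("starts", "values", "length")

    def __init__(self, starts: np.ndarray, values: np.ndarray, length: int):
        starts = np.asarray(starts, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if length < 0:
            raise ValidationError("chromosome length must be >= 0")
        if starts.shape != values.shape:
            raise ValidationError("starts and values must have equal shape")
        if length == 0:
            self.starts = np.zeros(1, dtype=np.int64)
            self.values = np.zeros(1, dtype=np.float64)
            self.length = 0
            return
        if starts.size == 0:
            starts = np.zeros(1, dtype=np.int64)
            values = np.zeros(1, dtype=np.float64)
        if starts[0] != 0:
            raise ValidationError("first run must start at 0")
        if np.any(np.diff(starts) <= 0):
            raise ValidationError("run starts must be strictly increasing")
        if starts[-1] >= length:
            raise ValidationError("run start beyond chromosome length")
        if np.any(values < 0):
            raise ValidationError("signal values must be nonnegative")
        # canonicalize: merge adjacent equal-valued runs
        if values.size > 1:
            keep = np.empty(values.size, dtype=bool)
            keep[0] = True
            keep[1:] = values[1:] != values[:-1]
            starts = starts[keep]
            values = values[keep]
        self.starts = starts
        self.values = values
        self.length = int(length)

    # -- constructors ---------------------------------------------------

    @classmethod
    def zeros(cls, length: int) -> "RunLengthSignal":
        return cls(np.zeros(1, dtype=np.int64), np.zeros(1), length)

    @classmethod
    def from_dense(cls, arr: np.ndarray, length: Optional[int] = None) -> "RunLengthSignal":
        arr = np.asarray(arr, dtype=np.float64)
        if length is None:
            length = arr.size
        if arr.size == 0:
            return cls.zeros(length)
        change = np.empty(arr.size, dtype=bool)
        change[0] = True
        change[1:] = arr[1:] != arr[:-1]
        starts = np.flatnonzero(change)
        return cls(starts, arr[starts], length)

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[Tuple[int, int, float]],
        length: int,
        context: str = "",
    ) -> "RunLengthSignal":
        """Build from half-open ``(start, end, value)`` intervals.

        Gaps are zero-filled; overlapping intervals raise :class:`FormatError`
        naming the first overlap.
        """
        if not intervals:
            return cls.zeros(length)
        ivs = sorted(intervals, key=lambda t: (t[0], t[1]))
        starts: List[int] = []
        values: List[float] = []
        cursor = 0
        for s, e, v in ivs:
            if s < 0 or e > length:
                raise FormatError(
                    f"{context}interval [{s}, {e}) outside chromosome of length {length}"
                )
            if e <= s:
                raise FormatError(f"{context}empty or inverted interval [{s}, {e})")
            if v < 0:
                raise FormatError(f"{context}negative value {v} at [{s}, {e})")
            if s < cursor:
                raise FormatError(
                    f"{context}overlapping intervals: [{s}, {e}) overlaps a prior "
                    f"interval ending at {cursor}"
                )
            if s > cursor:
                starts.append(cursor)
                values.append(0.0)
            starts.append(s)
            values.append(float(v))
            cursor = e
        if cursor < length:
            starts.append(cursor)
            values.append(0.0)
        return cls(np.array(starts), np.array(values), length)

    # -- accessors ------------------------------------------------------

    def _bounds(self) -> np.ndarray:
        return np.concatenate([self.starts, [self.length]])

    def iter_intervals(self, include_zero: bool = False) -> Iterator[Tuple[int, int, float]]:
        bounds = self._bounds()
        for i, v in enumerate(self.values):
            if include_zero or v != 0.0:
                yield int(bounds[i]), int(bounds[i + 1]), float(v)

    def to_dense(self, start: int = 0, end: Optional[int] = None) -> np.ndarray:
        """Materialize per-base values on ``[start, end)``."""
        if end is None:
            end = self.length
        if not (0 <= start <= end <= self.length):
            raise ValidationError(
                f"slice [{start}, {end}) outside chromosome of length {self.length}"
            )
        if start == end:
            return np.zeros(0)
        bounds = self._bounds()
        lo = int(np.searchsorted(bounds, start, side="right")) - 1
        hi = int(np.searchsorted(bounds, end, side="left"))
        seg_starts = np.maximum(bounds[lo:hi], start)
        seg_ends = np.minimum(bounds[lo + 1 : hi + 1], end)
        return np.repeat(self.values[lo:hi], seg_ends - seg_starts)

    def sum(self) -> float:
        run_lengths = np.diff(self._bounds())
        return float(np.sum(self.values * run_lengths))

    def scaled(self, factor: float) -> "RunLengthSignal":
        if factor < 0:
            raise ValidationError("scale factor must be nonnegative")
        return RunLengthSignal(self.starts.copy(), self.values * factor, self.length)

    def _trimmed(self) -> Tuple[np.ndarray, np.ndarray]:
        """Runs with a trailing zero run removed (for length-agnostic equality)."""
        if self.values.size > 1 and self.values[-1] == 0.0:
            return self.starts[:-1], self.values[:-1]
        if self.values.size == 1 and self.values[0] == 0.0:
            return self.starts[:0], self.values[:0]
        return self.starts, self.values

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunLengthSignal):
            return NotImplemented
        s1, v1 = self._trimmed()
        s2, v2 = other._trimmed()
        return bool(np.array_equal(s1, s2) and np.array_equal(v1, v2))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RunLengthSignal(n_runs={self.values.size}, length={self.length})"


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    name: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS {self.tss}")


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus TSS-bearing gene records."""

    chrom_lengths: Dict[str, int]
    genes: List[Gene] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_lengths:
                raise ValidationError(
                    f"gene {g.gene_id}: chromosome {g.chrom!r} not in chrom_lengths"
                )
            if not 0 <= g.tss < self.chrom_lengths[g.chrom]:
                raise ValidationError(
                    f"gene {g.gene_id}: TSS {g.tss} outside chromosome "
                    f"{g.chrom} of length {self.chrom_lengths[g.chrom]}"
                )
        self._by_id = {g.gene_id: g for g in self.genes}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class CoverageTrack:
    """Per-base nonnegative signal for one sample across chromosomes."""

    sample_id: str
    assay: str
    genotype: str
    signal: Dict[str, RunLengthSignal]

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ValidationError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"genotype must be one of {GENOTYPES}, got {self.genotype!r}"
            )

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: s.length for c, s in self.signal.items()}

    @property
    def total_signal(self) -> float:
        return float(sum(s.sum() for s in self.signal.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            sample_id=self.sample_id,
            assay=self.assay,
            genotype=self.genotype,
            signal={c: s.scaled(factor) for c, s in self.signal.items()},
        )

    def validate_against(self, annotation: GenomeAnnotation) -> None:
        for chrom, sig in self.signal.items():
            if chrom not in annotation.chrom_lengths:
                raise ValidationError(
                    f"track {self.sample_id}: unknown chromosome {chrom!r}"
                )
            if sig.length > annotation.chrom_lengths[chrom]:
                raise ValidationError(
                    f"track {self.sample_id}: signal on {chrom} extends to "
                    f"{sig.length} beyond chromosome length "
                    f"{annotation.chrom_lengths[chrom]}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if (self.sample_id, self.assay, self.genotype) != (
            other.sample_id,
            other.assay,
            other.genotype,
        ):
            return False
        chroms = set(self.signal) | set(other.signal)
        for c in chroms:
            a = self.signal.get(c)
            b = other.signal.get(c)
            if a is None:
                a = RunLengthSignal.zeros(b.length)
            if b is None:
                b = RunLengthSignal.zeros(a.length)
            if a != b:
                return False
        return True


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    genotype: str
    replicate: int

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"sample {self.sample_id}: genotype must be one of {GENOTYPES}"
            )


@dataclass
class ExpressionMatrix:
    """Feature x sample intensity matrix with genotype/replicate metadata."""

    feature_ids: List[str]
    samples: List[SampleInfo]
    values: np.ndarray
    scale: str = RAW_SCALE

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n_feat, n_samp = len(self.feature_ids), len(self.samples)
        if self.values.shape != (n_feat, n_samp):
            raise ValidationError(
                f"values shape {self.values.shape} != ({n_feat}, {n_samp})"
            )
        if len(set(self.feature_ids)) != n_feat:
            raise ValidationError("feature_ids must be unique")
        if len({s.sample_id for s in self.samples}) != n_samp:
            raise ValidationError("sample ids must be unique")
        if self.scale not in (RAW_SCALE, TRANSFORMED_SCALE):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite cells")
        if self.scale == RAW_SCALE and n_feat and np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise ValidationError(
                f"raw-intensity matrix must be strictly positive; "
                f"feature {self.feature_ids[i]!r}, sample "
                f"{self.samples[j].sample_id!r} has value {self.values[i, j]}"
            )

    def genotype_columns(self, genotype: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.genotype == genotype])

    def with_values(self, values: np.ndarray, scale: Optional[str] = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            samples=list(self.samples),
            values=values,
            scale=self.scale if scale is None else scale,
        )


@dataclass
class GeneSetCollection:
    """Flat term -> member gene ids mapping (GMT semantics)."""

    terms: Dict[str, Tuple[str, List[str]]]

    def __post_init__(self):
        for term, (_, members) in self.terms.items():
            if not members:
                raise ValidationError(f"term {term!r} has no members")
            if len(set(members)) != len(members):
                raise ValidationError(f"term {term!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.terms)

    def members(self, term: str) -> List[str]:
        return self.terms[term][1]

    def description(self, term: str) -> str:
        return self.terms[term][0]
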