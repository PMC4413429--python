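"""TSS-anchored coverage density computation.

Depth normalization scales every track to the mean total signal; densities
are per-base means in sliding windows (default 100 bp windows, 20 bp
slide) over a 6 kb interval centred on each TSS; composite profiles take
the per-window median across a gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np

from .model import CoverageTrack, GenomeAnnotation, RunLengthSignal, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "CompositeProfile",
    "LocusSlice",
    "ProfileBoundsError",
    "depth_normalize",
    "windowed_density",
    "composite_profile",
    "locus_extract",
]


class ProfileBoundsError(ValidationError):
    """Profiling interval extends beyond the chromosome."""


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout relative to an anchor.

    Window ``i`` covers offsets ``[-span/2 + i*slide, -span/2 + i*slide + window)``;
    reported offsets are window centres.
    """

    span: int = 6000
    window: int = 100
    slide: int = 20

    def __post_init__(self):
        if self.span <= 0 or self.window <= 0 or self.slide <= 0:
            raise ValidationError("span, window and slide must be positive")
        if self.window > self.span:
            raise ValidationError("window must not exceed span")
        if self.span % 2 != 0:
            raise ValidationError("span must be even (interval centred on the anchor)")
        if (self.span - self.window) % self.slide != 0:
            raise ValidationError("(span - window) must be divisible by slide")

    @property
    def n_windows(self) -> int:
        return (self.span - self.window) // self.slide + 1

    @property
    def offsets(self) -> np.ndarray:
        """Window-centre offsets relative to the anchor (float for odd windows)."""
        start = -self.span / 2 + self.window / 2
        return start + self.slide * np.arange(self.n_windows)


@dataclass
class CompositeProfile:
    grid: WindowGrid
    track_id: str
    gene_set_id: str
    gene_ids: List[str]  # included genes, row order of per_gene_matrix
    per_gene_matrix: np.ndarray  # genes x windows
    median_profile: np.ndarray  # per-window median over included genes
    excluded: List[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class LocusSlice:
    chrom: str
    start: int  # 0-based
    values: np.ndarray

    @property
    def end(self) -> int:
        return self.start + self.values.size

    def to_track(self, template: CoverageTrack, chrom_length: int) -> CoverageTrack:
        """Embed the slice in an otherwise-zero track (for bedGraph export)."""
        sig = np.zeros(chrom_length)
        sig[self.start : self.end] = self.values
        return CoverageTrack(
            sample_id=template.sample_id,
            assay=template.assay,
            genotype=template.genotype,
            signal={self.chrom: RunLengthSignal.from_dense(sig, chrom_length)},
        )


def depth_normalize(tracks: Sequence[CoverageTrack]) -> List[CoverageTrack]:
    """Scale each track by mean(total_signal) / total_signal.

    After normalization all totals equal the pre-normalization mean.
    """
    if not tracks:
        raise ValidationError("depth_normalize needs >= 1 track")
    totals = [t.total_signal for t in tracks]
    for t, tot in zip(tracks, totals):
        if tot <= 0:
            raise ValidationError(f"track {t.sample_id!r} has zero total signal")
    mean_total = float(np.mean(totals))
    return [t.scaled(mean_total / tot) for t, tot in zip(tracks, totals)]


def windowed_density(
    track: CoverageTrack,
    chrom: str,
    tss: int,
    strand: str,
    grid: WindowGrid,
    strand_flip: bool = True,
) -> np.ndarray:
    """Per-window mean per-base signal over ``[tss - span/2, tss + span/2)``.

    For ``-`` strand genes the vector is reversed (unless ``strand_flip``
    is off) so offsets read 5' -> 3' along the gene.
    """
    if chrom not in track.signal:
        raise ValidationError(f"track {track.sample_id!r} has no chromosome {chrom!r}")
    sig = track.signal[chrom]
    half = grid.span // 2
    lo, hi = tss - half, tss + half
    if lo < 0 or hi > sig.length:
        raise ProfileBoundsError(
            f"interval [{lo}, {hi}) around TSS {tss} exceeds chromosome "
            f"{chrom} of length {sig.length}"
        )
    dense = sig.to_dense(lo, hi)
    windows = np.lib.stride_tricks.sliding_window_view(dense, grid.window)[:: grid.slide]
    out = windows.mean(axis=1)
    if strand == "-" and strand_flip:
        out = out[::-1]
    return np.ascontiguousarray(out)


def composite_profile(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    gene_ids: Iterable[str],
    grid: WindowGrid,
    strand_flip: bool = True,
    gene_set_id: str = "set",
) -> CompositeProfile:
    """Per-window median density across a gene set.

    Genes whose interval exceeds chromosome bounds are excluded (and
    reported), not zero-padded. Even-count medians are the mean of the two
    central order statistics (numpy convention).
    """
    ids = sorted(set(gene_ids))
    missing = [g for g in ids if g not in annotation]
    if missing:
        raise ValidationError(f"gene ids not in annotation: {', '.join(missing[:10])}")
    rows = []
    included: List[str] = []
    excluded: List[str] = []
    half = grid.span // 2
    for gid in ids:
        g = annotation[gid]
        length = annotation.chrom_lengths[g.chrom]
        if g.tss - half < 0 or g.tss + half > length:
            excluded.append(gid)
            continue
        rows.append(windowed_density(track, g.chrom, g.tss, g.strand, grid, strand_flip))
        included.append(gid)
    if not included:
        raise ValidationError(
            f"no genes with a full {grid.span} bp interval in bounds "
            f"({len(excluded)} excluded)"
        )
    if excluded:
        logger.info(
            "composite_profile %s/%s: excluded %d gene(s) near chromosome edges",
            track.sample_id,
            gene_set_id,
            len(excluded),
        )
    matrix = np.vstack(rows)
    return CompositeProfile(
        grid=grid,
        track_id=track.sample_id,
        gene_set_id=gene_set_id,
        gene_ids=included,
        per_gene_matrix=matrix,
        median_profile=np.median(matrix, axis=0),
        excluded=excluded,
    )


def locus_extract(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    gene_id: str,
    flank: int,
) -> LocusSlice:
    """Per-base signal on ``[tss - flank, tss + flank)`` for one gene.

    Out-of-bounds flanks are truncated with a warning.
    """
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    if gene_id not in annotation:
        raise ValidationError(f"unknown gene {gene_id!r}")
    g = annotation[gene_id]
    length = annotation.chrom_lengths[g.chrom]
    lo, hi = g.tss - flank, g.tss + flank
    if lo < 0 or hi > length:
        logger.warning(
            "locus_extract %s: flank truncated to chromosome bounds", gene_id
        )
        lo, hi = max(lo, 0), min(hi, length)
    if g.chrom in track.signal:
        sig = track.signal[g.chrom]
        hi_avail = min(hi, sig.length)
        values = np.zeros(hi - lo)
        if hi_avail > lo:
            values[: hi_avail - lo] = sig.to_dense(lo, hi_avail)
    else:
        values = np.zeros(hi - lo)
    return LocusSlice(chrom=g.chrom, start=lo, values=values)
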