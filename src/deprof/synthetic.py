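"""Synthetic annotations, expression matrices and ChIP/input coverage
tracks with known ground truth.

The expression model mirrors the moderated-t generative assumptions:
gene-wise variances are drawn from a scaled inverse-chi-square prior
(``d0_true``, ``s0sq_true``); log2 intensities are Normal with a planted
symmetric group shift of ``delta`` for DE genes; raw intensities are
``2 ** log2``.

ChIP coverage is Poisson-sampled around a per-base expectation of a flat
background plus one Gaussian-shaped bump per TSS, whose amplitude in the
knockout is attenuated by ``ko_down_attenuation`` for down-class genes
only. Input tracks carry background only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .model import (
    CoverageTrack,
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    RunLengthSignal,
    SampleInfo,
    ValidationError,
)

__all__ = [
    "ChipConfig",
    "SimConfig",
    "SimTruth",
    "simulate_annotation",
    "simulate_expression",
    "simulate_chip_coverage",
    "simulate_all",
]

# rng stream tags, so each stage draws from an independent child stream
_STREAM_ANNOTATION = 1
_STREAM_EXPRESSION = 2
_STREAM_CHIP = 3

# TSSs are kept >= half the default 6 kb profiling span away from chromosome
# ends so no gene is excluded for bounds reasons by default.
TSS_CLEARANCE = 3000


@dataclass
class ChipConfig:
    background_rate: float = 0.05  # expected hits per base, background
    peak_amplitude: float = 2.0  # extra expected hits per base at the peak
    peak_sd: float = 400.0  # Gaussian bump sd in bp
    ko_down_attenuation: float = 0.5  # rho: KO amplitude multiplier, down genes
    depth: float = 1.0  # baseline per-sample depth factor
    depth_factors: Dict[str, float] = field(default_factory=dict)  # per sample_id
    replicates: int = 1  # sequencing-style samples per genotype/assay
    asymmetric_widths: Optional[Tuple[float, float]] = None  # (5' sd, 3' sd)
    # Expected hits per base on the gene-free bulk chromosome (all assays).
    # The bulk compartment stands in for the rest of a real genome: it keeps
    # the planted TSS peaks a negligible share of each sample's total mapped
    # bases (~1e-4, as for a real library), so normalizing every track to the
    # mean total does not imprint the down-gene KO deficit on null genes.
    bulk_rate: float = 2000.0

    def validate(self) -> None:
        if self.background_rate <= 0:
            raise ValidationError("background_rate must be positive")
        if self.peak_amplitude < 0:
            raise ValidationError("peak_amplitude must be nonnegative")
        if self.peak_sd <= 0:
            raise ValidationError("peak_sd must be positive")
        if not 0.0 <= self.ko_down_attenuation <= 1.0:
            raise ValidationError("ko_down_attenuation must be in [0, 1]")
        if self.depth <= 0 or any(v <= 0 for v in self.depth_factors.values()):
            raise ValidationError("depth factors must be positive")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.bulk_rate < 0:
            raise ValidationError("bulk_rate must be >= 0")


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_chroms: int = 4
    chrom_length: int = 3_000_000
    bulk_length: int = 1_000_000  # gene-free bulk chromosome; 0 disables it
    # default spacing keeps any neighbour's 5-sd-truncated peak out of a
    # gene's +/-3 kb profiling window, so per-gene densities are independent
    min_tss_spacing: int = 5000
    replicates: int = 3  # expression replicates per genotype
    de_frac_down: float = 0.10
    de_frac_up: float = 0.05
    delta: float = 1.5  # planted |log2FC| for DE genes
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    d0_true: float = 4.0  # variance prior degrees of freedom
    s0sq_true: float = 0.05  # variance prior scale
    additive_noise_sd: float = 0.0  # raw-scale additive noise (VST stressor)
    chip: ChipConfig = field(default_factory=ChipConfig)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.chip, Mapping):
            self.chip = ChipConfig(**self.chip)

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValidationError("n_genes must be >= 0")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValidationError("need >= 1 chromosome of positive length")
        if self.replicates < 2:
            raise ValidationError("need >= 2 expression replicates per genotype")
        if self.de_frac_down < 0 or self.de_frac_up < 0:
            raise ValidationError("DE fractions must be nonnegative")
        if self.de_frac_down + self.de_frac_up >= 1:
            raise ValidationError("de_frac_down + de_frac_up must be < 1")
        if self.delta < 0:
            raise ValidationError("delta must be nonnegative")
        if self.d0_true <= 0 or self.s0sq_true <= 0:
            raise ValidationError("variance prior parameters must be positive")
        if self.baseline_log2_sd < 0 or self.additive_noise_sd < 0:
            raise ValidationError("spread parameters must be nonnegative")
        if self.min_tss_spacing < 0:
            raise ValidationError("min_tss_spacing must be >= 0")
        if self.bulk_length < 0:
            raise ValidationError("bulk_length must be >= 0")
        self.chip.validate()

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Per-gene planted ground truth."""

    table: pd.DataFrame  # gene_id, class, log2fc, variance, amp_wt, amp_ko

    def gene_ids(self, cls: str) -> List[str]:
        return list(self.table.loc[self.table["class"] == cls, "gene_id"])


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Place ``n_genes`` TSSs with >= ``TSS_CLEARANCE`` from chromosome ends
    and >= ``min_tss_spacing`` between consecutive TSSs; strands Bernoulli(0.5).
    """
    config.validate()
    rng = _rng(config, _STREAM_ANNOTATION)
    gene_chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length for c in gene_chroms}
    if config.bulk_length > 0:
        chrom_lengths["chrBulk"] = config.bulk_length
    counts = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        counts[i] += 1
    genes: List[Gene] = []
    gid = 0
    for ci, (chrom, k) in enumerate(zip(gene_chroms, counts)):
        if k == 0:
            continue
        lo = TSS_CLEARANCE
        hi = config.chrom_length - TSS_CLEARANCE - 1
        usable = hi - lo + 1 - (k - 1) * config.min_tss_spacing
        if usable < k:
            need = 2 * TSS_CLEARANCE + (k - 1) * config.min_tss_spacing + k
            raise ValidationError(
                f"{chrom}: length {config.chrom_length} too short for {k} genes; "
                f"need >= {need} bp"
            )
        base = np.sort(rng.integers(0, usable, size=k))
        tss = lo + base + np.arange(k) * config.min_tss_spacing
        strands = rng.random(k) < 0.5
        for j in range(k):
            gid += 1
            genes.append(
                Gene(
                    gene_id=f"g{gid:05d}",
                    chrom=chrom,
                    tss=int(tss[j]),
                    strand="+" if strands[j] else "-",
                    name=f"g{gid:05d}",
                )
            )
    return GenomeAnnotation(chrom_lengths=chrom_lengths, genes=genes)


def simulate_expression(
    annotation: GenomeAnnotation, config: SimConfig
) -> Tuple[ExpressionMatrix, SimTruth]:
    """Raw-scale intensity matrix (2 genotypes x ``replicates``) plus truth."""
    config.validate()
    rng = _rng(config, _STREAM_EXPRESSION)
    n = len(annotation.genes)
    gene_ids = annotation.gene_ids

    n_down = int(round(n * config.de_frac_down))
    n_up = int(round(n * config.de_frac_up))
    classes = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    classes[perm[:n_down]] = "down"
    classes[perm[n_down : n_down + n_up]] = "up"
    log2fc = np.zeros(n)
    log2fc[classes == "down"] = -config.delta
    log2fc[classes == "up"] = config.delta

    # scaled inverse-chi-square: sigma^2 = d0 * s0^2 / chi2_{d0}
    variances = config.d0_true * config.s0sq_true / rng.chisquare(config.d0_true, size=n)
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    n_rep = config.replicates
    samples = [
        SampleInfo(sample_id=f"WT_{r + 1}", genotype="WT", replicate=r + 1)
        for r in range(n_rep)
    ] + [
        SampleInfo(sample_id=f"KO_{r + 1}", genotype="KO", replicate=r + 1)
        for r in range(n_rep)
    ]
    sd = np.sqrt(variances)[:, None]
    wt = rng.normal((mu - log2fc / 2)[:, None], sd, size=(n, n_rep))
    ko = rng.normal((mu + log2fc / 2)[:, None], sd, size=(n, n_rep))
    raw = np.power(2.0, np.concatenate([wt, ko], axis=1))
    if config.additive_noise_sd > 0:
        # unsubtracted additive background: offset at 2 sd keeps clipping rare
        # while leaving a genuine additive variance component at low intensity
        noise = rng.normal(2.0 * config.additive_noise_sd, config.additive_noise_sd, size=raw.shape)
        raw = np.maximum(raw + noise, 1e-6)

    matrix = ExpressionMatrix(
        feature_ids=gene_ids, samples=samples, values=raw, scale="raw-intensity"
    )
    amp = config.chip.peak_amplitude
    rho = config.chip.ko_down_attenuation
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "class": classes,
                "log2fc": log2fc,
                "variance": variances,
                "amp_wt": np.full(n, amp),
                "amp_ko": np.where(classes == "down", amp * rho, amp),
            }
        )
    )
    return matrix, truth


def _bump_profile(sd5: float, sd3: float, half: int) -> np.ndarray:
    """Unit-amplitude bump over offsets [-half, half], 5' sd left of 0."""
    x = np.arange(-half, half + 1, dtype=np.float64)
    out = np.empty_like(x)
    left = x < 0
    out[left] = np.exp(-(x[left] ** 2) / (2 * sd5**2))
    out[~left] = np.exp(-(x[~left] ** 2) / (2 * sd3**2))
    return out


def simulate_chip_coverage(
    annotation: GenomeAnnotation, truth: SimTruth, config: SimConfig
) -> List[CoverageTrack]:
    """Poisson coverage tracks for (H3ac, input) x (WT, KO) x replicates.

    Expected signal per base is ``background + sum_g A_g * bump(b - tss_g)``
    scaled by the per-sample depth factor; Gaussian bumps are truncated at
    5 sd. For ``-``-strand genes with asymmetric widths the bump is
    mirrored so the 5' side follows the gene orientation.
    """
    config.validate()
    chip = config.chip
    rng = _rng(config, _STREAM_CHIP)
    if chip.asymmetric_widths is None:
        sd5 = sd3 = chip.peak_sd
    else:
        sd5, sd3 = chip.asymmetric_widths
    half = int(math.ceil(5 * max(sd5, sd3)))
    bump_fwd = _bump_profile(sd5, sd3, half)
    bump_rev = bump_fwd[::-1]

    amp = dict(
        zip(truth.table["gene_id"], zip(truth.table["amp_wt"], truth.table["amp_ko"]))
    )

    def background_field() -> Dict[str, np.ndarray]:
        # flat background everywhere; the gene-free bulk chromosome carries
        # the rest-of-genome signal mass in every assay
        field = {
            c: np.full(l, chip.background_rate) for c, l in annotation.chrom_lengths.items()
        }
        if "chrBulk" in field:
            field["chrBulk"] += chip.bulk_rate
        return field

    # expected (pre-depth) per-base rate per genotype/assay, dense per chrom
    expected: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    for genotype in ("WT", "KO"):
        chrom_exp = background_field()
        for g in annotation.genes:
            a = amp[g.gene_id][0 if genotype == "WT" else 1]
            if a == 0:
                continue
            bump = bump_fwd if g.strand == "+" else bump_rev
            arr = chrom_exp[g.chrom]
            lo = g.tss - half
            hi = g.tss + half + 1
            blo = max(0, -lo)
            bhi = bump.size - max(0, hi - arr.size)
            arr[max(lo, 0) : min(hi, arr.size)] += a * bump[blo:bhi]
        expected[("H3ac", genotype)] = chrom_exp
        expected[("input", genotype)] = background_field()

    tracks: List[CoverageTrack] = []
    for assay in ("H3ac", "input"):
        for genotype in ("WT", "KO"):
            for rep in range(1, chip.replicates + 1):
                sample_id = f"{assay}_{genotype}_{rep}"
                depth = chip.depth * chip.depth_factors.get(sample_id, 1.0)
                signal = {}
                for chrom in sorted(annotation.chrom_lengths):
                    lam = expected[(assay, genotype)][chrom] * depth
                    counts = rng.poisson(lam).astype(np.float64)
                    signal[chrom] = RunLengthSignal.from_dense(
                        counts, annotation.chrom_lengths[chrom]
                    )
                tracks.append(
                    CoverageTrack(
                        sample_id=sample_id, assay=assay, genotype=genotype, signal=signal
                    )
                )
    return tracks


def simulate_all(
    config: SimConfig,
) -> Tuple[GenomeAnnotation, ExpressionMatrix, SimTruth, List[CoverageTrack]]:
    annotation = simulate_annotation(config)
    matrix, truth = simulate_expression(annotation, config)
    tracks = simulate_chip_coverage(annotation, truth, config)
    return annotation, matrix, truth, tracks


def write_truth(truth: SimTruth, path: str) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> SimTruth:
    return SimTruth(table=pd.read_csv(path, sep="\t"))
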