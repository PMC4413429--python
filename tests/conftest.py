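import numpy as np
import pytest

from deprof.model import (
    CoverageTrack,
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    RunLengthSignal,
    SampleInfo,
)
from deprof.synthetic import SimConfig, simulate_all


def make_track(dense_by_chrom, sample_id="s", assay="H3ac", genotype="WT"):
    return CoverageTrack(
        sample_id=sample_id,
        assay=assay,
        genotype=genotype,
        signal={
            c: RunLengthSignal.from_dense(np.asarray(a, dtype=float))
            for c, a in dense_by_chrom.items()
        },
    )


def make_matrix(values, scale="transformed", n_wt=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    n_wt = n // 2 if n_wt is None else n_wt
    samples = [
        SampleInfo(f"WT_{i + 1}", "WT", i + 1) for i in range(n_wt)
    ] + [SampleInfo(f"KO_{i + 1}", "KO", i + 1) for i in range(n - n_wt)]
    return ExpressionMatrix(
        feature_ids=[f"g{i}" for i in range(values.shape[0])],
        samples=samples,
        values=values,
        scale=scale,
    )


@pytest.fixture
def tiny_annotation():
    return GenomeAnnotation(
        chrom_lengths={"chr1": 100_000},
        genes=[
            Gene("gA", "chr1", 10_000, "+"),
            Gene("gB", "chr1", 30_000, "-"),
            Gene("gC", "chr1", 50_000, "+"),
        ],
    )


# Small, fast simulation config for seed-loop property tests. Production
# defaults (2000 genes, 4 Mb + bulk) are exercised in test_acceptance.py.
SMALL_SIM = dict(
    n_genes=240,
    n_chroms=1,
    chrom_length=400_000,
    bulk_length=200_000,
    min_tss_spacing=1200,
    seed=0,
)


@pytest.fixture(scope="session")
def default_run():
    """One full-scale simulation shared by the slower integration tests."""
    cfg = SimConfig(seed=11)
    annotation, matrix, truth, tracks = simulate_all(cfg)
    return cfg, annotation, matrix, truth, tracks
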