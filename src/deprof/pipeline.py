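"""Stage integration: stratify TSSs by DE call, build per-genotype
composite profiles per stratum, test WT-vs-KO TSS-proximal differences,
and run the whole pipeline from a config file.

The TSS-proximal per-gene statistic is the mean windowed density over
windows whose centres lie within ``proximal_halfwidth`` (default 500 bp)
of the TSS; genotypes are compared with a paired two-sided Wilcoxon
signed-rank across genes (exact for <= 25 informative pairs, normal
approximation with continuity correction above). With one ChIP sample per
genotype this pairs genes, not samples; the manifest states this.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from . import formats_io
from .chip_profiler import (
    CompositeProfile,
    WindowGrid,
    composite_profile,
    depth_normalize,
)
from .expression_de import (
    DEResult,
    filter_de,
    fit_moderation,
    moderated_t_test,
    rsn_normalize,
    vst_transform,
    enrichment_test,
)
from .model import (
    CoverageTrack,
    ExpressionMatrix,
    GenomeAnnotation,
    ValidationError,
)
from .synthetic import SimConfig, simulate_all, write_truth

logger = logging.getLogger(__name__)

__all__ = [
    "StratifiedSets",
    "ProfileComparison",
    "PipelineError",
    "stratify_tss",
    "compare_profiles",
    "run_pipeline",
]

EXACT_WILCOXON_MAX_N = 25


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class StratifiedSets:
    down: Set[str]
    up: Set[str]
    unchanged: Set[str]
    fc_threshold: Optional[float] = None
    p_threshold: Optional[float] = None
    p_mode: Optional[str] = None
    dropped: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, Set[str]]:
        return {"down": self.down, "up": self.up, "unchanged": self.unchanged}


@dataclass
class ProfileComparison:
    stratum: str
    pairs: pd.DataFrame  # index gene_id: wt, ko
    effect: float  # median paired difference (WT - KO)
    p: float
    n_pairs: int
    flagged: bool = False  # all pairs zero-difference


def stratify_tss(de: DEResult, annotation: GenomeAnnotation) -> StratifiedSets:
    """Split analyzed genes into down/up/unchanged sets of TSS anchors.

    Gene ids absent from the annotation are dropped (and recorded).
    """
    calls = de.calls
    dropped = [g for g in calls.index if g not in annotation]
    if dropped:
        logger.warning("stratify_tss: dropped %d gene id(s) not in annotation", len(dropped))
    kept = calls.drop(index=dropped)
    sets = StratifiedSets(
        down=set(kept.index[kept == "down"]),
        up=set(kept.index[kept == "up"]),
        unchanged=set(kept.index[kept == "unchanged"]),
        fc_threshold=de.fc_threshold,
        p_threshold=de.p_threshold,
        p_mode=de.p_mode,
        dropped=dropped,
    )
    if not sets.down and not sets.up:
        raise ValidationError("no down- or upregulated genes to profile")
    return sets


def _proximal_means(profile: CompositeProfile, halfwidth: float) -> np.ndarray:
    mask = np.abs(profile.grid.offsets) <= halfwidth
    if not np.any(mask):
        raise ValidationError(
            f"no window centres within +/-{halfwidth} bp of the anchor"
        )
    return profile.per_gene_matrix[:, mask].mean(axis=1)


def compare_profiles(
    track_wt: CoverageTrack,
    track_ko: CoverageTrack,
    annotation: GenomeAnnotation,
    gene_set: Iterable[str],
    grid: WindowGrid = WindowGrid(),
    proximal_halfwidth: float = 500.0,
    stratum: str = "set",
) -> ProfileComparison:
    """Paired WT-vs-KO comparison of TSS-proximal mean densities."""
    cp_wt = composite_profile(track_wt, annotation, gene_set, grid, gene_set_id=stratum)
    cp_ko = composite_profile(track_ko, annotation, gene_set, grid, gene_set_id=stratum)
    assert cp_wt.gene_ids == cp_ko.gene_ids  # same annotation, grid, set
    wt = _proximal_means(cp_wt, proximal_halfwidth)
    ko = _proximal_means(cp_ko, proximal_halfwidth)
    pairs = pd.DataFrame({"wt": wt, "ko": ko}, index=pd.Index(cp_wt.gene_ids, name="gene_id"))
    diffs = wt - ko
    effect = float(np.median(diffs))
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return ProfileComparison(
            stratum=stratum, pairs=pairs, effect=0.0, p=1.0, n_pairs=len(diffs), flagged=True
        )
    if nonzero.size <= EXACT_WILCOXON_MAX_N:
        res = stats.wilcoxon(nonzero, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            nonzero, alternative="two-sided", method="approx", correction=True
        )
    return ProfileComparison(
        stratum=stratum,
        pairs=pairs,
        effect=effect,
        p=float(res.pvalue),
        n_pairs=len(diffs),
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


_DE_DEFAULTS = {
    "fc_threshold": 2.0,
    "p_threshold": 0.05,
    "p_mode": "raw",
    "transform": "vst",
}
_PROFILE_DEFAULTS = {
    "span": 6000,
    "window": 100,
    "slide": 20,
    "strand_flip": True,
    "depth_norm": True,
    "proximal_halfwidth": 500.0,
    "write_gene_matrices": False,
}


def run_pipeline(
    config: Union[str, Mapping],
    outdir: str,
    seed: Optional[int] = None,
) -> Dict:
    """Run simulate/load -> DE -> stratify -> profile -> compare; write a
    report directory and return the manifest dict.

    The config is YAML with a ``simulate`` block (self-generating run) or
    an ``inputs`` block (expression/metadata/annotation/coverage paths),
    plus optional ``de`` and ``profile`` blocks overriding defaults. Every
    default is echoed into the manifest.
    """
    if isinstance(config, str):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    os.makedirs(outdir, exist_ok=True)
    log_lines: List[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    manifest: Dict = {"tool": "deprof", "version": __version__}
    try:
        result = _run_stages(cfg, outdir, seed, manifest, log)
    except Exception as exc:
        with open(os.path.join(outdir, "FAILED"), "w") as fh:
            fh.write(f"{exc}\n")
        raise
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


def _stage(name: str):
    def wrap(exc: Exception) -> PipelineError:
        return PipelineError(f"stage {name!r} failed: {exc}")

    return wrap


def _run_stages(cfg, outdir, seed, manifest, log) -> Dict:
    de_cfg = {**_DE_DEFAULTS, **(cfg.get("de") or {})}
    prof_cfg = {**_PROFILE_DEFAULTS, **(cfg.get("profile") or {})}
    manifest["de"] = de_cfg
    manifest["profile"] = prof_cfg
    manifest["note"] = (
        "one ChIP sample per genotype/assay: comparisons pair genes, not samples"
    )

    # ---- stage: inputs -------------------------------------------------
    try:
        if "simulate" in cfg:
            sim_dict = dict(cfg.get("simulate") or {})
            if seed is not None:
                sim_dict["seed"] = seed
            sim = SimConfig.from_dict(sim_dict)
            manifest["seed"] = sim.seed
            manifest["simulate"] = sim.to_dict()
            annotation, matrix, truth, tracks = simulate_all(sim)
            inputs_dir = os.path.join(outdir, "inputs")
            os.makedirs(inputs_dir, exist_ok=True)
            formats_io.write_annotation(annotation, os.path.join(inputs_dir, "annotation.bed"))
            formats_io.write_expression(matrix, os.path.join(inputs_dir, "expression.tsv"))
            formats_io.write_sample_metadata(
                matrix.samples, os.path.join(inputs_dir, "samples.tsv")
            )
            write_truth(truth, os.path.join(inputs_dir, "truth.tsv"))
            for t in tracks:
                formats_io.write_coverage(
                    t, os.path.join(inputs_dir, f"{t.sample_id}.bedgraph"), "bedgraph"
                )
            log(f"simulated {len(annotation.genes)} genes, {len(tracks)} coverage tracks")
            gmt_path = (cfg.get("inputs") or {}).get("gmt")
        else:
            inputs = cfg.get("inputs") or {}
            manifest["seed"] = seed
            manifest["inputs"] = {k: v for k, v in inputs.items() if k != "coverage"}
            annotation = formats_io.read_annotation(
                inputs["annotation"], inputs.get("annotation_dialect", "bed6")
            )
            matrix = formats_io.read_expression(inputs["expression"], inputs["metadata"])
            tracks = [
                formats_io.read_coverage(
                    c["path"],
                    c.get("dialect", "bedgraph"),
                    sample_id=c.get("sample_id", os.path.basename(c["path"])),
                    assay=c["assay"],
                    genotype=c["genotype"],
                    annotation=annotation,
                )
                for c in inputs.get("coverage", [])
            ]
            truth = None
            gmt_path = inputs.get("gmt")
            log(f"loaded {len(annotation.genes)} genes, {len(tracks)} coverage tracks")
    except (KeyError, OSError, ValueError) as exc:
        raise _stage("inputs")(exc) from exc

    # ---- stage: differential expression --------------------------------
    try:
        if de_cfg["transform"] == "log2":
            transformed = vst_transform(matrix, mode="log2")
        else:
            transformed = vst_transform(matrix, mode="vst")
        normalized = rsn_normalize(transformed)
        fit = fit_moderation(normalized)
        de = moderated_t_test(normalized, fit)
        de = filter_de(
            de,
            fc_threshold=de_cfg["fc_threshold"],
            p_threshold=de_cfg["p_threshold"],
            p_mode=de_cfg["p_mode"],
        )
        de.table.to_csv(os.path.join(outdir, "de_table.tsv"), sep="\t")
        for call in ("down", "up"):
            ids = sorted(de.gene_ids(call))
            with open(os.path.join(outdir, f"genes_{call}.txt"), "w") as fh:
                fh.write("\n".join(ids) + ("\n" if ids else ""))
        manifest["moderation"] = {
            "d0": fit.d0 if math.isfinite(fit.d0) else "inf",
            "s0sq": fit.s0sq,
            "d_g": fit.d_g,
        }
        counts = de.calls.value_counts().to_dict()
        manifest["de_counts"] = {
            "down": int(counts.get("down", 0)),
            "up": int(counts.get("up", 0)),
            "unchanged": int(counts.get("unchanged", 0)),
        }
        log(
            f"DE: {manifest['de_counts']['down']} down, "
            f"{manifest['de_counts']['up']} up of {len(de.table)} genes"
        )
    except (ValidationError, ValueError) as exc:
        raise _stage("differential-expression")(exc) from exc

    # ---- stage: enrichment ---------------------------------------------
    try:
        if gmt_path:
            collection = formats_io.read_gmt(gmt_path)
            universe = set(de.table.index)
            for call in ("down", "up"):
                query = de.gene_ids(call)
                enr = enrichment_test(query, universe, collection)
                enr.table.to_csv(os.path.join(outdir, f"enrichment_{call}.tsv"), sep="\t")
            log(f"enrichment over {len(collection)} terms written")
    except (ValidationError, ValueError, OSError) as exc:
        raise _stage("enrichment")(exc) from exc

    # ---- stage: stratify -----------------------------------------------
    try:
        strata = stratify_tss(de, annotation)
        manifest["strata"] = {k: len(v) for k, v in strata.as_dict().items()}
        manifest["dropped_gene_ids"] = len(strata.dropped)
    except (ValidationError, ValueError) as exc:
        raise _stage("stratify")(exc) from exc

    if not tracks:
        log("no coverage tracks given; profiling skipped")
        return manifest

    # ---- stage: profile ------------------------------------------------
    try:
        grid = WindowGrid(
            span=prof_cfg["span"], window=prof_cfg["window"], slide=prof_cfg["slide"]
        )
        if prof_cfg["depth_norm"]:
            pre_totals = {t.sample_id: t.total_signal for t in tracks}
            tracks = depth_normalize(tracks)
            manifest["depth_norm"] = {
                "pre_totals": pre_totals,
                "post_total": tracks[0].total_signal,
            }
        profiles: Dict[Tuple[str, str], CompositeProfile] = {}
        exclusions = {}
        for t in tracks:
            for stratum, ids in strata.as_dict().items():
                if not ids:
                    continue
                cp = composite_profile(
                    t,
                    annotation,
                    ids,
                    grid,
                    strand_flip=prof_cfg["strand_flip"],
                    gene_set_id=stratum,
                )
                profiles[(t.sample_id, stratum)] = cp
                exclusions[f"{t.sample_id}:{stratum}"] = len(cp.excluded)
                out = pd.DataFrame(
                    {
                        "offset": cp.grid.offsets,
                        "median": cp.median_profile,
                        "n": cp.n_genes,
                    }
                )
                out.to_csv(
                    os.path.join(outdir, f"composite_{t.sample_id}_{stratum}.tsv"),
                    sep="\t",
                    index=False,
                )
                if prof_cfg["write_gene_matrices"]:
                    pd.DataFrame(
                        cp.per_gene_matrix,
                        index=pd.Index(cp.gene_ids, name="gene_id"),
                        columns=[f"{o:g}" for o in cp.grid.offsets],
                    ).to_csv(
                        os.path.join(outdir, f"matrix_{t.sample_id}_{stratum}.tsv"),
                        sep="\t",
                    )
        manifest["profile_exclusions"] = exclusions
        log(f"wrote {len(profiles)} composite profiles")
    except (ValidationError, ValueError) as exc:
        raise _stage("profile")(exc) from exc

    # ---- stage: compare ------------------------------------------------
    try:
        by_key: Dict[Tuple[str, str, int], CoverageTrack] = {}
        for t in tracks:
            rep = int(t.sample_id.rsplit("_", 1)[-1]) if t.sample_id.rsplit("_", 1)[-1].isdigit() else 1
            by_key[(t.assay, t.genotype, rep)] = t
        rows = []
        for (assay, genotype, rep), t in sorted(by_key.items()):
            if genotype != "WT":
                continue
            ko = by_key.get((assay, "KO", rep))
            if ko is None:
                continue
            for stratum, ids in sorted(strata.as_dict().items()):
                if not ids:
                    continue
                comp = compare_profiles(
                    t,
                    ko,
                    annotation,
                    ids,
                    grid,
                    proximal_halfwidth=prof_cfg["proximal_halfwidth"],
                    stratum=stratum,
                )
                rows.append(
                    {
                        "assay": assay,
                        "replicate": rep,
                        "stratum": stratum,
                        "n_pairs": comp.n_pairs,
                        "effect": comp.effect,
                        "p": comp.p,
                        "flagged": comp.flagged,
                    }
                )
        comparisons = pd.DataFrame(rows)
        if len(comparisons):
            comparisons["p_adj"] = multipletests(
                comparisons["p"].to_numpy(), method="fdr_bh"
            )[1]
            comparisons.to_csv(
                os.path.join(outdir, "comparisons.tsv"), sep="\t", index=False
            )
            log(f"wrote {len(comparisons)} stratum comparisons")
        manifest["n_comparisons"] = int(len(comparisons))
    except (ValidationError, ValueError) as exc:
        raise _stage("compare")(exc) from exc

    return manifest
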