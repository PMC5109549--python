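"""End-to-end runs: load or simulate, deduplicate, cluster, test, call
QTCs, and (when simulation truth is available) score the result.

All randomness flows from the config's master seed; per-stage seeds are
derived deterministically so that a config fully reproduces a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from .clustering import build_hierarchy
from .genotypes import (align, deduplicate_markers, impute_missing,
                        load_genotypes, load_phenotype)
from .hit import call_qtcs, run_hit
from .simulate import (EffectDistribution, simulate_phenotype,
                       simulate_structured_genotypes)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, fully serializable description of a run."""

    # input paths (leave None to simulate)
    genotypes: str | None = None
    genotype_format: str = "table"
    phenotype: str | None = None
    # simulation parameters (used when genotypes is None)
    sim_n_individuals: int = 300
    sim_p_markers: int = 1500
    sim_k_subpops: int = 1
    sim_fst: float = 0.0
    sim_n_causal: int = 5
    sim_effect_kind: str = "gamma"
    sim_h2: float = 0.7
    ploidy_mode: str = "inbred"
    # method parameters
    family: str = "gaussian"
    alpha: float = 0.05
    n_splits: int = 50
    gamma_min: float = 0.05
    max_partition_size: int = 2000
    cv_folds: int = 10
    seed: int = 0
    threads: int = 1
    out_prefix: str | None = None
    window_bp: int = 10_000

    def to_file(self, path) -> None:
        with open(str(path), "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _stage_seed(master: int, stage: str) -> int:
    import zlib

    h = zlib.crc32(stage.encode()) % (2**16)
    return int(np.random.SeedSequence([int(master), h]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig):
    """Execute the full pipeline; returns (QTCResult, EvalReport | None).

    Stages: load/simulate -> impute -> deduplicate -> cluster -> HIT ->
    QTC calling -> evaluation (when truth is available).  Artifacts are
    written under ``out_prefix`` when it is set.
    """
    t0 = time.time()
    out = Path(config.out_prefix) if config.out_prefix else None
    if out is not None:
        out.parent.mkdir(parents=True, exist_ok=True)
        config.to_file(str(out) + ".config.yaml")

    truth = None
    stage = "load"
    try:
        if config.genotypes is not None:
            G = load_genotypes(config.genotypes, config.genotype_format,
                               config.ploidy_mode)
            ph = load_phenotype(config.phenotype, config.family)
            G, ph = align(G, ph)
        else:
            G = simulate_structured_genotypes(
                config.sim_n_individuals, config.sim_p_markers,
                config.sim_k_subpops, config.sim_fst,
                ploidy_mode=config.ploidy_mode,
                seed=_stage_seed(config.seed, "genotypes"))
            ph, truth = simulate_phenotype(
                G, config.sim_n_causal, EffectDistribution(config.sim_effect_kind),
                config.sim_h2, seed=_stage_seed(config.seed, "phenotype"))
        logger.info("stage load done (%.1fs): %d individuals x %d markers",
                    time.time() - t0, G.n_individuals, G.p_markers)

        stage = "dedup"
        G_full = impute_missing(G)
        Gd, dup = deduplicate_markers(G_full)
        marker_positions = {
            mid: (G_full.chrom[j], int(G_full.pos_bp[j]))
            for j, mid in enumerate(G_full.marker_ids)}

        stage = "cluster"
        H = build_hierarchy(Gd, config.max_partition_size,
                            seed=_stage_seed(config.seed, "cluster"))
        if out is not None:
            (out.parent / (out.name + ".hierarchy.json")).write_text(H.to_json())

        stage = "hit"
        table = run_hit(Gd, ph, H, config.family, config.alpha,
                        config.n_splits, config.gamma_min,
                        seed=_stage_seed(config.seed, "hit"),
                        cv_folds=config.cv_folds, n_jobs=config.threads)

        stage = "call"
        qtcs = call_qtcs(table, H, Gd, dup, config.alpha, marker_positions)
        qtcs.provenance = {"seed": config.seed, "n_splits": config.n_splits,
                           "alpha": config.alpha, "gamma_min": config.gamma_min}
        if out is not None:
            qtcs.to_frame().to_csv(str(out) + ".qtcs.tsv", sep="\t", index=False)
            freq = Gd.marker_positions()
            freq["selection_freq"] = table.selection_freq
            freq.to_csv(str(out) + ".selection_freq.tsv", sep="\t", index=False)

        report = None
        if truth is not None:
            stage = "evaluate"
            # remap causal indices from the full matrix into dedup space not
            # needed: truth indices refer to G_full and matching is by position
            report = ev.match_to_truth(qtcs, truth, G_full, config.window_bp,
                                       marker_positions)
            medoids = [q.medoid_id for q in qtcs.qtcs]
            if medoids and G_full.n_individuals > len(medoids) + 1:
                report.explained_r2 = ev.explained_variance(Gd, medoids, ph.values)
            if out is not None:
                with open(str(out) + ".eval.json", "w") as fh:
                    json.dump({"tp": report.n_true_positive,
                               "fp": report.n_false_positive,
                               "precision": report.precision,
                               "explained_r2": report.explained_r2}, fh)
        logger.info("pipeline finished in %.1fs", time.time() - t0)
        return qtcs, report
    except Exception:
        logger.error("pipeline failed in stage %r", stage)
        raise
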