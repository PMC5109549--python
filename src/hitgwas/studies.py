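"""Desk-scale simulation studies of the method's operating
characteristics: family-wise error under a structured null, calibration
of the phenotype generator's heritability, and localization precision
in a high-signal unstructured population.

Each study function is deterministic given its seed and returns plain
numbers, so the same code backs the test suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np

from .clustering import build_hierarchy
from .evaluate import match_to_truth
from .genotypes import deduplicate_markers
from .hit import call_qtcs, run_hit
from .simulate import (EffectDistribution, simulate_phenotype,
                       simulate_structured_genotypes,
                       simulate_structured_null_phenotype)


def fwer_structured_null(n_replicates: int = 50, n_individuals: int = 400,
                         p_markers: int = 3000, k_subpops: int = 5,
                         fst: float = 0.1, structure_share: float = 0.3,
                         n_splits: int = 10, alpha: float = 0.05,
                         seed: int = 0, progress: bool = False) -> dict:
    """Family-wise error rate under a structured null.

    Island-model genotypes; the phenotype depends on the subpopulation
    label only (no causal marker).  Returns the percentage of replicates
    in which at least one QTC is reported at level ``alpha``, plus the
    per-replicate QTC counts.
    """
    counts = []
    for rep in range(n_replicates):
        s = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        G = simulate_structured_genotypes(
            n_individuals, p_markers, k_subpops, fst, seed=s)
        ph = simulate_structured_null_phenotype(
            G, k_subpops, structure_share, seed=s + 1)
        Gd, dup = deduplicate_markers(G)
        H = build_hierarchy(Gd, seed=s + 2)
        table = run_hit(Gd, ph, H, alpha=alpha, n_splits=n_splits, seed=s + 3)
        qtcs = call_qtcs(table, H, Gd, dup, alpha)
        counts.append(len(qtcs.qtcs))
        if progress:
            print(f"  replicate {rep + 1}/{n_replicates}: {counts[-1]} QTCs",
                  flush=True)
    counts = np.asarray(counts)
    return {
        "fwer_percent": 100.0 * float(np.mean(counts >= 1)),
        "n_replicates": n_replicates,
        "qtc_counts": counts.tolist(),
    }


def heritability_calibration(n_causal: int, effect_kind: str, h2: float,
                             n_replicates: int = 100, n_individuals: int = 500,
                             p_markers: int = 5000, k_subpops: int = 5,
                             fst: float = 0.1, seed: int = 0) -> dict:
    """Mean realized var(g)/var(y) of the phenotype generator.

    One island-model genotype matrix; ``n_replicates`` independent
    phenotype draws on top of it.
    """
    G = simulate_structured_genotypes(
        n_individuals, p_markers, k_subpops, fst,
        seed=int(np.random.SeedSequence([seed, 91]).generate_state(1)[0] % (2**31)))
    vals = []
    for rep in range(n_replicates):
        s = int(np.random.SeedSequence([seed, 7, rep]).generate_state(1)[0] % (2**31))
        ph, truth = simulate_phenotype(
            G, n_causal, EffectDistribution(effect_kind), h2, seed=s)
        vals.append(truth.realized_h2(ph.values))
    vals = np.asarray(vals)
    return {
        "mean_h2": float(vals.mean()),
        "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        "n_replicates": n_replicates,
    }


def localization_precision(n_replicates: int = 20, n_individuals: int = 500,
                           p_markers: int = 2000, n_causal: int = 5,
                           h2: float = 0.9, n_splits: int = 10,
                           alpha: float = 0.05, window_bp: int = 10_000,
                           seed: int = 0, progress: bool = False) -> dict:
    """Fraction of reported QTCs within ``window_bp`` of a causal marker
    in an unstructured, high-signal simulation."""
    total_qtcs = 0
    total_matched = 0
    for rep in range(n_replicates):
        s = int(np.random.SeedSequence([seed, 3, rep]).generate_state(1)[0] % (2**31))
        G = simulate_structured_genotypes(
            n_individuals, p_markers, k_subpops=1, fst=0.0, seed=s)
        ph, truth = simulate_phenotype(
            G, n_causal, EffectDistribution("gamma"), h2, seed=s + 1)
        Gd, dup = deduplicate_markers(G)
        H = build_hierarchy(Gd, seed=s + 2)
        table = run_hit(Gd, ph, H, alpha=alpha, n_splits=n_splits, seed=s + 3)
        qtcs = call_qtcs(table, H, Gd, dup, alpha)
        rep_eval = match_to_truth(qtcs, truth, G, window_bp)
        total_qtcs += len(qtcs.qtcs)
        total_matched += rep_eval.n_true_positive
        if progress:
            print(f"  replicate {rep + 1}/{n_replicates}: "
                  f"{rep_eval.n_true_positive}/{len(qtcs.qtcs)} QTCs matched",
                  flush=True)
    frac = total_matched / total_qtcs if total_qtcs else 1.0
    return {
        "fraction_within_window": float(frac),
        "n_qtcs": total_qtcs,
        "n_matched": total_matched,
        "n_replicates": n_replicates,
    }
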