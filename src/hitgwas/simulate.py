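"""Synthetic genotypes and phenotypes for power and error studies.

Two genotype generators are provided.  ``simulate_structured_genotypes``
draws an island-model (Balding-Nichols) population: subpopulation allele
frequencies are Beta-distributed around an ancestral frequency with
variance FST * p0 * (1 - p0), which induces exactly the feature that
matters for association testing, namely correlation between physically
unlinked markers.  ``simulate_ril_genotypes`` builds a biparental
recombinant-inbred-line population from two parental haplotypes and a
genetic map, with Poisson crossovers (no interference) and full
homozygosity.

Phenotypes are additive: a requested number of causal markers receive
effects from a Gamma(0.5, 1) or standard-normal distribution, applied to
a randomly chosen allele (random sign), and Gaussian environmental noise
is calibrated on the realized genetic variance so that the target
narrow-sense heritability h2 = var(g) / var(y) is met in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, Phenotype

__all__ = [
    "EffectDistribution", "SimTruth",
    "simulate_structured_genotypes", "subpopulation_labels",
    "simulate_phenotype", "simulate_structured_null_phenotype",
    "simulate_ril_genotypes", "simulate_binary_phenotype",
]


@dataclass
class EffectDistribution:
    """Distribution of causal additive effects.

    kind "gamma": Gamma(shape=0.5, scale=1), strictly positive draws
    whose sign comes from the random allele choice.  kind "normal":
    standard normal.
    """

    kind: str = "gamma"
    shape: float = 0.5
    scale: float = 1.0
    mean: float = 0.0
    sd: float = 1.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "gamma":
            return rng.gamma(self.shape, self.scale, size)
        if self.kind == "normal":
            return rng.normal(self.mean, self.sd, size)
        raise ValueError(f"unknown effect distribution {self.kind!r}")


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype."""

    causal_indices: np.ndarray
    effects: np.ndarray            # signed, on the dosage scale
    h2_target: float
    genetic_values: np.ndarray
    noise_variance: float

    def realized_h2(self, y: np.ndarray) -> float:
        return float(np.var(self.genetic_values, ddof=1) / np.var(y, ddof=1))


# ---------------------------------------------------------------------
# genotypes: island model
# ---------------------------------------------------------------------

def subpopulation_labels(n_individuals: int, k_subpops: int) -> np.ndarray:
    """Deterministic equal-share assignment of individuals to
    subpopulations (first block to subpopulation 0, and so on)."""
    base = n_individuals // k_subpops
    rem = n_individuals % k_subpops
    sizes = [base + (1 if k < rem else 0) for k in range(k_subpops)]
    return np.repeat(np.arange(k_subpops), sizes)


def _random_positions(p: int, n_chrom: int, chrom_length_bp: int,
                      rng: np.random.Generator):
    chrom = np.sort(rng.integers(0, n_chrom, size=p))
    pos = rng.integers(1, chrom_length_bp + 1, size=p)
    labels = np.array([f"chr{c + 1}" for c in chrom], dtype=object)
    order = np.lexsort((pos, chrom))
    chrom, pos, labels = chrom[order], pos[order], labels[order]
    # force strictly increasing positions within a chromosome
    for j in range(1, p):
        if chrom[j] == chrom[j - 1] and pos[j] <= pos[j - 1]:
            pos[j] = pos[j - 1] + 1
    return labels, pos


def simulate_structured_genotypes(n_individuals: int, p_markers: int,
                                  k_subpops: int, fst: float,
                                  maf_range=(0.05, 0.5), ploidy_mode: str = "inbred",
                                  n_chrom: int = 5, chrom_length_bp: int = 30_000_000,
                                  seed: int = 0) -> GenotypeMatrix:
    """Island-model genotype matrix with ``k_subpops`` equal-sized
    subpopulations at differentiation ``fst``."""
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1)")
    if min(n_individuals, p_markers, k_subpops) <= 0:
        raise ValueError("population sizes must be positive")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(maf_range[0], maf_range[1], size=p_markers)
    if fst == 0.0:
        freqs = np.tile(p0, (k_subpops, 1))
    else:
        a = p0 * (1.0 - fst) / fst
        b = (1.0 - p0) * (1.0 - fst) / fst
        freqs = rng.beta(a, b, size=(k_subpops, p_markers))
    labels = subpopulation_labels(n_individuals, k_subpops)
    f_ind = freqs[labels]                     # n x p
    if ploidy_mode == "inbred":
        vals = 2.0 * (rng.random((n_individuals, p_markers)) < f_ind)
    elif ploidy_mode == "outbred":
        vals = rng.binomial(2, f_ind).astype(float)
    else:
        raise ValueError(f"unknown ploidy_mode {ploidy_mode!r}")
    chrom, pos = _random_positions(p_markers, n_chrom, chrom_length_bp, rng)
    width = len(str(p_markers))
    marker_ids = [f"m{j + 1:0{width}d}" for j in range(p_markers)]
    ind_ids = [f"P{labels[i] + 1}_i{i + 1}" for i in range(n_individuals)]
    return GenotypeMatrix(vals, ind_ids, marker_ids, chrom, pos, ploidy_mode)


# ---------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------

def simulate_phenotype(G: GenotypeMatrix, n_causal: int,
                       effect_dist: EffectDistribution | None = None,
                       h2: float = 0.7, seed: int = 0) -> tuple[Phenotype, SimTruth]:
    """Additive phenotype with ``n_causal`` uniformly drawn causal
    markers and Gaussian noise calibrated to the target heritability."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must be in (0, 1]")
    if n_causal > G.p_markers:
        raise ValueError("n_causal exceeds the number of markers")
    effect_dist = effect_dist or EffectDistribution("gamma")
    rng = np.random.default_rng(seed)

    causal, beta, g = _draw_effects(G, n_causal, effect_dist, rng)
    if np.var(g) == 0.0:
        causal, beta, g = _draw_effects(G, n_causal, effect_dist, rng)
        if np.var(g) == 0.0:
            raise ValueError("all causal markers monomorphic; zero genetic variance")

    var_g = np.var(g, ddof=1)
    noise_var = var_g * (1.0 - h2) / h2
    noise = rng.normal(0.0, np.sqrt(noise_var), size=len(g)) if noise_var > 0 else 0.0
    y = g + noise
    truth = SimTruth(causal, beta, h2, g, float(noise_var))
    return Phenotype(y, "gaussian", None, list(G.individual_ids)), truth


def _draw_effects(G, n_causal, effect_dist, rng):
    causal = np.sort(rng.choice(G.p_markers, size=n_causal, replace=False))
    raw = effect_dist.draw(rng, n_causal)
    # the effect attaches to a randomly chosen allele: effect on the
    # alternate allele flips the sign on the dosage scale
    sign = rng.choice([-1.0, 1.0], size=n_causal)
    beta = raw * sign
    g = G.values[:, causal] @ beta
    return causal, beta, g


def simulate_structured_null_phenotype(G: GenotypeMatrix, k_subpops: int,
                                       structure_share: float = 0.3,
                                       seed: int = 0) -> Phenotype:
    """Phenotype depending only on the subpopulation label: per-pop means
    scaled to the requested share of the total variance, plus Gaussian
    noise with the complementary variance.  No marker is causal."""
    rng = np.random.default_rng(seed)
    labels = subpopulation_labels(G.n_individuals, k_subpops)
    means = rng.normal(size=k_subpops)
    s = means[labels].astype(float)
    s = s - s.mean()
    sd = s.std(ddof=1)
    if sd > 0:
        s *= np.sqrt(structure_share) / sd
    y = s + rng.normal(0.0, np.sqrt(1.0 - structure_share), size=G.n_individuals)
    return Phenotype(y, "gaussian", None, list(G.individual_ids))


def simulate_binary_phenotype(G: GenotypeMatrix, truth: SimTruth,
                              prevalence: float, seed: int = 0) -> Phenotype:
    """Liability-threshold case-control phenotype: liability = genetic
    value + environmental noise; the top ``prevalence`` fraction of the
    realized liabilities are cases (empirical-quantile threshold, so the
    case count is exact)."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(truth.genetic_values)
    liability = truth.genetic_values + rng.normal(
        0.0, np.sqrt(truth.noise_variance), size=n)
    n_cases = int(round(n * prevalence))
    order = np.argsort(-liability, kind="stable")
    y = np.zeros(n)
    y[order[:n_cases]] = 1.0
    return Phenotype(y, "binomial", None, list(G.individual_ids))


# ---------------------------------------------------------------------
# genotypes: biparental RILs
# ---------------------------------------------------------------------

def simulate_ril_genotypes(parent_a, parent_b, genetic_map, n_lines: int,
                           map_expansion: float = 2.0, seed: int = 0) -> GenotypeMatrix:
    """Recombinant inbred lines from two haploid parents.

    ``genetic_map`` is a DataFrame-like with columns marker_id, chrom,
    pos_bp, cm (monotone within chromosome).  Per line and chromosome
    the crossover count is Poisson(map_expansion * map length in
    Morgans) with positions uniform on the genetic map; the expansion
    factor (default 2) approximates the extra effective recombination
    accumulated during selfing to homozygosity.  Lines are fully
    homozygous, coded {0, 2}.
    """
    import pandas as pd

    gm = pd.DataFrame(genetic_map)
    a = np.asarray(parent_a, dtype=float).ravel()
    b = np.asarray(parent_b, dtype=float).ravel()
    p = len(gm)
    if not (len(a) == len(b) == p):
        raise ValueError("parent vectors must match the genetic map length")
    chroms = gm["chrom"].to_numpy()
    cm = gm["cm"].to_numpy(dtype=float)
    for c in pd.unique(chroms):
        d = np.diff(cm[chroms == c])
        if (d < 0).any():
            raise ValueError(f"genetic map not monotone on {c}")
    total_len = sum(cm[chroms == c].max() - cm[chroms == c].min()
                    for c in pd.unique(chroms))
    if np.all(a == b):
        if total_len == 0:
            warnings.warn("identical parents and zero-length map: degenerate population")
        else:
            raise ValueError("parents must differ at one marker or more")

    rng = np.random.default_rng(seed)
    vals = np.empty((n_lines, p))
    for c in pd.unique(chroms):
        sel = chroms == c
        cm_c = cm[sel]
        lo, hi = float(cm_c.min()), float(cm_c.max())
        L = (hi - lo) / 100.0            # Morgans
        hap_a, hap_b = a[sel], b[sel]
        for i in range(n_lines):
            start = int(rng.integers(2))
            n_co = rng.poisson(map_expansion * L) if L > 0 else 0
            if n_co == 0:
                hap = hap_a if start == 0 else hap_b
            else:
                xo = np.sort(rng.uniform(lo, hi, size=n_co))
                phase = (start + np.searchsorted(xo, cm_c, side="right")) % 2
                hap = np.where(phase == 0, hap_a, hap_b)
            vals[i, sel] = 2.0 * hap
    ids = [f"RIL{i + 1}" for i in range(n_lines)]
    return GenotypeMatrix(vals, ids, gm["marker_id"].astype(str).tolist(),
                          gm["chrom"].to_numpy(), gm["pos_bp"].to_numpy(), "inbred")
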