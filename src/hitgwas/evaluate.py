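"""Scoring of association results against simulation truth.

A reported cluster counts as a true positive when any of its member
markers lies within a fixed window (default 10 kb, closed) of a causal
marker on the same chromosome; candidate matches are assigned greedily
one-to-one by increasing distance, so each causal locus is credited at
most once and surplus clusters near the same locus count as false
positives.  Additional diagnostics: explained variance of the medoid
regression, the genomic relationship matrix, and the per-marker
population-structure involvement (variance explained by the leading
principal coordinates of the GRM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport", "match_to_truth", "explained_variance",
    "compute_grm", "structure_involvement", "power_curve",
]


@dataclass
class EvalReport:
    n_true_positive: int
    n_false_positive: int
    matched_pairs: list                 # (qtc_id, causal marker index, distance bp)
    precision: float
    explained_r2: float | None = None
    per_alpha: pd.DataFrame | None = field(default=None, repr=False)


def match_to_truth(qtcs, truth, G, window_bp: int = 10_000,
                   marker_positions=None) -> EvalReport:
    """Match reported QTCs to causal markers within ``window_bp``.

    ``G`` supplies marker coordinates for the causal indices in
    ``truth``; ``marker_positions`` (marker_id -> (chrom, pos)) covers
    QTC members that are not columns of ``G`` (reinstated duplicates).
    """
    if marker_positions is None:
        marker_positions = {
            mid: (G.chrom[j], int(G.pos_bp[j])) for j, mid in enumerate(G.marker_ids)}
    causal = np.asarray(truth.causal_indices, dtype=int)
    causal_pos = [(G.chrom[j], int(G.pos_bp[j])) for j in causal]

    candidates = []          # (distance, qtc order, causal order)
    for qi, q in enumerate(qtcs.qtcs):
        for ci, (cchrom, cpos) in enumerate(causal_pos):
            dists = [abs(marker_positions[mid][1] - cpos)
                     for mid in q.marker_ids
                     if marker_positions[mid][0] == cchrom]
            if dists and min(dists) <= window_bp:
                candidates.append((min(dists), qi, ci))
    candidates.sort()
    matched_q: set = set()
    matched_c: set = set()
    pairs = []
    for dist, qi, ci in candidates:
        if qi in matched_q or ci in matched_c:
            continue
        matched_q.add(qi)
        matched_c.add(ci)
        pairs.append((qtcs.qtcs[qi].qtc_id, int(causal[ci]), int(dist)))
    tp = len(pairs)
    fp = len(qtcs.qtcs) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return EvalReport(tp, fp, pairs, precision)


def explained_variance(G, marker_ids, y) -> float:
    """R-squared of the least-squares fit of the phenotype on the given
    marker columns (one regressor per QTC medoid) plus an intercept.
    Collinear columns are dropped with a warning."""
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if len(marker_ids) == 0:
        return 0.0
    pos = {mid: j for j, mid in enumerate(G.marker_ids)}
    cols = [pos[m] for m in marker_ids]
    X = G.values[:, cols]
    n = len(y)
    if n <= len(cols) + 1:
        raise ValueError("need n > number of regressors + 1")
    A = np.column_stack([np.ones(n), X])
    import scipy.linalg

    Q, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(A.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < A.shape[1]:
        logger.warning("dropped %d collinear medoid columns", A.shape[1] - rank)
    keep = piv[:rank]
    coef, *_ = np.linalg.lstsq(A[:, keep], y, rcond=None)
    resid = y - A[:, keep] @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return float(1.0 - float(resid @ resid) / tss)


def compute_grm(G) -> np.ndarray:
    """Genomic relationship matrix: cross-product of column-standardized
    genotypes divided by the number of polymorphic markers.  Symmetric,
    with mean diagonal ~ 1."""
    vals = G.values
    sd = vals.std(axis=0)
    poly = sd > 0
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers for a GRM")
    Z = (vals[:, poly] - vals[:, poly].mean(axis=0)) / sd[poly]
    return Z @ Z.T / poly.sum()


def structure_involvement(G, grm: np.ndarray, marker_index: int,
                          n_axes: int = 5) -> float:
    """Variance of one marker explained by the first ``n_axes``
    principal coordinates of the (double-centered) GRM."""
    x = G.values[:, marker_index]
    if x.std() == 0:
        raise ValueError("marker is monomorphic")
    if n_axes == 0:
        return 0.0
    n = grm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    K = J @ grm @ J
    w, V = np.linalg.eigh(K)
    axes = V[:, np.argsort(w)[::-1][:n_axes]]
    A = np.column_stack([np.ones(n), axes])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ coef
    tss = float(np.sum((x - x.mean()) ** 2))
    return float(1.0 - float(resid @ resid) / tss)


def power_curve(results_by_alpha: dict, truth, G, window_bp: int = 10_000) -> pd.DataFrame:
    """True/false positive counts per significance level.

    ``results_by_alpha`` maps alpha -> QTCResult (e.g. from calling the
    same aggregated table at nested thresholds).
    """
    rows = []
    for alpha in sorted(results_by_alpha):
        rep = match_to_truth(results_by_alpha[alpha], truth, G, window_bp)
        rows.append({"alpha": alpha, "tp": rep.n_true_positive,
                     "fp": rep.n_false_positive})
    return pd.DataFrame(rows, columns=["alpha", "tp", "fp"])
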