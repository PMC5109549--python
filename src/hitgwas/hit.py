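"""Hierarchical inference testing (HIT) over a marker hierarchy.

The association model is the high-dimensional linear model
y = X beta + e with p >> n and sparse beta.  Because correlated markers
are exchangeable explainers of the phenotype, inference is done on
clusters of a correlation hierarchy rather than on single markers:

1.  A random half of the individuals is used to screen markers with a
    cross-validated LASSO (liberal: penalty at minimum CV error).
2.  On the other half, clusters are tested top-down along the hierarchy
    with nested-model ANOVA: the selected members of a cluster are
    contrasted against all other selected markers (partial F-test for
    gaussian traits, likelihood-ratio chi-square for binomial traits).
    A tested cluster's p-value is adjusted by the selection-proportion
    factor |S| / |C and S| and monotonized against its parent; the
    descent continues only below clusters that remain significant.
3.  Splitting is repeated B times and per-node p-values are aggregated
    with the quantile rule of multi sample-splitting:
    (1 - log gamma_min) * inf_gamma Q(gamma), with
    Q(gamma) = gamma-quantile of {p_b / gamma}.

The lowest clusters still significant after aggregation are the result
clusters (QTCs); markers previously collapsed as perfect duplicates are
reinstated into the QTC of their representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

from .clustering import MarkerHierarchy, cut_children
from .genotypes import DuplicateMap, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SplitResult", "ClusterPValueTable", "QTC", "QTCResult",
    "lasso_screen", "cluster_test", "hierarchical_adjust",
    "run_split", "aggregate_pvalues", "run_hit", "call_qtcs",
]


# ---------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------

@dataclass
class SplitResult:
    """Outcome of one random sample split."""

    split_index: int
    screening_idx: np.ndarray
    testing_idx: np.ndarray
    selected: np.ndarray                  # marker indices chosen by the LASSO
    node_pvalues: dict = field(default_factory=dict)   # node_id -> adjusted p


@dataclass
class ClusterPValueTable:
    """Aggregated per-node p-values over all sample splits."""

    node_pvalues: dict                    # node_id -> aggregated p (monotone)
    selection_freq: np.ndarray            # per-marker fraction of splits selecting it
    n_splits: int
    alpha: float
    gamma_min: float
    splits: list = field(default_factory=list)


@dataclass
class QTC:
    """A quantitative trait cluster: the smallest still-significant
    cluster of correlated markers."""

    qtc_id: int
    node_id: int
    marker_ids: list                      # including reinstated duplicates
    span: dict                            # chrom -> (start_bp, end_bp)
    p_value: float
    medoid_id: str


@dataclass
class QTCResult:
    qtcs: list
    alpha: float
    provenance: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for q in self.qtcs:
            for chrom, (lo, hi) in q.span.items():
                rows.append({
                    "qtc_id": q.qtc_id, "chrom": chrom, "start": lo, "end": hi,
                    "n_markers": len(q.marker_ids), "medoid": q.medoid_id,
                    "p_aggregated": q.p_value,
                })
        return pd.DataFrame(rows, columns=[
            "qtc_id", "chrom", "start", "end", "n_markers", "medoid", "p_aggregated"])


# ---------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------

def _residualize(M: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Project out intercept and fixed covariates (unpenalized terms)."""
    n = M.shape[0]
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ beta


def lasso_screen(G_screen: np.ndarray, y_screen: np.ndarray, family: str = "gaussian",
                 covariates: np.ndarray | None = None, cv_folds: int = 10,
                 seed: int = 0, return_coefs: bool = False):
    """LASSO variable screening with cross-validated penalty.

    The penalty is chosen at minimum CV error (liberal screening; the
    downstream hierarchical test controls the error).  Columns are
    standardized internally; the intercept and fixed covariates are not
    penalized (they are projected out of the marker columns, and out of
    a gaussian response).  Returns the indices of markers with nonzero
    coefficients (and their coefficients if ``return_coefs``).
    """
    X = np.asarray(G_screen, dtype=float)
    y = np.asarray(y_screen, dtype=float).ravel()
    n = len(y)
    if n < 2 * cv_folds:
        raise ValueError(f"screening half has {n} < {2 * cv_folds} individuals")
    if family == "binomial":
        if len(np.unique(y)) < 2:
            raise ValueError("binomial phenotype has a single class")
    elif np.std(y) == 0:
        raise ValueError("constant phenotype")
    sd = X.std(axis=0)
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    Xs = _residualize(Xs, covariates)

    if family == "gaussian":
        yr = _residualize(y[:, None], covariates).ravel()
        # glmnet-style path: 100 penalties, min ratio 0.01 in the n < p regime
        eps = 0.01 if n < X.shape[1] else 1e-4
        model = LassoCV(
            alphas=100, eps=eps, tol=1e-3, max_iter=5000,
            cv=KFold(cv_folds, shuffle=True, random_state=seed % (2**31)),
        ).fit(Xs, yr)
        coefs = model.coef_
    elif family == "binomial":
        model = LogisticRegressionCV(
            Cs=25, l1_ratios=(1,), solver="liblinear", scoring="neg_log_loss",
            cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed % (2**31)),
            max_iter=200, tol=1e-3,
        ).fit(Xs, y.astype(int))
        coefs = model.coef_.ravel()
    else:
        raise ValueError(f"unknown family {family!r}")

    selected = np.flatnonzero(coefs != 0)
    if return_coefs:
        return selected, coefs[selected]
    return selected


# ---------------------------------------------------------------------
# cluster testing
# ---------------------------------------------------------------------

def _design(X: np.ndarray, cols: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = X.shape[0]
    parts = [np.ones((n, 1))]
    if covariates is not None:
        parts.append(covariates)
    if len(cols):
        parts.append(X[:, cols])
    return np.column_stack(parts)


def _rss_rank(A: np.ndarray, y: np.ndarray) -> tuple[float, int, np.ndarray]:
    """RSS, rank and kept columns of a least-squares fit with pivoted QR
    (collinear columns dropped)."""
    Q, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = (diag[0] * max(A.shape) * np.finfo(float).eps) if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = piv[:rank]
    coef, *_ = np.linalg.lstsq(A[:, keep], y, rcond=None)
    resid = y - A[:, keep] @ coef
    return float(resid @ resid), rank, keep


def _independent_columns(A: np.ndarray) -> np.ndarray:
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = (diag[0] * max(A.shape) * np.finfo(float).eps) if diag.size else 0.0
    return np.sort(piv[: int(np.sum(diag > tol))])


def cluster_test(G_test: np.ndarray, y_test: np.ndarray, family: str,
                 members_in_S, S, covariates: np.ndarray | None = None) -> float:
    """Raw p-value contrasting a cluster's selected members against all
    other selected markers.

    Gaussian: partial F-test of the model on S versus the model on
    S minus the cluster members.  Binomial: likelihood-ratio chi-square
    between the corresponding nested logistic models.  Collinear columns
    are dropped by pivoted QR, with degrees of freedom adjusted.
    """
    S = np.asarray(S, dtype=int)
    members_in_S = np.asarray(members_in_S, dtype=int)
    if members_in_S.size == 0:
        raise ValueError("empty cluster-member set")
    if not np.isin(members_in_S, S).all():
        raise ValueError("members_in_S must be a subset of S")
    X = np.asarray(G_test, dtype=float)
    y = np.asarray(y_test, dtype=float).ravel()
    n = len(y)
    others = S[~np.isin(S, members_in_S)]
    A_full = _design(X, S, covariates)
    A_red = _design(X, others, covariates)

    if family == "gaussian":
        rss1, rank1, _ = _rss_rank(A_full, y)
        if n - rank1 <= 0:
            raise ValueError(
                "no residual degrees of freedom on the testing half; reduce |S|")
        rss0, rank0, _ = _rss_rank(A_red, y)
        df_num = rank1 - rank0
        if df_num <= 0:
            return 1.0          # cluster members collinear with the rest of S
        if rss1 <= 0:
            return 0.0
        F = ((rss0 - rss1) / df_num) / (rss1 / (n - rank1))
        return float(stats.f.sf(max(F, 0.0), df_num, n - rank1))

    if family == "binomial":
        import statsmodels.api as sm

        keep1 = _independent_columns(A_full)
        keep0 = _independent_columns(A_red)
        rank1, rank0 = len(keep1), len(keep0)
        if n - rank1 <= 0:
            raise ValueError(
                "no residual degrees of freedom on the testing half; reduce |S|")
        df_num = rank1 - rank0
        if df_num <= 0:
            return 1.0
        fam = sm.families.Binomial()
        ll1 = sm.GLM(y, A_full[:, keep1], family=fam).fit(maxiter=200).llf
        ll0 = sm.GLM(y, A_red[:, keep0], family=fam).fit(maxiter=200).llf
        lr = max(2.0 * (ll1 - ll0), 0.0)
        return float(stats.chi2.sf(lr, df_num))

    raise ValueError(f"unknown family {family!r}")


def hierarchical_adjust(raw_p: float, cluster_hits: int, total_selected: int,
                        parent_adjusted_p: float = 0.0) -> float:
    """Selection-proportion multiplicity adjustment with monotonization:
    p_adj = min(1, raw_p * |S| / |C and S|), then max with the parent's
    adjusted p so that significance can only shrink down the tree."""
    if not (1 <= cluster_hits <= total_selected):
        raise ValueError("cluster_hits must be in [1, total_selected]")
    if not (0.0 <= parent_adjusted_p <= 1.0):
        raise ValueError("parent_adjusted_p outside [0, 1]")
    p_adj = min(1.0, raw_p * total_selected / cluster_hits)
    return max(p_adj, parent_adjusted_p)


# ---------------------------------------------------------------------
# sample splitting
# ---------------------------------------------------------------------

def _split_seed(master_seed: int, b: int) -> int:
    """Per-split seed derived from the master seed via a counter; stable
    under parallel execution order."""
    return int(np.random.SeedSequence([int(master_seed), int(b)]).generate_state(1)[0] % (2**31))


def run_split(G: GenotypeMatrix, y, H: MarkerHierarchy, family: str = "gaussian",
              alpha: float = 0.05, split_fraction: float = 0.5, seed: int = 0,
              covariates: np.ndarray | None = None, cv_folds: int = 10,
              split_index: int = 0) -> SplitResult:
    """One sample split: LASSO screening on a random half, top-down
    hierarchical ANOVA testing on the other half."""
    n = G.n_individuals
    if n < 20:
        raise ValueError("need at least 20 individuals for sample splitting")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_screen = int(round(n * split_fraction))
    screen_idx = np.sort(perm[:n_screen])
    test_idx = np.sort(perm[n_screen:])
    y = np.asarray(y, dtype=float).ravel()
    cov_s = covariates[screen_idx] if covariates is not None else None
    cov_t = covariates[test_idx] if covariates is not None else None

    selected, coefs = lasso_screen(
        G.values[screen_idx], y[screen_idx], family, cov_s, cv_folds,
        seed=seed, return_coefs=True)

    # keep residual degrees of freedom on the testing half
    n_test = len(test_idx)
    cap = n_test // 2
    if len(selected) > cap:
        logger.info("split %d: truncating |S|=%d to %d largest-coefficient markers",
                    split_index, len(selected), cap)
        order = np.argsort(-np.abs(coefs))[:cap]
        selected = np.sort(selected[order])

    result = SplitResult(split_index, screen_idx, test_idx, np.sort(selected))
    if len(selected) == 0:
        return result

    X_test = G.values[test_idx]
    y_t = y[test_idx]
    sel_mask = np.zeros(G.p_markers, dtype=bool)
    sel_mask[selected] = True

    # top-down descent over nodes that contain selected markers
    stack = [(H.root, 0.0)]
    while stack:
        node, parent_p = stack.pop()
        hits = H.members[node][sel_mask[H.members[node]]]
        if hits.size == 0:
            continue
        raw = cluster_test(X_test, y_t, family, hits, selected, cov_t)
        p_adj = hierarchical_adjust(raw, hits.size, len(selected), parent_p)
        result.node_pvalues[node] = p_adj
        if p_adj <= alpha:
            for child in cut_children(H, node):
                stack.append((child, p_adj))
    return result


def aggregate_pvalues(p_list, gamma_min: float = 0.05) -> float:
    """Quantile aggregation of per-split p-values.

    Q(gamma) = min(1, empirical gamma-quantile of {p_b / gamma});
    returns min(1, (1 - log gamma_min) * inf_{gamma in [gamma_min, 1]} Q(gamma)),
    the infimum evaluated on the grid of order statistics.
    """
    p = np.sort(np.asarray(p_list, dtype=float))
    B = len(p)
    if B == 0:
        raise ValueError("empty p-value list")
    if not ((p >= 0).all() and (p <= 1).all()):
        raise ValueError("p-values outside [0, 1]")
    # Q(gamma) is piecewise p_(k)/gamma for gamma in ((k-1)/B, k/B]; its
    # infimum over [gamma_min, 1] is attained on {gamma_min} U {k/B}
    k_min = int(np.ceil(gamma_min * B))
    best = p[k_min - 1] / gamma_min
    for k in range(k_min, B + 1):
        best = min(best, p[k - 1] / (k / B))
    return float(min(1.0, (1.0 - np.log(gamma_min)) * best))


def run_hit(G: GenotypeMatrix, y, H: MarkerHierarchy, family: str = "gaussian",
            alpha: float = 0.05, n_splits: int = 50, gamma_min: float = 0.05,
            seed: int = 0, covariates: np.ndarray | None = None,
            cv_folds: int = 10, split_fraction: float = 0.5,
            n_jobs: int = 1) -> ClusterPValueTable:
    """Run ``n_splits`` independent sample splits and aggregate.

    Per-split seeds derive from the master seed via a counter, so the
    result is independent of execution order (and of ``n_jobs``).
    """
    yv = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if covariates is None and getattr(y, "covariates", None) is not None:
        covariates = y.covariates
    fam = getattr(y, "family", family) if not isinstance(y, np.ndarray) else family

    def one(b):
        return run_split(G, yv, H, fam, alpha, split_fraction,
                         seed=_split_seed(seed, b), covariates=covariates,
                         cv_folds=cv_folds, split_index=b)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        splits = Parallel(n_jobs=n_jobs)(delayed(one)(b) for b in range(n_splits))
    else:
        splits = [one(b) for b in range(n_splits)]
    splits = sorted(splits, key=lambda s: s.split_index)

    tested_nodes = sorted({nd for s in splits for nd in s.node_pvalues})
    agg = {}
    for nd in tested_nodes:
        plist = [s.node_pvalues.get(nd, 1.0) for s in splits]
        agg[nd] = aggregate_pvalues(plist, gamma_min)

    # final monotonization down the tree
    for nd in H.top_down_order():
        if nd in agg:
            par = H.parent[nd]
            if par != -1 and par in agg:
                agg[nd] = max(agg[nd], agg[par])

    freq = np.zeros(G.p_markers)
    for s in splits:
        freq[s.selected] += 1.0
    freq /= n_splits

    return ClusterPValueTable(agg, freq, n_splits, alpha, gamma_min, splits)


# ---------------------------------------------------------------------
# QTC calling
# ---------------------------------------------------------------------

def call_qtcs(table: ClusterPValueTable, H: MarkerHierarchy, G: GenotypeMatrix,
              dup_map: DuplicateMap | None = None, alpha: float | None = None,
              marker_positions=None, max_height: float = 0.5) -> QTCResult:
    """Minimal significant clusters: aggregated p <= alpha and no
    significant descendant.

    A QTC is a cluster of *highly correlated* markers — markers that
    cannot be distinguished for their individual contribution to the
    phenotype.  A significant cluster whose height exceeds
    ``max_height`` (average within-cluster |r| below ``1 - max_height``)
    is a diffuse polygenic or population-structure signal, not a
    localized locus: it stays in the p-value table but is not called.
    Duplicate markers are reinstated into the QTC of their
    representative; the genomic span is reported per chromosome present
    in the QTC."""
    alpha = table.alpha if alpha is None else alpha
    sig = {nd for nd, p in table.node_pvalues.items() if p <= alpha}
    # p-values are monotone, so "no significant descendant" = no significant child
    minimal = [nd for nd in sig
               if not any(k in sig for k in H.children[nd])
               and H.height[nd] <= max_height]
    minimal.sort(key=lambda nd: int(H.members[nd][0]))

    if marker_positions is None:
        marker_positions = {
            mid: (G.chrom[j], int(G.pos_bp[j])) for j, mid in enumerate(G.marker_ids)}
    if dup_map is not None:
        # duplicates share their representative's coordinates for spans
        for rep, mates in dup_map.members.items():
            if rep in marker_positions:
                for mid, _ in mates:
                    marker_positions.setdefault(mid, marker_positions[rep])

    qtcs = []
    for i, nd in enumerate(minimal, start=1):
        member_idx = H.members[nd]
        ids = []
        for j in member_idx:
            rep = G.marker_ids[j]
            ids.extend(dup_map.expanded_ids(rep) if dup_map else [rep])
        span: dict = {}
        for mid in ids:
            chrom, pos = marker_positions[mid]
            lo, hi = span.get(chrom, (pos, pos))
            span[chrom] = (min(lo, pos), max(hi, pos))
        med = G.marker_ids[H.medoid(G, nd)]
        qtcs.append(QTC(i, nd, ids, span, table.node_pvalues[nd], med))
    return QTCResult(qtcs, alpha)
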