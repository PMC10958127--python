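"""Gene-set enrichment of sample scores against LSC transcriptional programs.

:func:`gsva_scores` implements single-sample gene-set variation analysis:
per gene, a kernel-CDF statistic expresses where each sample sits in that
gene's cross-sample distribution (Gaussian kernel, bandwidth sd/4, or a
Poisson kernel for counts); per sample, genes are ranked by that statistic
and a Kolmogorov-Smirnov-like random walk over the ranked list — inside-set
steps weighted by the symmetric rank statistic ``|p/2 - rank|`` raised to
``tau``, outside-set steps ``1/(p - |set|)`` — yields the enrichment score,
either as the sum of the maximum positive and negative deviations
(``max_diff``, the default) or the single largest deviation (``max_dev``).

The remaining operations relate enrichment profiles to score groups:
k-medoids (PAM) clustering of samples, Fisher's exact concordance between
two binary labelings, Pearson correlation matrices of gene sets and
scores, and moderated-t group differences of enrichment scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "ESMatrix",
    "ConcordanceResult",
    "gsva_scores",
    "pam_cluster",
    "fisher_concordance",
    "score_geneset_correlations",
    "groupwise_es_difference",
]


@dataclass
class ESMatrix:
    """Gene sets x samples enrichment scores.

    Sets with no member gene in the expression matrix are listed in
    ``skipped_sets`` and carry no score row.
    """

    values: pd.DataFrame
    valid_gene_counts: dict[str, int] = field(default_factory=dict)
    skipped_sets: list[str] = field(default_factory=list)

    @property
    def set_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ConcordanceResult:
    """2x2 contingency of two binary labelings with Fisher's exact test."""

    table: pd.DataFrame
    odds_ratio: float
    p_value: float
    degenerate: bool = False


def _gaussian_kcdf(X: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian kernel CDF of each sample within the gene's distribution."""
    n = X.shape[1]
    Z = np.empty_like(X, dtype=float)
    sd = X.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1e-12)
    for i in range(X.shape[0]):  # genes; pairwise within-gene comparisons
        d = (X[i][:, None] - X[i][None, :]) / h[i]
        Z[i] = scipy.stats.norm.cdf(d).sum(axis=1) / n
    return Z


def _poisson_kcdf(X: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    Z = np.empty_like(X, dtype=float)
    for i in range(X.shape[0]):
        lam = X[i] + 0.5
        Z[i] = scipy.stats.poisson.cdf(X[i][:, None], lam[None, :]).sum(axis=1) / n
    return Z


def _walk_es(order: np.ndarray, weight: np.ndarray, in_set: np.ndarray,
             tau: float, mode: str) -> float:
    """KS-like random walk over one sample's ranked gene list."""
    w = np.abs(weight[order]) ** tau
    members = in_set[order]
    denom_in = w[members].sum()
    p = len(order)
    n_out = p - members.sum()
    steps = np.where(members, w / denom_in if denom_in > 0 else 0.0, -1.0 / n_out)
    path = np.cumsum(steps)
    if mode == "max_diff":
        return float(max(path.max(), 0.0) + min(path.min(), 0.0))
    return float(path[np.argmax(np.abs(path))])


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    kcdf: str = "gaussian",
    tau: float = 1.0,
    mode: str = "max_diff",
) -> ESMatrix:
    """Single-sample enrichment scores for each gene set.

    Parameters follow the conventional defaults: Gaussian kernel CDF
    (appropriate for log-scale or microarray-like data; ``poisson`` for
    integer counts), ``tau = 1`` rank weighting, ``max_diff`` score mode.
    Needs at least 3 samples for the kernel CDF to be meaningful.
    """
    if kcdf not in ("gaussian", "poisson"):
        raise ValueError("kcdf must be 'gaussian' or 'poisson'")
    if mode not in ("max_diff", "max_dev"):
        raise ValueError("mode must be 'max_diff' or 'max_dev'")
    if expr.shape[1] < 3:
        raise ValueError("kernel CDF estimation needs at least 3 samples")
    X = expr.values.to_numpy(dtype=float)
    genes = expr.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    Z = _gaussian_kcdf(X) if kcdf == "gaussian" else _poisson_kcdf(X)
    p, n = Z.shape
    # per sample: rank genes by decreasing kernel-CDF score (rank 1 = highest);
    # ties broken by stable gene order for determinism
    orders = np.empty((n, p), dtype=int)
    ranks = np.empty((n, p))
    for j in range(n):
        order = np.argsort(-Z[:, j], kind="stable")
        orders[j] = order
        r = np.empty(p)
        r[order] = np.arange(1, p + 1)
        ranks[j] = r
    sym = np.abs(p / 2.0 - ranks)  # symmetric rank statistic, samples x genes

    rows, counts, skipped = {}, {}, []
    for name in sets.names():
        members = [g for g in sets.genes(name) if g in gene_pos]
        if not members:
            skipped.append(name)
            continue
        if len(members) >= p:
            raise ValueError(f"gene set {name!r} covers every gene; walk undefined")
        in_set = np.zeros(p, dtype=bool)
        in_set[[gene_pos[g] for g in members]] = True
        es = np.empty(n)
        for j in range(n):
            es[j] = _walk_es(orders[j], sym[j], in_set, tau, mode)
        rows[name] = es
        counts[name] = len(members)
    values = pd.DataFrame(rows, index=expr.sample_ids).T
    return ESMatrix(values=values, valid_gene_counts=counts, skipped_sets=skipped)


# ---------------------------------------------------------------------------
# PAM (k-medoids) clustering


def _pairwise_distance(V: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(V, metric="euclidean"))
    if metric == "correlation":
        return scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(V, metric="correlation"))
    raise ValueError("distance must be 'euclidean' or 'correlation'")


def pam_cluster(es: ESMatrix, k: int = 2, distance: str = "euclidean",
                seed: int = 0) -> tuple[pd.Series, list[str]]:
    """Partitioning-around-medoids clustering of samples by enrichment profile.

    Classic BUILD phase (greedy medoid seeding) followed by SWAP
    (best-improvement medoid/non-medoid exchanges until no swap lowers the
    total within-cluster distance).  Deterministic for fixed data; ties
    break toward the lower sample index.  Returns per-sample labels
    (``pam1`` ... ``pamk``) and the medoid sample ids.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    samples = es.sample_ids
    n = len(samples)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    D = _pairwise_distance(es.values.to_numpy(dtype=float).T, distance)

    # BUILD: start from the most central sample, then add greedily
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, None
        dist_to_med = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(dist_to_med - D[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    def total_cost(meds):
        return D[:, meds].min(axis=1).sum()

    cost = total_cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = total_cost(trial) - cost
                if delta < best[0] - 1e-15:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            new_cost = total_cost(medoids)
            assert new_cost <= cost + 1e-12, "SWAP must not increase total cost"
            cost = new_cost
            improved = True

    assign = np.argmin(D[:, medoids], axis=1)
    labels = pd.Series([f"pam{a + 1}" for a in assign], index=samples, name="pam")
    return labels, [samples[m] for m in medoids]


def fisher_concordance(labels_a: pd.Series, labels_b: pd.Series) -> ConcordanceResult:
    """Fisher's exact test of association between two binary labelings.

    Two-sided p by the probability-mass convention (tables at most as
    probable as the observed one).  The odds ratio is the sample odds
    ratio, reported as inf/0 symbolically when a cell is empty.  A
    constant labeling yields p = 1 with a degenerate-table warning.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b).reindex(a.index)
    if b.isna().any():
        raise ValueError("labelings cover different samples")
    la, lb = sorted(map(str, a.unique())), sorted(map(str, b.unique()))
    if len(la) > 2 or len(lb) > 2:
        raise ValueError("labels must be binary")
    table = pd.crosstab(a, b)
    if len(la) < 2 or len(lb) < 2:
        warnings.warn("degenerate 2x2 table (a labeling is constant); p = 1")
        full = table.reindex(index=la + [None][:2 - len(la)],
                             columns=lb + [None][:2 - len(lb)], fill_value=0)
        return ConcordanceResult(table=full, odds_ratio=np.nan, p_value=1.0,
                                 degenerate=True)
    t = table.to_numpy()
    _, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    num, den = t[0, 0] * t[1, 1], t[0, 1] * t[1, 0]
    if den == 0:
        oratio = np.inf if num > 0 else np.nan
    else:
        oratio = num / den
    return ConcordanceResult(table=table, odds_ratio=float(oratio), p_value=float(p))


def score_geneset_correlations(es: ESMatrix, scores: dict[str, pd.DataFrame]
                               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among gene-set ES rows and score vectors.

    Returns (r, p, adj_p) square DataFrames over gene sets + scores;
    two-sided p from the t transform; Benjamini-Hochberg adjustment across
    the upper triangle.  Zero-variance rows give missing correlations.
    """
    stack = es.values.copy()
    for name, sc in scores.items():
        col = sc["score"] if isinstance(sc, pd.DataFrame) else pd.Series(sc)
        stack.loc[name] = col.reindex(stack.columns).to_numpy(dtype=float)
    names = list(stack.index)
    m = len(names)
    r = pd.DataFrame(np.eye(m), index=names, columns=names)
    p = pd.DataFrame(np.zeros((m, m)), index=names, columns=names)
    upper = []
    for i in range(m):
        for j in range(i + 1, m):
            x, y = stack.iloc[i].to_numpy(), stack.iloc[j].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = scipy.stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            upper.append((i, j, pij))
    valid = [(i, j, q) for i, j, q in upper if not np.isnan(q)]
    adj = pd.DataFrame(np.full((m, m), np.nan), index=names, columns=names)
    np.fill_diagonal(adj.values, 0.0)
    if valid:
        qs = multipletests([q for _, _, q in valid], method="fdr_bh")[1]
        for (i, j, _), q in zip(valid, qs):
            adj.iloc[i, j] = adj.iloc[j, i] = q
    return r, p, adj


def groupwise_es_difference(es: ESMatrix, groups: pd.Series) -> pd.DataFrame:
    """Mean enrichment difference (high - low) per gene set with moderated-t p.

    The effect column ``es_diff`` is a difference of group means — the
    group-contrast heatmaps elsewhere call this a fold change, but ES
    values are signed so a literal ratio is undefined.  Skipped sets are
    reported as missing rows.  p-values use the same empirical-Bayes
    moderated t as the signature module, with gene sets as rows, and are
    BH-adjusted.
    """
    from .io import CellTypeLabels
    from .signature import differential_expression_one_vs_rest

    groups = pd.Series(groups).reindex(es.sample_ids)
    for g in ("high", "low"):
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    used = groups[groups.isin(["high", "low"])]
    mat = ExpressionMatrix(es.values[list(used.index)].copy(),
                           scale="log2")  # container reuse; units are ES
    labels = CellTypeLabels({s: str(g) for s, g in used.items()},
                            cell_types=("high", "low"))
    degs = differential_expression_one_vs_rest(mat, labels)
    high = degs[degs["cell_type"] == "high"].set_index("gene")
    out = pd.DataFrame({
        "es_diff": high["log2fc"],
        "t_stat": high["t_stat"],
        "p": high["p_value"],
        "adj_p": high["adj_p"],
    })
    out.index.name = "gene_set"
    for name in es.skipped_sets:
        out.loc[name] = np.nan
    return out
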