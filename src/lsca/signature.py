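"""Signature-matrix construction from labeled sorted reference profiles.

One-vs-rest differential expression (empirical-Bayes moderated t on log2
expression) nominates marker genes per cell type; markers passing a log2
fold-change floor and per-type adjusted-p thresholds are kept, sorted by
fold change and capped at a top-N; the signature matrix then records each
marker's per-type median expression on the linear scale, the convention
reference-based deconvolution expects.

The moderated test shrinks gene-wise sample variances toward a common prior:
with gene variance ``s_g^2`` on ``d_g`` degrees of freedom and a prior
``(d0, s0^2)`` estimated from the marginal distribution of all ``s_g^2``,
the posterior variance is ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` and the t
statistic gains ``d0`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import CellTypeLabels, ExpressionMatrix

__all__ = [
    "DEGTable",
    "SignatureMatrix",
    "PUBLISHED_ADJP_OVERRIDES",
    "differential_expression_one_vs_rest",
    "select_marker_genes",
    "build_signature_matrix",
    "build_signature",
]

#: Relaxed per-type adjusted-p thresholds used for the rare populations
#: (LSC, RApos, MPP) so each cell type retains at least a handful of markers.
PUBLISHED_ADJP_OVERRIDES = {"LSC": 0.1, "RApos": 0.1, "MPP": 0.2}

DEGTable = pd.DataFrame  # columns: cell_type, gene, log2fc, t_stat, p_value, adj_p


@dataclass
class SignatureMatrix:
    """Marker-genes x cell-types matrix of per-type median linear expression."""

    values: pd.DataFrame
    marker_lists: dict[str, list[str]] = field(default_factory=dict)
    shared_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature values must be non-negative (linear scale)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def marker_counts(self) -> pd.Series:
        return pd.Series({ct: len(g) for ct, g in self.marker_lists.items()}, name="n_markers")

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def _trigamma_inverse(target: float) -> float:
    """Solve trigamma(x) = target for x > 0 (Newton iteration)."""
    if target <= 0:
        return np.inf
    if target > 1e7:
        return 1.0 / np.sqrt(target)
    if target < 1e-6:
        return 1.0 / target
    x = 0.5 + 1.0 / target
    for _ in range(50):
        tri = scipy.special.polygamma(1, x)
        dif = tri * (1.0 - tri / target) / scipy.special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the scaled-F prior (d0, s0^2) to gene-wise sample variances.

    Moment-matches the distribution of log variances: for s2 ~ s0^2 *
    chi2_d/d scaled by an inverse-chi2 prior with d0 df, the log variances
    have known digamma/trigamma moments, so d0 solves a trigamma equation
    and s0^2 follows from the mean.  Returns (inf, geometric-mean-based
    s0^2) when the observed spread is no larger than sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(positive.mean()) if positive.size else 1.0
    z = np.log(positive)
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    target = float(e.var(ddof=1)) - float(scipy.special.polygamma(1, df / 2.0))
    if target <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(target)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(emean + scipy.special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def differential_expression_one_vs_rest(
    profiles: ExpressionMatrix,
    labels: CellTypeLabels,
    moderation: str = "eb_moderated",
) -> DEGTable:
    """Per-cell-type one-vs-rest differential expression on log2 profiles.

    Returns a long table with one row per (cell_type, gene): the log2 fold
    change (type mean minus rest mean), a (moderated or ordinary) t
    statistic, its two-sided p-value and the Benjamini-Hochberg adjusted p
    computed within each cell type.
    """
    if moderation not in ("eb_moderated", "ordinary"):
        raise ValueError("moderation must be 'eb_moderated' or 'ordinary'")
    if profiles.scale != "log2":
        raise ValueError("differential expression expects log2-scale profiles")
    labels.validate_against(profiles, min_per_type=2)
    X = profiles.values
    rows = []
    for ct in labels.present_types():
        in_samples = labels.samples_of(ct)
        out_samples = [s for s in profiles.sample_ids if labels.mapping.get(s) != ct]
        n1, n0 = len(in_samples), len(out_samples)
        if n1 < 2:
            raise ValueError(f"cell type {ct!r} has fewer than 2 replicates")
        if n0 < 2:
            raise ValueError(f"rest group for {ct!r} has fewer than 2 samples")
        g1 = X[in_samples].to_numpy(dtype=float)
        g0 = X[out_samples].to_numpy(dtype=float)
        logfc = g1.mean(axis=1) - g0.mean(axis=1)
        v1 = g1.var(axis=1, ddof=1)
        v0 = g0.var(axis=1, ddof=1)
        df_resid = n1 + n0 - 2
        s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df_resid
        sefac = np.sqrt(1.0 / n1 + 1.0 / n0)
        if moderation == "eb_moderated":
            d0, s0_2 = estimate_variance_prior(s2, df_resid)
            if np.isinf(d0):
                s2_post = np.full_like(s2, s0_2)
                df_total = np.inf
            else:
                s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
                df_total = d0 + df_resid
        else:
            s2_post = s2
            df_total = df_resid
        se = np.sqrt(s2_post) * sefac
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0),
                         np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))
        if np.isinf(df_total):
            p = 2.0 * scipy.stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * scipy.stats.t.sf(np.abs(t), df_total)
        p = np.where(np.isnan(p), 1.0, np.clip(p, 0.0, 1.0))
        adj = multipletests(p, method="fdr_bh")[1]
        rows.append(pd.DataFrame({
            "cell_type": ct, "gene": X.index, "log2fc": logfc,
            "t_stat": t, "p_value": p, "adj_p": adj,
        }))
    return pd.concat(rows, ignore_index=True)


def select_marker_genes(
    degs: DEGTable,
    logfc_min: float = 1.0,
    adjp_default: float = 0.05,
    adjp_overrides: dict[str, float] | None = None,
    top_n: int = 150,
) -> dict[str, list[str]]:
    """Threshold and rank DEGs into per-type marker lists.

    Keeps genes with ``log2fc >= logfc_min`` and ``adj_p <= threshold``
    (per-type overrides allowed), sorts by descending log2fc with ties
    broken by ascending adj_p then gene id, and truncates to ``top_n``.
    """
    adjp_overrides = dict(adjp_overrides or {})
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    cell_types = list(dict.fromkeys(degs["cell_type"]))
    unknown = set(adjp_overrides) - set(cell_types)
    if unknown:
        raise ValueError(f"adjp overrides for unknown cell types: {sorted(unknown)}")
    for thr in [adjp_default, *adjp_overrides.values()]:
        if not 0 < thr <= 1:
            raise ValueError("adjusted-p thresholds must be in (0, 1]")
    lists = {}
    for ct in cell_types:
        thr = adjp_overrides.get(ct, adjp_default)
        sub = degs.loc[(degs["cell_type"] == ct)
                       & (degs["log2fc"] >= logfc_min)
                       & (degs["adj_p"] <= thr)]
        sub = sub.sort_values(["log2fc", "adj_p", "gene"],
                              ascending=[False, True, True], kind="mergesort")
        lists[ct] = sub["gene"].head(top_n).tolist()
    return lists


def build_signature_matrix(
    profiles: ExpressionMatrix,
    labels: CellTypeLabels,
    marker_lists: dict[str, list[str]],
    shared_policy: str = "keep",
) -> SignatureMatrix:
    """Assemble a signature matrix from per-type marker lists.

    Rows are the union of the marker lists; with ``shared_policy='drop_shared'``
    genes selected for more than one type are removed.  Values are per-type
    median linear-scale expression.  Shared genes are recorded either way.
    """
    if shared_policy not in ("keep", "drop_shared"):
        raise ValueError("shared_policy must be 'keep' or 'drop_shared'")
    from .synth import celltype_medians  # per-gene per-type linear medians

    counts: dict[str, int] = {}
    for genes in marker_lists.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    shared = sorted(g for g, c in counts.items() if c > 1)
    union: list[str] = list(dict.fromkeys(g for genes in marker_lists.values() for g in genes))
    if shared_policy == "drop_shared":
        union = [g for g in union if counts[g] == 1]
    if not union:
        raise ValueError("signature would be empty (no markers after policy)")
    missing = set(union) - set(profiles.gene_ids)
    if missing:
        raise ValueError(f"markers absent from profiles: {sorted(missing)[:5]}")
    medians = celltype_medians(profiles, labels)
    cts = [ct for ct in labels.present_types() if ct in marker_lists] or labels.present_types()
    return SignatureMatrix(
        values=medians.loc[union, cts],
        marker_lists={ct: list(genes) for ct, genes in marker_lists.items()},
        shared_genes=shared,
    )


def build_signature(
    profiles: ExpressionMatrix,
    labels: CellTypeLabels,
    logfc_min: float = 1.0,
    adjp_default: float = 0.05,
    adjp_overrides: dict[str, float] | None = None,
    top_n: int = 150,
    shared_policy: str = "keep",
    moderation: str = "eb_moderated",
) -> SignatureMatrix:
    """Differential expression -> marker selection -> signature, in one call."""
    degs = differential_expression_one_vs_rest(profiles, labels, moderation=moderation)
    lists = select_marker_genes(degs, logfc_min=logfc_min, adjp_default=adjp_default,
                                adjp_overrides=adjp_overrides, top_n=top_n)
    lists = {ct: genes for ct, genes in lists.items() if genes}
    if not lists:
        raise ValueError("no markers passed the selection thresholds for any cell type")
    return build_signature_matrix(profiles, labels, lists, shared_policy=shared_policy)
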