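"""Expression-cohort integration stage.

Validates the array-level findings in an independent expression cohort:
per-gene differential expression by PR status (Welch test, Bonferroni),
restriction to kinome genes, a two-cluster stratification of samples on
the kinase-gene signature, Kaplan-Meier / log-rank survival comparison
of the clusters, and the intersection of differentially expressed kinase
genes with the upstream-kinase ranking.

The Kaplan-Meier estimator and the two-sample log-rank test are
implemented directly from their defining formulas (product-limit curve;
observed-vs-expected event counts with hypergeometric variance at each
distinct event time), so the survival comparison carries no dependency
beyond scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


def de_genes(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    stratum: dict[str, str] | None = None,
    grouping: str = "pr",
    alpha: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch test with Bonferroni control.

    ``expr`` is gene x sample (log-intensity scale).  Adjusted p-values
    are min(1, p * G) over the G tested genes; by default only rows with
    adjusted p < alpha are returned (sorted by raw p), with group means
    and lfc = mean_pos - mean_neg.  Genes with zero variance in both
    groups receive adjusted p = 1 but stay in the tested universe.
    """
    from .diffphos import split_groups

    neg_m, pos_m = split_groups(expr, annot, stratum, grouping)
    if neg_m.shape[1] < 2 or pos_m.shape[1] < 2:
        raise ValueError("need >=2 samples per group")
    neg = neg_m.to_numpy(dtype=float)
    pos = pos_m.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(pos, neg, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups
    G = expr.shape[0]
    table = pd.DataFrame(
        {
            "gene_symbol": expr.index,
            "p_raw": p,
            "p_adj": np.minimum(1.0, p * G),
            "mean_neg": neg.mean(axis=1),
            "mean_pos": pos.mean(axis=1),
        }
    )
    table["lfc"] = table["mean_pos"] - table["mean_neg"]
    table = table.sort_values("p_raw", kind="mergesort").reset_index(drop=True)
    if return_all:
        return table
    return table.loc[table["p_adj"] < alpha].reset_index(drop=True)


def filter_kinome(gene_table: pd.DataFrame, kinome_list: list[str]) -> pd.DataFrame:
    """Restrict a DE gene table to kinome genes (case-normalized symbols)."""
    if not kinome_list:
        raise ValueError("kinome list is empty")
    kinome = {g.upper() for g in kinome_list}
    mask = gene_table["gene_symbol"].astype(str).str.upper().isin(kinome)
    return gene_table.loc[mask].reset_index(drop=True)


@dataclass
class SignatureClustering:
    """Two-way sample stratification on a gene signature.

    Cluster 2 is, by convention, the cluster with the higher mean
    expression of the signature genes that are up in the PR-negative
    group — i.e. the PR-negative-enriched, putatively high-risk cluster.
    """

    selected_genes: list[str]
    labels: pd.Series  # sample -> {1, 2}
    linkage: str = "complete"
    distance: str = "euclidean"


def cluster_samples(
    expr: pd.DataFrame,
    signature_genes: list[str],
    annot: pd.DataFrame | None = None,
    grouping: str = "pr",
    k: int = 2,
) -> SignatureClustering:
    """Hierarchically cluster sample columns on the signature genes.

    Euclidean distance, complete linkage, tree cut at ``k`` (=2).  When
    an annotation is supplied, labels are oriented so cluster 2 has the
    higher mean expression of the signature genes that are up in the
    negative group; otherwise cluster 2 is the one with higher overall
    signature mean.  The orientation makes labels invariant to sample
    order.
    """
    genes = [g for g in signature_genes if g in expr.index]
    if not genes:
        raise ValueError("no signature gene present in the expression matrix")
    sub = expr.loc[genes]
    n = sub.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    data = sub.to_numpy(dtype=float).T
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        raise ValueError("degenerate clustering: fewer than k distinct clusters")

    up_in_neg = genes
    if annot is not None:
        shared = [s for s in sub.columns if s in annot.index]
        neg = [s for s in shared if annot.loc[s, grouping] == "neg"]
        pos = [s for s in shared if annot.loc[s, grouping] == "pos"]
        if neg and pos:
            diff = sub[neg].mean(axis=1) - sub[pos].mean(axis=1)
            chosen = diff.index[diff > 0].tolist()
            up_in_neg = chosen or genes
    score = sub.loc[up_in_neg].mean(axis=0)
    cluster_means = {lab: score[raw == lab].mean() for lab in np.unique(raw)}
    high = max(cluster_means, key=lambda lab: (cluster_means[lab], lab))
    labels = pd.Series(np.where(raw == high, 2, 1), index=sub.columns, name="cluster")
    return SignatureClustering(selected_genes=genes, labels=labels)


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step function as a table (time, n_at_risk, n_events,
    survival) over the distinct event times, prefixed with S(0) = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows = [(0.0, len(time), 0, 1.0)]
    surv = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_logrank(
    survival: pd.DataFrame, group_labels: pd.Series
) -> tuple[float, float, dict[object, pd.DataFrame]]:
    """Two-sample log-rank test with per-group Kaplan-Meier curves.

    ``survival`` needs columns ``time`` and ``event`` indexed by sample;
    ``group_labels`` maps the same samples to exactly two groups.  At
    each distinct event time t the observed events in group 1 are
    compared with their conditional expectation d_t * n1_t / n_t, with
    hypergeometric variance; the squared standardized sum is chi-square
    with 1 df.  Returns (chi_square, p, curves).
    """
    shared = [s for s in group_labels.index if s in survival.index]
    labels = group_labels.loc[shared]
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups, got {len(groups)}")
    sub = survival.loc[shared]
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int)
    in_g1 = (labels == groups[0]).to_numpy()
    for g, mask in zip(groups, (in_g1, ~in_g1)):
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has no subjects")
        if event[mask].sum() == 0:
            raise ValueError(f"group {g!r} has no events")

    observed = expected = variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in_g1).sum()
        d = int(np.sum((time == t) & (event == 1)))
        d1 = int(np.sum((time == t) & (event == 1) & in_g1))
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi_square = 0.0 if variance == 0 else (observed - expected) ** 2 / variance
    p = float(stats.chi2.sf(chi_square, df=1))
    curves = {
        g: km_curve(time[mask], event[mask]) for g, mask in zip(groups, (in_g1, ~in_g1))
    }
    return float(chi_square), p, curves


def intersect_candidates(
    uka_scores: pd.DataFrame, kinase_gene_table: pd.DataFrame
) -> pd.DataFrame:
    """Kinases found both by UKA and as DE kinome genes.

    Matches UKA kinase names against DE gene symbols case-insensitively;
    the result carries the UKA tau/direction and the expression lfc and
    is sorted by UKA rank.
    """
    if uka_scores.empty or kinase_gene_table.empty:
        raise ValueError("both UKA scores and the kinase gene table must be non-empty")
    uka = uka_scores.copy()
    uka["_key"] = uka["kinase"].str.upper()
    de = kinase_gene_table.copy()
    de["_key"] = de["gene_symbol"].str.upper()
    merged = uka.merge(de[["_key", "p_adj", "lfc"]], on="_key", how="inner")
    merged["direction"] = np.select(
        [merged["tau"] > 0, merged["tau"] < 0], ["higher_in_neg", "higher_in_pos"], "none"
    )
    cols = ["kinase", "rank", "tau", "direction", "combined", "p_adj", "lfc"]
    out = merged.sort_values("rank", kind="mergesort")[cols]
    return out.rename(columns={"p_adj": "expr_p_adj", "lfc": "expr_lfc"}).reset_index(drop=True)
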