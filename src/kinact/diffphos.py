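"""Per-peptide differential phosphorylation and peptide clustering.

Compares two receptor-defined sample groups (by default PR+ vs PR- within
an ER+/HER2 stratum) peptide by peptide with Welch's unequal-variance
t-test on log2 signal, reports group means and the log2 fold change
(positive group mean minus negative group mean), and controls the false
discovery rate with Benjamini-Hochberg.  Also provides the unsupervised
peptide clustering and per-cluster activity summaries used to describe
global kinase-activity structure across tumors.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["substrate_id", "gene_symbol", "p_raw", "q", "mean_neg", "mean_pos", "lfc"]


def stratum_samples(annot: pd.DataFrame, stratum: dict[str, str] | None) -> pd.DataFrame:
    """Restrict an annotation table to samples matching a stratum filter.

    ``stratum`` maps annotation columns to required values, e.g.
    ``{"her2": "neg"}`` keeps ER+/HER2- samples only.
    """
    if not stratum:
        return annot
    mask = pd.Series(True, index=annot.index)
    for col, value in stratum.items():
        if col not in annot.columns:
            raise KeyError(f"stratum column {col!r} not in annotation")
        mask &= annot[col] == value
    return annot.loc[mask]


def split_groups(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    stratum: dict[str, str] | None = None,
    grouping: str = "pr",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split matrix columns into (negative-group, positive-group) views."""
    sub = stratum_samples(annot, stratum)
    sub = sub.loc[[s for s in sub.index if s in matrix.columns]]
    neg = [s for s in sub.index if sub.loc[s, grouping] == "neg"]
    pos = [s for s in sub.index if sub.loc[s, grouping] == "pos"]
    return matrix[neg], matrix[pos]


def group_test(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    stratum: dict[str, str] | None = None,
    grouping: str = "pr",
    gene_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Welch two-group test per peptide; returns a result table.

    Missing values are dropped pairwise per peptide; a peptide is skipped
    (with a log entry) when either group retains fewer than two values.
    Columns: substrate_id, gene_symbol, p_raw, q (Benjamini-Hochberg over
    all tested peptides), mean_neg, mean_pos, lfc = mean_pos - mean_neg.
    Rows are sorted by p_raw ascending.
    """
    neg_m, pos_m = split_groups(matrix, annot, stratum, grouping)
    if neg_m.shape[1] < 2 or pos_m.shape[1] < 2:
        raise ValueError(
            f"need >=2 samples per group, got {neg_m.shape[1]} neg / {pos_m.shape[1]} pos"
        )
    rows = []
    for pep in matrix.index:
        neg = neg_m.loc[pep].dropna().to_numpy()
        pos = pos_m.loc[pep].dropna().to_numpy()
        if len(neg) < 2 or len(pos) < 2:
            logger.info("group_test: skipping %s (<2 values in a group)", pep)
            continue
        if np.var(neg) == 0 and np.var(pos) == 0:
            p = 1.0 if neg.mean() == pos.mean() else 0.0
        else:
            p = float(stats.ttest_ind(pos, neg, equal_var=False).pvalue)
        symbol = gene_map.get(pep, "") if gene_map else ""
        rows.append((pep, symbol, p, np.nan, neg.mean(), pos.mean(), pos.mean() - neg.mean()))
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not result.empty:
        result["q"] = multipletests(result["p_raw"], method="fdr_bh")[1]
        result = result.sort_values("p_raw", kind="mergesort").reset_index(drop=True)
    return result


def select_significant(
    results: pd.DataFrame, alpha: float = 0.05, on: str = "p_raw"
) -> tuple[pd.DataFrame, int]:
    """Rows with ``on`` (p_raw or q) strictly below alpha, plus the count
    of distinct non-empty gene symbols among them."""
    if results.empty:
        raise ValueError("empty result table")
    if on not in ("p_raw", "q"):
        raise ValueError("selection statistic must be 'p_raw' or 'q'")
    hits = results.loc[results[on] < alpha].sort_values("p_raw", kind="mergesort")
    n_genes = hits.loc[hits["gene_symbol"] != "", "gene_symbol"].nunique()
    return hits.reset_index(drop=True), int(n_genes)


def _complete_linkage_labels(data: np.ndarray, k: int) -> np.ndarray:
    """Hierarchical clustering (Euclidean, complete linkage) cut at k."""
    if k > data.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows ({data.shape[0]})")
    if k == 1:
        return np.ones(data.shape[0], dtype=int)
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    return hierarchy.fcluster(link, t=k, criterion="maxclust")


def cluster_peptides(matrix: pd.DataFrame, k: int = 3) -> pd.Series:
    """Cluster peptide rows into ``k`` groups (Euclidean, complete linkage).

    NaNs are imputed with the peptide's row mean for distance computation
    only.  Labels are relabelled 1..k by first appearance in input order,
    which makes the assignment deterministic for a given matrix.
    """
    if matrix.isna().all(axis=1).any():
        raise ValueError("all-missing peptide rows cannot be clustered")
    data = matrix.to_numpy(dtype=float)
    row_mean = np.nanmean(data, axis=1, keepdims=True)
    data = np.where(np.isnan(data), row_mean, data)
    raw = _complete_linkage_labels(data, k)
    labels = _relabel_by_appearance(raw)
    return pd.Series(labels, index=matrix.index, name="cluster")


def _relabel_by_appearance(labels: np.ndarray) -> np.ndarray:
    order: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
        out[i] = order[lab]
    return out


def cluster_mean_summary(
    matrix: pd.DataFrame,
    peptide_clusters: pd.Series,
    annot: pd.DataFrame,
    subgroup_cols: tuple[str, ...] = ("her2", "pr"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample mean activity of each peptide cluster, with subgroup tests.

    Returns ``(means, tests)`` where ``means`` is sample x cluster (mean
    log2 signal over the cluster's peptides, NaN-aware) and ``tests``
    holds pairwise Welch p-values between annotation subgroups (the
    cross-product of ``subgroup_cols`` values) within each cluster.
    """
    missing = peptide_clusters.index.difference(matrix.index)
    if len(missing):
        raise ValueError("cluster assignment refers to peptides absent from the matrix")
    means = {}
    for lab in sorted(peptide_clusters.unique()):
        peps = peptide_clusters.index[peptide_clusters == lab]
        if len(peps) == 0:
            logger.warning("cluster %s is empty; excluded from summary", lab)
            continue
        means[f"cluster_{lab}"] = matrix.loc[peps].mean(axis=0, skipna=True)
    mean_df = pd.DataFrame(means)

    shared = [s for s in annot.index if s in mean_df.index]
    sub = annot.loc[shared]
    keys = sub[list(subgroup_cols)].astype(str).agg("/".join, axis=1)
    test_rows = []
    for col in mean_df.columns:
        for g1, g2 in itertools.combinations(sorted(keys.unique()), 2):
            a = mean_df.loc[keys.index[keys == g1], col].dropna()
            b = mean_df.loc[keys.index[keys == g2], col].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            if a.var() == 0 and b.var() == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            test_rows.append((col, g1, g2, p))
    tests = pd.DataFrame(test_rows, columns=["cluster", "group1", "group2", "p"])
    return mean_df, tests
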