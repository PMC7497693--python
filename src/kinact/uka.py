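"""Upstream kinase analysis (UKA).

Infers which kinases drive the difference in substrate phosphorylation
between two sample groups.  Each kinase is represented by its predicted
substrate set; its difference statistic tau is the (optionally
prediction-weighted) mean of per-substrate standardized mean differences
delta = (mean_neg - mean_pos) / pooled SD, so tau > 0 means lower
activity in the positive (PR+) group.

Two permutation nulls qualify each tau:

* significance — resample the *sample* group labels; asks whether tau is
  larger than expected for this substrate set under no group effect.
* specificity — resample the *substrate* set (same size, drawn from the
  scored universe); asks whether tau is specific to the predicted
  substrates rather than a property of any random peptide set.

Each null yields a Phred-like score Q = -10*log10(max(m/M, 1/M)), where
m counts permutations with |tau_p| > |tau| strictly, out of M.  Kinases
are ranked by the sum of both scores.  Whenever the number of distinct
permutations is at most M the null is enumerated exhaustively instead of
sampled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .diffphos import split_groups

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 500


@dataclass
class KinaseSubstrateSets:
    """Kinase -> predicted substrate sets over a common substrate universe.

    ``weights`` optionally maps (kinase, substrate) to a positive
    prediction strength; unweighted members count as 1.
    """

    sets: dict[str, list[str]]
    universe: list[str]
    weights: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("substrate universe contains duplicates")
        for kinase, members in self.sets.items():
            if not members:
                raise ValueError(f"kinase {kinase!r} has an empty substrate set")
            extra = set(members) - uni
            if extra:
                raise ValueError(f"kinase {kinase!r} has substrates outside the universe: {extra}")
        if self.weights is not None:
            if any(w <= 0 for w in self.weights.values()):
                raise ValueError("prediction weights must be positive")

    def member_weights(self, kinase: str, members: list[str] | None = None) -> np.ndarray:
        members = self.sets[kinase] if members is None else members
        if self.weights is None:
            return np.ones(len(members))
        return np.array([self.weights.get((kinase, s), 1.0) for s in members])

    def restricted_to(self, universe: list[str]) -> "KinaseSubstrateSets":
        """Intersect every set with a new universe (e.g. the peptides that
        survived preprocessing); kinases left empty are dropped."""
        uni = set(universe)
        sets = {}
        for kinase, members in self.sets.items():
            kept = [s for s in members if s in uni]
            if kept:
                sets[kinase] = kept
        if not sets:
            raise ValueError("no kinase set overlaps the new universe")
        weights = None
        if self.weights is not None:
            weights = {k: w for k, w in self.weights.items() if k[1] in uni}
        return KinaseSubstrateSets(sets=sets, universe=list(universe), weights=weights)

    @classmethod
    def from_gmt(
        cls,
        sets: dict[str, list[str]],
        universe: list[str] | None = None,
        weights: dict[tuple[str, str], float] | None = None,
    ) -> "KinaseSubstrateSets":
        if universe is None:
            universe = sorted({s for members in sets.values() for s in members})
        return cls(sets=sets, universe=list(universe), weights=weights)


@dataclass(frozen=True)
class UkaScore:
    """Per-kinase UKA result: tau with its two permutation Q-scores."""

    kinase: str
    tau: float
    m_sig: int
    q_sig: float
    m_spec: int
    q_spec: float
    M_sig: int
    M_spec: int
    n_substrates: int
    rank: int = 0

    @property
    def combined(self) -> float:
        return self.q_sig + self.q_spec

    @property
    def direction(self) -> str:
        """'higher_in_neg' when tau > 0 (lower activity in the positive group)."""
        if self.tau > 0:
            return "higher_in_neg"
        if self.tau < 0:
            return "higher_in_pos"
        return "none"


def q_from_counts(m: int, M: int) -> float:
    """Permutation exceedance count -> Q = -10*log10(max(m/M, 1/M)).

    The 1/M floor caps the score at 10*log10(M) when no permutation
    exceeds the observed statistic.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0 <= m <= M:
        raise ValueError(f"m must lie in [0, M]; got m={m}, M={M}")
    return -10.0 * math.log10(max(m / M, 1.0 / M))


def permuted_deltas(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Standardized mean differences for a batch of group assignments.

    ``X`` is peptide x sample (NaN = missing); ``masks`` is a
    (n_assignments, n_samples) boolean array marking the negative group
    of each assignment.  Returns a (n_peptides, n_assignments) array of
    delta = (mean_neg - mean_pos) / pooled SD; entries with fewer than
    two usable values in either group, or zero pooled variance, are NaN.
    """
    masks = np.atleast_2d(masks)
    ok = ~np.isnan(X)
    filled = np.where(ok, X, 0.0)
    sq = filled * filled
    B = masks.T.astype(float)  # (n_samples, n_assignments)
    n1 = ok @ B
    s1 = filled @ B
    q1 = sq @ B
    n2 = ok.sum(axis=1, keepdims=True) - n1
    s2 = filled.sum(axis=1, keepdims=True) - s1
    q2 = sq.sum(axis=1, keepdims=True) - q1
    with np.errstate(invalid="ignore", divide="ignore"):
        m1, m2 = s1 / n1, s2 / n2
        v1 = np.maximum((q1 - n1 * m1**2) / (n1 - 1), 0.0)
        v2 = np.maximum((q2 - n2 * m2**2) / (n2 - 1), 0.0)
        pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        delta = (m1 - m2) / pooled
    bad = (n1 < 2) | (n2 < 2) | ~(pooled > 0)
    return np.where(bad, np.nan, delta)


def standardized_delta(X: np.ndarray, neg_mask: np.ndarray) -> np.ndarray:
    """Per-peptide standardized mean difference (neg minus pos) / pooled SD.

    Rows with fewer than two usable values in either group, or zero
    pooled variance, come out NaN (excluded from any kinase statistic).
    """
    return permuted_deltas(X, np.asarray(neg_mask, dtype=bool)[None, :])[:, 0]


def peptide_effect(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    stratum: dict[str, str] | None = None,
    grouping: str = "pr",
) -> pd.Series:
    """Per-substrate effect delta over the selected stratum.

    delta > 0 means higher phosphorylation in the negative group.
    Substrates with zero pooled variance (or <2 values per group) are
    dropped with a log entry.
    """
    neg_m, pos_m = split_groups(matrix, annot, stratum, grouping)
    if neg_m.shape[1] < 2 or pos_m.shape[1] < 2:
        raise ValueError("need >=2 samples in each group")
    X = pd.concat([neg_m, pos_m], axis=1).to_numpy(dtype=float)
    neg_mask = np.zeros(X.shape[1], dtype=bool)
    neg_mask[: neg_m.shape[1]] = True
    delta = pd.Series(standardized_delta(X, neg_mask), index=matrix.index, name="delta")
    n_drop = int(delta.isna().sum())
    if n_drop:
        logger.info("peptide_effect: %d substrate(s) excluded (degenerate variance)", n_drop)
    return delta.dropna()


def kinase_statistic(
    delta: pd.Series, members: list[str], weights: np.ndarray | None = None
) -> float:
    """tau: weighted mean of delta over the kinase's scoreable substrates."""
    scored = [s for s in members if s in delta.index]
    if not scored:
        raise ValueError("kinase substrate set has no scoreable substrates")
    values = delta.loc[scored].to_numpy()
    if weights is None:
        return float(values.mean())
    w = np.asarray(
        [w for s, w in zip(members, weights) if s in delta.index], dtype=float
    )
    return float(np.average(values, weights=w))


def _label_masks(
    n_samples: int, n_neg: int, M: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Permuted negative-group masks: exhaustive when C(n, n_neg) <= M."""
    n_splits = math.comb(n_samples, n_neg)
    if n_splits <= M:
        masks = np.zeros((n_splits, n_samples), dtype=bool)
        for i, idx in enumerate(combinations(range(n_samples), n_neg)):
            masks[i, list(idx)] = True
        return masks, True
    masks = np.zeros((M, n_samples), dtype=bool)
    for i in range(M):
        masks[i, rng.choice(n_samples, size=n_neg, replace=False)] = True
    return masks, False


def _set_taus(deltas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """NaN-aware weighted column means of a (n_members, n_assignments) block."""
    ok = ~np.isnan(deltas)
    w = weights[:, None] * ok
    denom = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        taus = np.where(ok, deltas * weights[:, None], 0.0).sum(axis=0) / denom
    return np.where(denom > 0, taus, np.nan)


def significance_score(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    members: list[str],
    M: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    stratum: dict[str, str] | None = None,
    grouping: str = "pr",
    weights: np.ndarray | None = None,
) -> tuple[float, int, float]:
    """Sample-label permutation null for one kinase set.

    Returns (tau, m_sig, q_sig) where m_sig counts permutations of the
    group labels whose |tau_p| strictly exceeds |tau|.  Exhaustive over
    all distinct label splits when there are at most M of them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neg_m, pos_m = split_groups(matrix, annot, stratum, grouping)
    if neg_m.shape[1] == 0 or pos_m.shape[1] == 0:
        raise ValueError("degenerate grouping: one group is empty")
    delta = peptide_effect(matrix, annot, stratum, grouping)
    if weights is None:
        weights = np.ones(len(members))
    tau = kinase_statistic(delta, members, weights)

    X = pd.concat([neg_m, pos_m], axis=1).to_numpy(dtype=float)
    member_idx = np.array([matrix.index.get_loc(s) for s in members if s in delta.index])
    w = np.asarray([wt for s, wt in zip(members, weights) if s in delta.index], dtype=float)
    masks, _ = _label_masks(X.shape[1], neg_m.shape[1], M, rng)
    taus = _set_taus(permuted_deltas(X, masks)[member_idx], w)
    m_sig = int(np.sum(np.abs(taus) > abs(tau)))
    M_eff = masks.shape[0]
    return tau, m_sig, q_from_counts(m_sig, M_eff)


def specificity_score(
    delta: pd.Series,
    members: list[str],
    universe: list[str],
    M: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    weights: np.ndarray | None = None,
) -> tuple[int, float]:
    """Substrate-set permutation null for one kinase set.

    Each permutation draws a uniformly random substrate subset of the
    same size from the scoreable universe and applies the kinase's
    weight multiset in drawn order; m_spec counts draws with
    |tau_p| > |tau| strictly.  Exhaustive over all subsets when there
    are at most M of them.  Undefined (error) when the set covers the
    whole universe.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scored_universe = [s for s in universe if s in delta.index]
    scored_members = [s for s in members if s in delta.index]
    if not scored_members:
        raise ValueError("kinase substrate set has no scoreable substrates")
    size = len(scored_members)
    if size >= len(scored_universe):
        raise ValueError("specificity undefined: set covers the scoreable universe")
    if weights is None:
        w = np.ones(size)
    else:
        w = np.asarray(
            [wt for s, wt in zip(members, weights) if s in delta.index], dtype=float
        )
    tau = float(np.average(delta.loc[scored_members].to_numpy(), weights=w))

    values = delta.loc[scored_universe].to_numpy()
    n_subsets = math.comb(len(scored_universe), size)
    if n_subsets <= M:
        draws = (np.array(idx) for idx in combinations(range(len(scored_universe)), size))
        M_eff = n_subsets
    else:
        draws = (
            rng.choice(len(scored_universe), size=size, replace=False) for _ in range(M)
        )
        M_eff = M
    m_spec = 0
    for idx in draws:
        tau_p = float(np.average(values[idx], weights=w))
        if abs(tau_p) > abs(tau):
            m_spec += 1
    return m_spec, q_from_counts(m_spec, M_eff)


def rank_kinases(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    sets: KinaseSubstrateSets,
    M: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    stratum: dict[str, str] | None = None,
    grouping: str = "pr",
) -> pd.DataFrame:
    """Score and rank every scoreable kinase.

    One row per kinase with a non-empty scoreable substrate set, sorted
    by combined = q_sig + q_spec descending; ties broken by |tau|
    descending, then kinase name.  The same sample-label permutations
    are shared across kinases so their significance scores are computed
    against a common null.
    """
    rng = np.random.default_rng(seed)
    delta = peptide_effect(matrix, annot, stratum, grouping)
    neg_m, pos_m = split_groups(matrix, annot, stratum, grouping)
    X = pd.concat([neg_m, pos_m], axis=1).to_numpy(dtype=float)
    n_neg = neg_m.shape[1]
    masks, _ = _label_masks(X.shape[1], n_neg, M, rng)
    M_sig = masks.shape[0]
    deltas_perm = permuted_deltas(X, masks)  # shared null across kinases

    skipped = []
    rows = []
    spec_rng = np.random.default_rng(rng.integers(2**31))
    for kinase in sorted(sets.sets):
        members = sets.sets[kinase]
        scored = [s for s in members if s in delta.index]
        if not scored:
            skipped.append(kinase)
            continue
        weights = sets.member_weights(kinase)
        tau = kinase_statistic(delta, members, weights)
        member_idx = np.array([matrix.index.get_loc(s) for s in scored])
        w = np.asarray(
            [wt for s, wt in zip(members, weights) if s in delta.index], dtype=float
        )
        taus = _set_taus(deltas_perm[member_idx], w)
        m_sig = int(np.sum(np.abs(taus) > abs(tau)))
        q_sig = q_from_counts(m_sig, M_sig)
        m_spec, q_spec = specificity_score(
            delta, members, sets.universe, M=M, seed=spec_rng, weights=weights
        )
        rows.append(
            {
                "kinase": kinase,
                "tau": tau,
                "m_sig": m_sig,
                "q_sig": q_sig,
                "m_spec": m_spec,
                "q_spec": q_spec,
                "combined": q_sig + q_spec,
                "n_substrates": len(scored),
            }
        )
    if not rows:
        raise ValueError("no kinase set overlaps the scored substrates")
    if skipped:
        logger.info("rank_kinases: skipped %d kinase(s) with no scoreable substrate", len(skipped))
    result = pd.DataFrame(rows)
    result["abs_tau"] = result["tau"].abs()
    result = result.sort_values(
        ["combined", "abs_tau", "kinase"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="abs_tau")
    result["rank"] = np.arange(1, len(result) + 1)
    result.attrs["skipped_kinases"] = skipped
    result.attrs["M"] = M
    result.attrs["seed"] = seed
    return result.reset_index(drop=True)
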