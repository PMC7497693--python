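"""Seeded synthetic-data generators.

Two generators emulate the data the pipeline consumes, with the planted
ground truth exposed so recovery can be tested:

* :func:`simulate_array` — a tyrosine-kinase peptide-array experiment
  (by default 144 substrate peptides x 29 ER+ samples x 3 technical
  replicates) with per-peptide baselines on the log2 scale, array-level
  sample effects, biological and replicate noise, saturation clipping at
  a raw-scale threshold, detection dropout, and optional driver kinases
  whose predicted substrates are shifted upward in PR-negative samples.

* :func:`simulate_cohort` — an expression/survival cohort in the style
  of a large ER+ breast-cancer consortium dataset: two PR groups, a
  planted kinase-gene signature expressed through two latent sample
  clusters correlated with PR status, and exponential survival with a
  multiplicative hazard for the high-risk cluster.

All randomness flows from a single integer seed per call; the same seed
reproduces bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import PeptideArrayExperiment
from .uka import KinaseSubstrateSets

DEFAULT_SIGNATURE_UP = ["LCK", "FGFR4", "EGFR", "ERBB2", "FGFR3", "INSR", "JAK2",
                        "KDR", "FLT1", "RET", "EPHA2", "EPHB1", "FES", "SRC"]
DEFAULT_SIGNATURE_DOWN = ["FRK", "MST1R", "NTRK2", "ROR1", "TEK", "MERTK", "DDR1",
                          "EPHB6", "TYRO3", "MUSK"]


@dataclass(frozen=True)
class ArraySimConfig:
    """Conditions for the synthetic peptide-array experiment.

    Defaults mirror the profiled study design: 144 substrate peptides,
    29 ER+ samples (mixed HER2/PR status) and 3 technical replicates.
    Effects are log2-scale mean shifts applied to a driver kinase's
    substrates in PR-negative samples; with the default noise budget the
    per-sample log2 SD of a collapsed peptide is ~1, so an effect of 1.0
    is approximately a standardized effect of 1.
    """

    n_peptides: int = 144
    n_samples: int = 29
    n_replicates: int = 3
    pr_pos_frac: float = 0.62
    her2_neg_frac: float = 0.76
    n_kinases: int = 20
    substrates_per_kinase: int = 6
    set_overlap: float = 0.0
    driver_kinases: dict[str, float] = field(default_factory=dict)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.8
    sample_effect_sd: float = 0.3
    biological_sd: float = 0.95
    replicate_noise_sd: float = 0.5
    saturation_threshold: float = 4096.0
    dropout_prob: float = 0.05
    low_signal_frac: float = 0.25
    low_signal_dropout: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pr_pos_frac", "her2_neg_frac", "set_overlap",
                     "dropout_prob", "low_signal_frac", "low_signal_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.substrates_per_kinase > self.n_peptides:
            raise ValueError("substrates_per_kinase exceeds n_peptides")
        for effect in self.driver_kinases.values():
            if not np.isfinite(effect):
                raise ValueError("driver effects must be finite")


def _peptide_ids(n: int, rng: np.random.Generator) -> list[str]:
    """Synthetic substrate IDs in the canonical <name>_<start>_<end> form."""
    ids = []
    for i in range(n):
        start = int(rng.integers(1, 1200))
        ids.append(f"PEP{i + 1:03d}_{start}_{start + 12}")
    return ids


def simulate_ks_map(cfg: ArraySimConfig, seed: int | None = None,
                    peptide_ids: list[str] | None = None) -> KinaseSubstrateSets:
    """Random kinase -> substrate-set map over the peptide universe.

    ``set_overlap`` = 0 gives pairwise-disjoint sets (requires
    n_kinases * substrates_per_kinase <= n_peptides); a positive value
    is the fraction of each set drawn from a small shared "promiscuous"
    peptide pool, producing controlled overlap between kinases.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if peptide_ids is None:
        peptide_ids = _peptide_ids(cfg.n_peptides, rng)
    names = sorted(set(cfg.driver_kinases))
    names += [f"KIN{i + 1:02d}" for i in range(cfg.n_kinases - len(names))]
    if len(names) != cfg.n_kinases:
        raise ValueError("more driver kinases than n_kinases")
    spk = cfg.substrates_per_kinase
    shuffled = list(rng.permutation(peptide_ids))
    sets: dict[str, list[str]] = {}
    if cfg.set_overlap == 0.0:
        if cfg.n_kinases * spk > cfg.n_peptides:
            raise ValueError("disjoint sets infeasible: n_kinases * substrates_per_kinase "
                             "> n_peptides")
        for i, name in enumerate(names):
            sets[name] = sorted(shuffled[i * spk:(i + 1) * spk])
    else:
        n_shared = int(round(cfg.set_overlap * spk))
        pool_size = min(len(shuffled), max(2 * spk, 10))
        pool, rest = shuffled[:pool_size], shuffled[pool_size:]
        for name in names:
            shared = list(rng.choice(pool, size=min(n_shared, len(pool)), replace=False))
            n_own = spk - len(shared)
            own = list(rng.choice(rest, size=n_own, replace=False)) if n_own else []
            sets[name] = sorted(set(shared + own))
    return KinaseSubstrateSets(sets=sets, universe=list(peptide_ids))


def _status_column(n: int, pos_frac: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(pos_frac * n))
    col = np.array(["pos"] * n_pos + ["neg"] * (n - n_pos))
    return rng.permutation(col)


def simulate_array(
    cfg: ArraySimConfig, ks_map: KinaseSubstrateSets | None = None
) -> tuple[PeptideArrayExperiment, pd.DataFrame, dict]:
    """Generate a peptide-array experiment with annotation and ground truth.

    Returns ``(experiment, annotation, ground_truth)``; the ground truth
    records the kinase map, driver kinases with their affected peptides,
    the low-detection peptides, and the planted per-peptide group shift.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    annot = pd.DataFrame(
        {
            "er": ["pos"] * cfg.n_samples,
            "pr": _status_column(cfg.n_samples, cfg.pr_pos_frac, rng),
            "her2": _status_column(cfg.n_samples, 1.0 - cfg.her2_neg_frac, rng),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if ks_map is None:
        ks_map = simulate_ks_map(cfg, seed=int(rng.integers(2**31)))
    peptide_ids = list(ks_map.universe)
    if len(peptide_ids) != cfg.n_peptides:
        raise ValueError("kinase map universe size does not match n_peptides")

    pep_pos = {p: i for i, p in enumerate(peptide_ids)}
    affected: dict[str, list[str]] = {}
    shift = np.zeros((cfg.n_peptides, cfg.n_samples))
    pr_neg = (annot["pr"] == "neg").to_numpy()
    for kinase, effect in cfg.driver_kinases.items():
        members = ks_map.sets[kinase]
        affected[kinase] = list(members)
        for s in members:
            shift[pep_pos[s], pr_neg] += effect

    driver_peptides = {p for peps in affected.values() for p in peps}
    eligible = [i for i, p in enumerate(peptide_ids) if p not in driver_peptides]
    n_low = int(round(cfg.low_signal_frac * cfg.n_peptides))
    low_idx = rng.choice(eligible, size=min(n_low, len(eligible)), replace=False)
    dropout = np.full(cfg.n_peptides, cfg.dropout_prob)
    dropout[low_idx] = cfg.low_signal_dropout

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_peptides)
    sample_effect = rng.normal(0.0, cfg.sample_effect_sd, size=cfg.n_samples)
    bio = rng.normal(0.0, cfg.biological_sd, size=(cfg.n_peptides, cfg.n_samples))
    rep = rng.normal(
        0.0, cfg.replicate_noise_sd,
        size=(cfg.n_peptides, cfg.n_samples, cfg.n_replicates),
    )
    log2_signal = (
        baseline[:, None, None]
        + sample_effect[None, :, None]
        + shift[:, :, None]
        + bio[:, :, None]
        + rep
    )
    raw = np.exp2(log2_signal)
    saturated = raw >= cfg.saturation_threshold
    raw = np.where(saturated, cfg.saturation_threshold, raw)
    # detection dropout acts on whole spots: a (peptide, sample) pair is
    # either measured in all replicates or not detected at all
    missing = rng.random((cfg.n_peptides, cfg.n_samples)) < dropout[:, None]
    raw[missing] = np.nan
    saturated &= ~missing[:, :, None]

    exp = PeptideArrayExperiment(raw, saturated, peptide_ids, sample_ids)
    ground_truth = {
        "ks_map": ks_map,
        "driver_kinases": dict(cfg.driver_kinases),
        "affected_peptides": affected,
        "low_signal_peptides": sorted(peptide_ids[i] for i in low_idx),
        "group_shift_log2": pd.DataFrame(shift, index=peptide_ids, columns=sample_ids),
        "baseline_log2": pd.Series(baseline, index=peptide_ids),
    }
    return exp, annot, ground_truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Conditions for the synthetic expression/survival cohort.

    The cohort is a scaled-down stand-in for a large ER+ consortium
    dataset: ``n_samples`` ER+ samples, mostly HER2-negative, ~30%
    PR-negative.  ``signature_effects`` maps gene symbol -> log-scale
    shift carried by the high-risk latent cluster (positive = up in the
    PR-negative-enriched cluster); the default signature holds 24 kinase
    genes.  ``cluster_flip_prob`` is the chance a sample's latent
    cluster disagrees with its PR status.
    """

    n_genes: int = 1000
    n_samples: int = 300
    pr_neg_frac: float = 0.30
    her2_neg_frac: float = 0.93
    signature_effects: dict[str, float] = field(default_factory=dict)
    signature_effect_size: float = 2.5
    cluster_flip_prob: float = 0.15
    cluster_hazard_ratio: float = 2.0
    baseline_hazard: float = 0.08
    censoring_rate: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if not 0.0 <= self.cluster_flip_prob <= 1.0:
            raise ValueError("cluster_flip_prob must be in [0, 1]")


def default_signature(effect_size: float = 2.5) -> dict[str, float]:
    """The default planted 24-kinase-gene signature.

    14 genes up and 10 down in the high-risk (PR-negative-enriched)
    cluster; includes LCK/FGFR4 (up) and FRK/MST1R (down).
    """
    sig = {g: effect_size for g in DEFAULT_SIGNATURE_UP}
    sig.update({g: -effect_size for g in DEFAULT_SIGNATURE_DOWN})
    return sig


def simulate_cohort(
    cfg: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (expression, annotation, survival, ground_truth).

    Expression is Gaussian on a log-intensity scale around per-gene
    baselines; signature genes are shifted in the high-risk latent
    cluster, which is a noisy copy of PR-negativity.  Survival times are
    exponential with the hazard multiplied by ``cluster_hazard_ratio``
    in the high-risk cluster; independent exponential censoring is
    scaled to the requested censoring fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    signature = cfg.signature_effects or default_signature(cfg.signature_effect_size)
    if len(signature) > cfg.n_genes:
        raise ValueError("more signature genes than n_genes")

    sample_ids = [f"P{i + 1:04d}" for i in range(cfg.n_samples)]
    annot = pd.DataFrame(
        {
            "er": ["pos"] * cfg.n_samples,
            "pr": _status_column(cfg.n_samples, 1.0 - cfg.pr_neg_frac, rng),
            "her2": _status_column(cfg.n_samples, 1.0 - cfg.her2_neg_frac, rng),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    pr_neg = (annot["pr"] == "neg").to_numpy()
    flip = rng.random(cfg.n_samples) < cfg.cluster_flip_prob
    high_risk = pr_neg ^ flip  # latent cluster 2

    sig_genes = sorted(signature)
    n_bg = cfg.n_genes - len(sig_genes)
    genes = sig_genes + [f"GENE{i + 1:04d}" for i in range(n_bg)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    expr = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    for gi, g in enumerate(sig_genes):
        expr[gi, high_risk] += signature[g]
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene_symbol"), columns=sample_ids)

    rate = cfg.baseline_hazard * np.where(high_risk, cfg.cluster_hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rate)
    if cfg.censoring_rate > 0:
        cens_rate = cfg.censoring_rate / (1.0 - cfg.censoring_rate) * rate
        censor_time = rng.exponential(1.0 / cens_rate)
    else:
        censor_time = np.full(cfg.n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    surv = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(sample_ids, name="sample_id")
    )

    ground_truth = {
        "signature_effects": dict(signature),
        "signature_genes": sig_genes,
        "high_risk_cluster": pd.Series(
            np.where(high_risk, 2, 1), index=sample_ids, name="cluster"
        ),
        "hazard_ratio": cfg.cluster_hazard_ratio,
    }
    return expr_df, annot, surv, ground_truth
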