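"""Peptide-array preprocessing.

Turns raw end-level kinetic signal tensors (peptide x sample x technical
replicate) into a per-sample log2 activity matrix, applying three quality
rules in order:

1. saturation masking  — saturated spots are treated as missing, peptides
   with no usable measurement left are dropped;
2. replicate collapse  — technical replicates with high dispersion lose
   their most outlying member, the rest are averaged and log2-transformed;
3. detection filter    — peptides detected in fewer than ``min_detect_frac``
   of the samples (default 25%) are removed.

Missing values are carried as NaN throughout.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PEPTIDE_ID_RE = re.compile(r"^(?P<name>.+)_(?P<start>\d+)_(?P<end>\d+)$")


class PeptideIdError(ValueError):
    """Raised when a substrate peptide ID cannot be parsed."""


@dataclass(frozen=True)
class SubstrateIdentity:
    """Identity of an array substrate peptide.

    ``protein_name`` is the short name embedded in the peptide ID (e.g.
    ``"B3AT"``); ``gene_symbol`` is the encoding gene (e.g. ``"SLC4A1"``)
    and is only filled when a mapping table is supplied.  Residue bounds
    are 1-based inclusive positions of the peptide within the protein.
    """

    protein_name: str
    start_residue: int
    end_residue: int
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise PeptideIdError(
                f"start residue {self.start_residue} > end residue "
                f"{self.end_residue} for {self.protein_name!r}"
            )
        if self.start_residue < 1:
            raise PeptideIdError(
                f"residue positions are 1-based; got {self.start_residue}"
            )


def parse_peptide_id(peptide_id: str, gene_map: dict[str, str] | None = None) -> SubstrateIdentity:
    """Parse a ``<name>_<start>_<end>`` substrate peptide ID.

    Parameters
    ----------
    peptide_id
        ID such as ``"CDK2_8_20"`` — protein short name followed by the
        1-based inclusive residue range of the spotted peptide.
    gene_map
        Optional protein-name -> gene-symbol mapping; the gene symbol is
        left unresolved (``None``) when absent.
    """
    m = _PEPTIDE_ID_RE.match(peptide_id)
    if m is None:
        raise PeptideIdError(
            f"peptide ID {peptide_id!r} does not match '<name>_<start>_<end>'"
        )
    name = m.group("name")
    start, end = int(m.group("start")), int(m.group("end"))
    symbol = gene_map.get(name) if gene_map else None
    return SubstrateIdentity(name, start, end, gene_symbol=symbol)


@dataclass
class PeptideArrayExperiment:
    """Raw peptide-array experiment: signal tensor plus saturation flags.

    ``signal`` has shape (n_peptides, n_samples, n_replicates) and holds
    nonnegative end-level kinetic values (raw fluorescence or already
    log2, see :class:`PreprocessConfig.input_scale`); NaN marks missing
    spots.  ``saturated`` has the same shape.
    """

    signal: np.ndarray
    saturated: np.ndarray
    peptide_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        if self.signal.ndim != 3:
            raise ValueError("signal must be a 3-d peptide x sample x replicate tensor")
        if self.signal.shape != self.saturated.shape:
            raise ValueError("signal and saturated tensors must share a shape")
        if len(self.peptide_ids) != self.signal.shape[0]:
            raise ValueError("peptide_ids length does not match signal tensor")
        if len(self.sample_ids) != self.signal.shape[1]:
            raise ValueError("sample_ids length does not match signal tensor")
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise ValueError("peptide_ids must be unique")

    @property
    def n_replicates(self) -> int:
        return self.signal.shape[2]


@dataclass(frozen=True)
class PreprocessConfig:
    """Quality-filter thresholds for array preprocessing.

    min_detect_frac
        Minimum fraction of samples a peptide must be detected in
        (boundary inclusive). Default 0.25.
    detection_floor
        A value counts as detected when non-missing and strictly above
        this floor (same scale as the collapsed matrix).
    saturation_threshold
        Raw-scale value at/above which spots were flagged saturated at
        load time; informational once flags exist.
    replicate_cv_max
        Maximum coefficient of variation (raw scale, sample SD / mean)
        tolerated across technical replicates before the replicate
        farthest from the median is excluded.
    input_scale
        ``"raw"`` means collapse averages raw values and log2-transforms
        the mean; ``"log2"`` means values are already log2 and are
        averaged as-is (the CV rule still operates on 2**value).
    """

    min_detect_frac: float = 0.25
    detection_floor: float = 0.0
    saturation_threshold: float = float("inf")
    replicate_cv_max: float = 0.5
    input_scale: str = "raw"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_detect_frac <= 1.0):
            raise ValueError("min_detect_frac must be in (0, 1]")
        if self.detection_floor < 0 or self.replicate_cv_max <= 0:
            raise ValueError("thresholds must be nonnegative (cv_max positive)")
        if self.input_scale not in ("raw", "log2"):
            raise ValueError("input_scale must be 'raw' or 'log2'")


def remove_saturated(exp: PeptideArrayExperiment) -> PeptideArrayExperiment:
    """Mask saturated spots and drop peptides with no measurement left.

    Saturated entries become NaN so every downstream aggregation treats
    them as missing; a peptide whose entries are all masked/missing is
    removed entirely.  Sample order is never touched.
    """
    signal = exp.signal.copy()
    signal[exp.saturated] = np.nan
    keep = ~np.all(np.isnan(signal), axis=(1, 2))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("remove_saturated: dropped %d fully-saturated peptide(s)", n_dropped)
    return PeptideArrayExperiment(
        signal=signal[keep],
        saturated=np.zeros(signal[keep].shape, dtype=bool),
        peptide_ids=[p for p, k in zip(exp.peptide_ids, keep) if k],
        sample_ids=list(exp.sample_ids),
    )


def collapse_replicates(exp: PeptideArrayExperiment, cfg: PreprocessConfig) -> pd.DataFrame:
    """Collapse the replicate axis into a peptide x sample log2 matrix.

    Per (peptide, sample) cell: if the raw-scale coefficient of variation
    across non-missing replicates exceeds ``cfg.replicate_cv_max``, the
    replicate farthest from the replicate median is excluded; the
    remaining replicates are averaged (raw scale) and log2-transformed.
    Cells with no usable replicate come out NaN.
    """
    n_pep, n_samp, _ = exp.signal.shape
    out = np.full((n_pep, n_samp), np.nan)
    for i in range(n_pep):
        for j in range(n_samp):
            out[i, j] = _collapse_cell(exp.signal[i, j], cfg)
    n_empty = int(np.isnan(out).sum())
    if n_empty:
        logger.debug("collapse_replicates: %d cell(s) left missing", n_empty)
    return pd.DataFrame(out, index=list(exp.peptide_ids), columns=list(exp.sample_ids))


def _collapse_cell(reps: np.ndarray, cfg: PreprocessConfig) -> float:
    vals = reps[~np.isnan(reps)]
    if vals.size == 0:
        return np.nan
    raw = np.exp2(vals) if cfg.input_scale == "log2" else vals
    if vals.size >= 2:
        mean = raw.mean()
        if mean > 0:
            cv = raw.std(ddof=1) / mean
            if cv > cfg.replicate_cv_max:
                drop = int(np.argmax(np.abs(raw - np.median(raw))))
                vals = np.delete(vals, drop)
                raw = np.delete(raw, drop)
    if cfg.input_scale == "log2":
        return float(vals.mean())
    mean = float(raw.mean())
    return float(np.log2(mean)) if mean > 0 else np.nan


def detection_filter(matrix: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """Keep peptides detected in at least ``min_detect_frac`` of samples.

    Detection means a non-missing value strictly above
    ``cfg.detection_floor``.  Row order is preserved; an empty result
    triggers a warning rather than an error.
    """
    detected = matrix.notna() & (matrix > cfg.detection_floor)
    frac = detected.sum(axis=1) / matrix.shape[1]
    keep = frac >= cfg.min_detect_frac
    if not keep.any():
        warnings.warn("detection filter removed every peptide", stacklevel=2)
    return matrix.loc[keep]


def preprocess_experiment(
    exp: PeptideArrayExperiment, cfg: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Full preprocessing: saturation mask -> replicate collapse -> detection filter."""
    cfg = cfg or PreprocessConfig()
    masked = remove_saturated(exp)
    collapsed = collapse_replicates(masked, cfg)
    return detection_filter(collapsed, cfg)
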