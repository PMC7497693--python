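"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular data travel as TSV; missing values are written as ``NA``.
Kinase-substrate prediction sets use the GMT convention
(``kinase<TAB>description<TAB>substrate1<TAB>substrate2...``) with an
optional companion weights TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PeptideArrayExperiment

NA_REP = "NA"

SIGNAL_COLUMNS = ["peptide_id", "sample_id", "replicate", "signal", "saturated"]


def read_signal_long(path: str | Path) -> PeptideArrayExperiment:
    """Read a long-format signal TSV into a :class:`PeptideArrayExperiment`.

    Expected columns: peptide_id, sample_id, replicate (integer, 0- or
    1-based), signal, saturated (0/1).  Peptide and sample order follow
    first appearance in the file; absent (peptide, sample, replicate)
    combinations become NaN.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal TSV {path} lacks column(s): {', '.join(missing)}")
    peptides = list(dict.fromkeys(df["peptide_id"]))
    samples = list(dict.fromkeys(df["sample_id"]))
    reps = sorted(df["replicate"].unique())
    rep_pos = {r: k for k, r in enumerate(reps)}
    pep_pos = {p: k for k, p in enumerate(peptides)}
    samp_pos = {s: k for k, s in enumerate(samples)}

    signal = np.full((len(peptides), len(samples), len(reps)), np.nan)
    saturated = np.zeros_like(signal, dtype=bool)
    pi = df["peptide_id"].map(pep_pos).to_numpy()
    si = df["sample_id"].map(samp_pos).to_numpy()
    ri = df["replicate"].map(rep_pos).to_numpy()
    signal[pi, si, ri] = df["signal"].to_numpy(dtype=float)
    saturated[pi, si, ri] = df["saturated"].to_numpy(dtype=float) > 0
    return PeptideArrayExperiment(signal, saturated, peptides, samples)


def write_signal_long(exp: PeptideArrayExperiment, path: str | Path) -> None:
    """Write an experiment as a long-format signal TSV (lossless modulo NaN)."""
    rows = []
    for i, pep in enumerate(exp.peptide_ids):
        for j, samp in enumerate(exp.sample_ids):
            for r in range(exp.n_replicates):
                rows.append((pep, samp, r + 1, exp.signal[i, j, r], int(exp.saturated[i, j, r])))
    pd.DataFrame(rows, columns=SIGNAL_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep=NA_REP
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV (sample_id, er, pr, her2; values pos/neg)."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in annot.columns:
        raise ValueError(f"annotation TSV {path} lacks a sample_id column")
    annot = annot.set_index("sample_id")
    for col in ("er", "pr", "her2"):
        if col in annot.columns:
            bad = set(annot[col].dropna()) - {"pos", "neg"}
            if bad:
                raise ValueError(f"annotation column {col} has values {bad}, expected pos/neg")
    return annot


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA_REP)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature IDs)."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "peptide_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, na_rep=NA_REP)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene/substrate sets: name, description, then member IDs."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
        name, _desc, *members = fields
        if name in sets:
            raise ValueError(f"duplicate set name in GMT: {name!r}")
        sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_weights(path: str | Path) -> dict[tuple[str, str], float]:
    """Read an optional weights TSV (kinase, substrate_id, weight)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("kinase", "substrate_id", "weight"):
        if col not in df.columns:
            raise ValueError(f"weights TSV {path} lacks column {col!r}")
    return {
        (str(r.kinase), str(r.substrate_id)): float(r.weight)
        for r in df.itertuples(index=False)
    }


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV (sample_id, time, event with event in {0,1})."""
    surv = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in surv.columns:
            raise ValueError(f"survival TSV {path} lacks column {col!r}")
    surv = surv.set_index("sample_id")
    if (surv["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    if not set(surv["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    return surv


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list; '#' comments and blanks skipped."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return symbols
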