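"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_gene_list


def _data_path(name: str):
    return resources.files("kinact.data").joinpath(name)


def load_diffphos_reference() -> pd.DataFrame:
    """Published per-substrate differential phosphorylation table.

    The 30 tyrosine-kinase substrate peptides reported as significantly
    differently phosphorylated (raw p < 0.05) between PR+ and PR-
    ER+/HER2- breast tumors, with raw and corrected p-values, the PR-
    and PR+ group means (log2) and the printed log2 fold change
    (PR+ minus PR-).  Used as a worked reference for the differential
    phosphorylation output format and its arithmetic.
    """
    with resources.as_file(_data_path("diffphos_reference_table.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_kinome_list() -> list[str]:
    """Default kinome gene list (~85 human PTK symbols plus the
    substrate-derived gene symbols represented on the array)."""
    with resources.as_file(_data_path("kinome_ptk.txt")) as path:
        return read_gene_list(path)
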