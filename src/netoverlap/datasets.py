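"""Loaders for the packaged study gene lists and the published screen table.

The packaged fixtures are the worm RNAi modifier screen hit lists (78
suppressors, 3 enhancers of amyloid-beta-induced paralysis), the 63 human
orthologue symbols of the suppressor hits, and the published per-gene +1
interactome overlap screen table (60 genes with empirical p-values,
larger/smaller direction, and the direct-interactor flag).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from netoverlap.data_io import GeneList, read_gene_list, read_results_table

__all__ = [
    "load_worm_suppressors",
    "load_worm_enhancers",
    "load_suppressor_orthologues",
    "load_overlap_screen_table",
    "summarize_overlap_table",
]


def _data_path(filename: str):
    return resources.files("netoverlap.data").joinpath(filename)


def load_worm_suppressors() -> GeneList:
    """Worm genes whose knock-down suppresses the paralysis phenotype (78)."""
    with resources.as_file(_data_path("worm_suppressors.txt")) as path:
        return read_gene_list(path, name="worm_suppressors")


def load_worm_enhancers() -> GeneList:
    """Worm genes whose knock-down enhances the paralysis phenotype (3)."""
    with resources.as_file(_data_path("worm_enhancers.txt")) as path:
        return read_gene_list(path, name="worm_enhancers")


def load_suppressor_orthologues() -> GeneList:
    """Human orthologue symbols of the suppressor screen hits (63)."""
    with resources.as_file(_data_path("suppressor_orthologues.txt")) as path:
        return read_gene_list(path, name="suppressor_orthologues")


def load_overlap_screen_table() -> pd.DataFrame:
    """Published per-gene overlap screen table (gene, p_value, direction,
    direct_interactor; 60 rows)."""
    with resources.as_file(_data_path("overlap_screen.tsv")) as path:
        return read_results_table(path)


def summarize_overlap_table(table: pd.DataFrame, alpha: float = 0.05) -> dict[str, int]:
    """Headline counts of an overlap screen table.

    Returns row count, number of genes significant at ``alpha`` (strict),
    the larger/smaller split among them, and the direct-interactor count.
    """
    sig = table[table["p_value"] < alpha]
    return {
        "n_rows": int(len(table)),
        "n_significant": int(len(sig)),
        "n_larger": int((sig["direction"] == "larger").sum()),
        "n_smaller": int((sig["direction"] == "smaller").sum()),
        "n_direct_interactors": int(table["direct_interactor"].sum()),
    }
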