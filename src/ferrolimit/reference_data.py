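"""Published reference tables for the *Ca.* Pelagibacter ubique
iron-limitation experiment, shipped as package data.

``load_transcript_table`` returns the 23 transcripts reported at least
50% more abundant under iron limitation 24 h after siderophore addition
(fluorescence ratio of three biological replicates, two-tailed t-test
p-value, and the radial-layout cluster each gene fell in, where one was
assigned).  ``load_protein_table`` returns the proteins reported at least
50% more abundant under iron limitation on days 18 and 28 (per-protein
fold ratio and Fisher-combined one-tailed p-value).

These tables serve as worked-example inputs for the fold filters and the
integration report; they are measurement results, not synthetic data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    path = resources.files("ferrolimit").joinpath("data", name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False,
                           na_values=[], dtype={"gene": str, "description": str})


def load_transcript_table() -> pd.DataFrame:
    """Upregulated-transcript table: locus_id, gene, description, ratio,
    p_value, cluster ('' where no cluster was assigned)."""
    return _load("iron_limitation_transcripts.tsv")


def load_protein_table() -> pd.DataFrame:
    """Upregulated-protein table: day, locus_id, gene, description,
    ratio, p_value."""
    return _load("iron_limitation_proteins.tsv")
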