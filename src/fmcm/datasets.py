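"""Bundled reference datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fdam import FDAM, fdam_from_table


def colorectal_adenoma_fdam() -> FDAM:
    """The published function-drug association screen for colorectal adenoma.

    46 drugs linked to eight functional modules (apoptosis, cell cycle,
    cell proliferation, DNA replication, immune system process, RNA
    metabolic process, transcription, signal transduction) by signed
    enrichment scores; 41 drugs are purely beneficial and 5 carry at least
    one harmful link. Used as the worked example for the compound search.
    """
    path = resources.files("fmcm.data").joinpath("colorectal_adenoma_fdam.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t", comment="#")
    return fdam_from_table(table)
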