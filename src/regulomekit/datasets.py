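"""Packaged reference tables.

Two small published tables ship with the package: the 4q24 lung cis-eQTL
rows (lung-function-associated SNPs with per-gene eQTL FDR and effect size
for the two neighbouring candidate genes) and the core-regulome fold-change
table (consensus differentially expressed genes at the 48 h and 120 h
timepoints under both knockdown constructs, as linear fold changes).
"""

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("regulomekit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_eqtl_table() -> pd.DataFrame:
    """4q24 cis-eQTL rows: snp, position, FEV1 p-value, per-gene FDR/effect."""
    return _load("eqtl_4q24.tsv")


def load_core_regulome_table() -> pd.DataFrame:
    """Core-regulome fold changes at 48 h / 120 h for both knockdowns."""
    return _load("core_regulome_fc.tsv")
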