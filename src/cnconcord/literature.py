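"""Literature-reported per-gene concordance counts.

Ten genes with experimentally supported CNV-expression coupling, with
their amplified-and-upregulated (n_AU) and deleted-and-downregulated
(n_DD) event counts across a pan-cancer tumor cohort as reported in the
literature.  Used to sanity-check the concordance-ratio arithmetic: nine
genes are A&U-dominant and one (STK11) is D&D-dominant.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_literature_counts() -> pd.DataFrame:
    """The packaged ten-gene count table (gene, n_AU, n_DD, direction)."""
    path = resources.files("cnconcord.data") / "literature_concordance_counts.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", index_col="gene")


def concordance_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Add au_ratio / dd_ratio columns (shares of concordant events)."""
    out = counts.copy()
    denom = out["n_AU"] + out["n_DD"]
    out["au_ratio"] = out["n_AU"] / denom
    out["dd_ratio"] = out["n_DD"] / denom
    return out


def dd_percentage(counts: pd.DataFrame, gene: str) -> float:
    """D&D share of a gene's concordant events, in percent."""
    row = counts.loc[gene]
    return 100.0 * row["n_DD"] / (row["n_AU"] + row["n_DD"])


def au_dominant_count(counts: pd.DataFrame) -> int:
    """Number of genes whose A&U events strictly exceed their D&D events."""
    return int((counts["n_AU"] > counts["n_DD"]).sum())
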