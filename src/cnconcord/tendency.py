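"""Four-way variation-tendency classification.

Each (gene, sample) pair with a variant copy-number event (call +-2) and
a co-occurring differential-expression event is labeled with one of the
four tendencies:

* ``AU`` amplified and upregulated,
* ``AD`` amplified and downregulated,
* ``DU`` deleted and upregulated,
* ``DD`` deleted and downregulated,

and ``none`` otherwise.  AU and DD are the concordant (dosage-consistent)
classes; AD and DU are discordant.  Genes whose Z-scores are undefined
contribute neither labels nor variant events to the cohort totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import zscores

LABELS = ("AU", "AD", "DU", "DD")


@dataclass
class TendencyTable:
    """Per-pair labels plus per-gene and cohort-level event counts."""

    labels: pd.DataFrame                 # gene x sample, {AU,AD,DU,DD,none}
    gene_counts: pd.DataFrame            # n_AU, n_AD, n_DU, n_DD, n_amp, n_del
    total_variant_cn: int                # +-2 events among valid genes

    def to_long(self) -> pd.DataFrame:
        """Long (gene, sample, label) table of the non-``none`` pairs."""
        stacked = self.labels.stack()
        stacked = stacked[stacked != "none"]
        out = stacked.rename("label").reset_index()
        out.columns = ["gene", "sample", "label"]
        return out


def classify_tendency(calls: pd.DataFrame, degs: pd.DataFrame,
                      valid_genes: pd.Index | None = None) -> TendencyTable:
    """Combine variant copy-number events with DEG status.

    ``valid_genes`` restricts the computation to genes with defined
    Z-scores (from :class:`~cnconcord.zscores.ZScoreMatrix`); invalid
    genes are excluded from both numerators and the variant-event
    denominator.
    """
    if not calls.index.equals(degs.index) or not calls.columns.equals(degs.columns):
        raise ValueError("call and DEG matrices must share gene/sample indices")
    c = calls.to_numpy(dtype=float)
    d = degs.to_numpy(dtype=object)
    if valid_genes is None:
        valid = np.ones(len(calls.index), dtype=bool)
    else:
        valid = calls.index.isin(valid_genes)

    amp = (c == 2) & valid[:, None]
    dele = (c == -2) & valid[:, None]
    up = d == zscores.UP
    down = d == zscores.DOWN

    labels = np.full(c.shape, "none", dtype=object)
    labels[amp & up] = "AU"
    labels[amp & down] = "AD"
    labels[dele & up] = "DU"
    labels[dele & down] = "DD"

    gene_counts = pd.DataFrame(
        {
            "n_AU": (labels == "AU").sum(axis=1),
            "n_AD": (labels == "AD").sum(axis=1),
            "n_DU": (labels == "DU").sum(axis=1),
            "n_DD": (labels == "DD").sum(axis=1),
            "n_amp": amp.sum(axis=1),
            "n_del": dele.sum(axis=1),
        },
        index=calls.index)
    total_variant = int(amp.sum() + dele.sum())
    return TendencyTable(
        labels=pd.DataFrame(labels, index=calls.index, columns=calls.columns),
        gene_counts=gene_counts,
        total_variant_cn=total_variant)


def cohort_tendency_fractions(table: TendencyTable, calls: pd.DataFrame,
                              grouping: pd.Series | None = None,
                              valid_genes: pd.Index | None = None) -> pd.DataFrame:
    """Tendency-event fractions of the total variant copy-number count.

    The denominator is the number of variant (+-2) events among valid
    genes, whether or not a DEG co-occurs.  With a sample->cohort
    ``grouping`` the fractions are computed per cohort; cohorts with zero
    variant events get NaN fractions and ``defined=False``.
    """
    labels = table.labels
    if grouping is None:
        grouping = pd.Series("all", index=labels.columns)
    else:
        missing = labels.columns.difference(grouping.index)
        if len(missing):
            raise ValueError(
                f"samples missing from cohort grouping: {list(missing[:5])}")
        grouping = grouping.reindex(labels.columns)
    if valid_genes is None:
        valid = np.ones(len(labels.index), dtype=bool)
    else:
        valid = labels.index.isin(valid_genes)

    lab = labels.to_numpy(dtype=object)
    c = calls.loc[labels.index, labels.columns].to_numpy(dtype=float)
    variant = ((c == 2) | (c == -2)) & valid[:, None]
    rows = []
    for cohort in pd.unique(grouping):
        mask = (grouping == cohort).to_numpy()
        sub = lab[:, mask]
        row = {"cohort": cohort,
               **{f"n_{k}": int((sub == k).sum()) for k in LABELS},
               "total_variant_cn": int(variant[:, mask].sum())}
        rows.append(row)
    return _finalize_fractions(pd.DataFrame(rows).set_index("cohort"))


def _finalize_fractions(out: pd.DataFrame) -> pd.DataFrame:
    total = out["total_variant_cn"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in LABELS:
            out[f"frac_{k}"] = np.where(total > 0, out[f"n_{k}"] / total, np.nan)
    out["defined"] = total > 0
    out["frac_concordant"] = out["frac_AU"] + out["frac_DD"]
    out["frac_discordant"] = out["frac_AD"] + out["frac_DU"]
    return out
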