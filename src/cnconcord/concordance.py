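"""Identification of AUGs and DDGs.

A gene is an AUG (amplified-and-upregulated gene) when, across the
cohort, its amplified-and-upregulated events dominate its
deleted-and-downregulated events (concordance ratio > 50%) and both its
Spearman rho and its A&U event count strictly exceed thresholds
calibrated as the medians of a reference oncogene list; DDGs are the
symmetric class against a tumor-suppressor reference list.  Because a
true DDG pairs deletion with downregulation, its dosage relationship is
positive, so the signed rho criterion points the same way for both
classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUG = "AUG"
DDG = "DDG"
NEITHER = "neither"


@dataclass(frozen=True)
class ConcordanceThresholds:
    rho_min_aug: float
    count_min_aug: float
    rho_min_ddg: float
    count_min_ddg: float
    ratio_min: float = 0.5

    def __post_init__(self):
        if not 0 < self.ratio_min < 1:
            raise ValueError("ratio_min must be in (0, 1)")
        if self.count_min_aug < 0 or self.count_min_ddg < 0:
            raise ValueError("count thresholds must be >= 0")


#: thresholds of the original pan-cancer tumor analysis (9159 samples):
#: oncogene-median rho 0.4 and A&U count 146.5; TSG-median rho 0.41 and
#: D&D count 18.5.  Only meaningful at a comparable cohort size.
FIXED_THRESHOLDS = ConcordanceThresholds(
    rho_min_aug=0.4, count_min_aug=146.5,
    rho_min_ddg=0.41, count_min_ddg=18.5)


def load_reference_list(name_or_path) -> list[str]:
    """Read a gene-symbol list (one per line, '#' comments allowed).

    ``"oncogenes"`` and ``"tsgs"`` name the packaged stand-in lists of
    well-known oncogenes and tumor suppressors.
    """
    if name_or_path in ("oncogenes", "tsgs"):
        text = (resources.files("cnconcord.data") /
                f"{name_or_path}.txt").read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    genes = [ln.strip() for ln in text.splitlines()]
    return [g for g in genes if g and not g.startswith("#")]


def calibrate_thresholds(gene_counts: pd.DataFrame, assoc: pd.DataFrame,
                         oncogenes: list[str], tsgs: list[str],
                         ratio_min: float = 0.5) -> ConcordanceThresholds:
    """Threshold calibration from reference gene lists.

    count_min_aug / rho_min_aug are the medians of n_AU / rho over the
    oncogene list; count_min_ddg / rho_min_ddg the medians of n_DD / rho
    over the tumor-suppressor list.  The median of an even-length list is
    the mean of the two central order statistics, which is how
    half-integer count thresholds arise.  Reference genes absent from the
    tables (or with undefined rho) are logged and dropped.
    """
    def usable(ref: list[str], label: str) -> pd.Index:
        present = [g for g in ref if g in gene_counts.index
                   and g in assoc.index and np.isfinite(assoc.loc[g, "rho"])]
        dropped = sorted(set(ref) - set(present))
        if dropped:
            logger.warning("%s reference genes dropped (absent or "
                           "undefined rho): %s", label, dropped)
        if not present:
            raise ValueError(
                f"no usable {label} reference genes; supply a valid list "
                f"or use fixed-threshold mode")
        return pd.Index(present)

    onco = usable(oncogenes, "oncogene")
    tsg = usable(tsgs, "tumor-suppressor")
    return ConcordanceThresholds(
        rho_min_aug=float(assoc.loc[onco, "rho"].median()),
        count_min_aug=float(gene_counts.loc[onco, "n_AU"].median()),
        rho_min_ddg=float(assoc.loc[tsg, "rho"].median()),
        count_min_ddg=float(gene_counts.loc[tsg, "n_DD"].median()),
        ratio_min=ratio_min)


def identify_aug_ddg(gene_counts: pd.DataFrame, assoc: pd.DataFrame,
                     thresholds: ConcordanceThresholds) -> pd.DataFrame:
    """Classify every gene as AUG, DDG or neither.

    AUG iff au_ratio > ratio_min AND rho > rho_min_aug AND
    n_AU > count_min_aug; DDG symmetric on dd_ratio / n_DD; all
    comparisons strict.  au_ratio = n_AU / (n_AU + n_DD); genes with no
    concordant events at all are always ``neither``.  Mutual exclusivity
    follows from au_ratio + dd_ratio = 1 with ratio_min >= 0.5.
    """
    gc = gene_counts.join(assoc[["rho"]], how="left")
    n_au = gc["n_AU"].to_numpy(dtype=float)
    n_dd = gc["n_DD"].to_numpy(dtype=float)
    rho = gc["rho"].to_numpy(dtype=float)
    denom = n_au + n_dd
    with np.errstate(invalid="ignore", divide="ignore"):
        au_ratio = np.where(denom > 0, n_au / denom, np.nan)
        dd_ratio = np.where(denom > 0, n_dd / denom, np.nan)
    with np.errstate(invalid="ignore"):
        is_aug = ((au_ratio > thresholds.ratio_min)
                  & (rho > thresholds.rho_min_aug)
                  & (n_au > thresholds.count_min_aug))
        is_ddg = ((dd_ratio > thresholds.ratio_min)
                  & (rho > thresholds.rho_min_ddg)
                  & (n_dd > thresholds.count_min_ddg))
    status = np.where(is_aug, AUG, np.where(is_ddg, DDG, NEITHER))
    return pd.DataFrame(
        {"n_AU": gc["n_AU"], "n_DD": gc["n_DD"], "au_ratio": au_ratio,
         "dd_ratio": dd_ratio, "rho": gc["rho"], "status": status},
        index=gc.index)


def rank_top_concordant(gc: pd.DataFrame, k: int,
                        status: str = AUG) -> list[str]:
    """Top-k genes of one concordant class.

    AUGs sort by n_AU descending (DDGs by n_DD), ties broken by rho
    descending then gene symbol ascending, so the ranking is
    deterministic.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if status not in (AUG, DDG):
        raise ValueError(f"status must be {AUG!r} or {DDG!r}")
    count_col = "n_AU" if status == AUG else "n_DD"
    sub = gc[gc["status"] == status].copy()
    sub = sub.reset_index(names="gene").sort_values(
        [count_col, "rho", "gene"], ascending=[False, False, True])
    return sub["gene"].head(k).tolist()


def chromosome_distribution(gc: pd.DataFrame,
                            annotation: pd.Series) -> pd.DataFrame:
    """Chromosome fractions of the AUG-union-DDG gene set.

    Unannotated concordant genes are logged and excluded from the
    denominator; fractions sum to 1 over the included genes.
    """
    concordant = gc.index[gc["status"].isin([AUG, DDG])]
    if len(concordant) == 0:
        return pd.DataFrame(columns=["n_genes", "fraction"])
    annotated = concordant.intersection(annotation.dropna().index)
    skipped = concordant.difference(annotated)
    if len(skipped):
        logger.warning("concordant genes without chromosome annotation "
                       "excluded: %s", list(skipped[:10]))
    if len(annotated) == 0:
        return pd.DataFrame(columns=["n_genes", "fraction"])
    counts = annotation.loc[annotated].value_counts()
    out = pd.DataFrame({"n_genes": counts,
                        "fraction": counts / counts.sum()})
    out.index.name = "chromosome"
    return out
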