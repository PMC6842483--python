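"""Diploid-referenced expression Z-scores and DEG calls.

For each gene the reference set is the samples that are copy-number
neutral (call 0) for that gene; the Z-score of every sample is
``(x - u) / o`` with ``u`` and ``o`` the mean and sample standard
deviation (n-1 denominator, cBioPortal convention) of expression over
that reference set.  A sample is an upregulation event when z > 2 and a
downregulation event when z < -2, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass
class ZScoreMatrix:
    """Z-scores plus per-gene reference-set diagnostics.

    ``z`` is gene x sample with NaN wherever the gene is invalid;
    ``stats`` has one row per gene: diploid_n, u (reference mean),
    o (reference sd), valid, reason.
    """

    z: pd.DataFrame
    stats: pd.DataFrame

    @property
    def valid_genes(self) -> pd.Index:
        return self.stats.index[self.stats["valid"]]


def compute_z(expression: pd.DataFrame, calls: pd.DataFrame,
              min_diploid: int = 3,
              log2_offset: float | None = None) -> ZScoreMatrix:
    """Compute diploid-referenced Z-scores for every gene and sample.

    Genes with fewer than ``min_diploid`` diploid reference samples, or a
    zero-variance reference set, are flagged invalid with a recorded
    reason and get undefined (NaN) z everywhere; they are excluded from
    all downstream per-gene computations rather than imputed.

    ``log2_offset``, when given, applies log2(x + offset) to the
    expression matrix first (off by default; RSEM-like values are used
    as-is).
    """
    if min_diploid < 2:
        raise ValueError(f"min_diploid must be >= 2, got {min_diploid}")
    if expression.empty:
        raise ValueError("empty expression matrix")
    if not expression.index.equals(calls.index) or \
            not expression.columns.equals(calls.columns):
        common_g = expression.index.intersection(calls.index)
        common_s = expression.columns.intersection(calls.columns)
        if len(common_g) == 0 or len(common_s) == 0:
            raise ValueError(
                "expression and call matrices share no genes or no samples")
        expression = expression.loc[common_g, common_s]
        calls = calls.loc[common_g, common_s]

    x = expression.to_numpy(dtype=float)
    if log2_offset is not None:
        x = np.log2(x + log2_offset)
    c = calls.to_numpy(dtype=float)
    diploid = c == 0

    n_ref = diploid.sum(axis=1)
    # masked stats over the diploid reference set of each gene
    xm = np.where(diploid, x, np.nan)
    with np.errstate(invalid="ignore"):
        u = np.nanmean(np.where(diploid, x, np.nan), axis=1)
        # sample sd (n-1); genes with n_ref < 2 handled by validity below
        sq = np.nansum((xm - u[:, None]) ** 2, axis=1)
        denom = np.maximum(n_ref - 1, 1)
        o = np.sqrt(sq / denom)

    valid = (n_ref >= min_diploid) & (o > 0) & np.isfinite(o)
    reason = np.where(
        n_ref < min_diploid, f"fewer than {min_diploid} diploid samples",
        np.where(o > 0, "", "zero variance in diploid reference"))
    reason = np.where(valid, "", reason)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - u[:, None]) / o[:, None]
    z[~valid, :] = np.nan
    # missing calls leave z defined (z-scores apply to all samples), but
    # missing expression propagates NaN naturally
    stats = pd.DataFrame(
        {"diploid_n": n_ref.astype(int), "u": u, "o": o, "valid": valid,
         "reason": reason},
        index=expression.index)
    return ZScoreMatrix(
        z=pd.DataFrame(z, index=expression.index, columns=expression.columns),
        stats=stats)


def call_degs(zmat: ZScoreMatrix | pd.DataFrame,
              threshold: float = 2.0) -> pd.DataFrame:
    """Call per-(gene, sample) DEG status from Z-scores.

    Strict inequalities: ``up`` iff z > threshold, ``down`` iff
    z < -threshold, else ``none``; undefined z is always ``none``.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    z = zmat.z if isinstance(zmat, ZScoreMatrix) else zmat
    v = z.to_numpy(dtype=float)
    status = np.full(v.shape, NONE, dtype=object)
    with np.errstate(invalid="ignore"):
        status[v > threshold] = UP
        status[v < -threshold] = DOWN
    return pd.DataFrame(status, index=z.index, columns=z.columns)


def deg_counts(degs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of up- and down-regulation events."""
    v = degs.to_numpy(dtype=object)
    return pd.DataFrame(
        {"n_up": (v == UP).sum(axis=1), "n_down": (v == DOWN).sum(axis=1)},
        index=degs.index)
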