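"""Discrete copy-number call harmonization.

Two input dialects are supported:

* GISTIC-style discrete calls on the five-level scale
  (-2 homozygous deletion, -1 hemizygous deletion, 0 neutral,
  +1 gain, +2 high-level amplification);
* PICNIC-style absolute total copy number plus per-sample average
  genome ploidy, reduced to amplified / deleted / neutral through
  ploidy-conditional thresholds.

Only the extreme levels (+-2) count as variant events for tendency
classification; gains and hemizygous losses remain ordinary regression
abscissae for the correlation statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AMPLIFIED = "amplified"
DELETED = "deleted"
NEUTRAL = "neutral"

#: average-genome-ploidy cutoff separating the two PICNIC regimes
PLOIDY_CUTOFF = 2.7
#: amplification requires total CN >= 5 (near-diploid) or >= 9 (polyploid)
AMP_CN_DIPLOID = 5
AMP_CN_POLYPLOID = 9


def classify_picnic(total_cn: float, ploidy: float) -> str:
    """Classify one (gene, sample) pair from absolute copy number.

    Amplified iff (ploidy <= 2.7 and total_cn >= 5) or
    (ploidy > 2.7 and total_cn >= 9); deleted iff
    (ploidy <= 2.7 and total_cn == 0) or
    (ploidy > 2.7 and total_cn < ploidy - 2.7); otherwise neutral.
    The two branches are mutually exclusive for every valid input.
    """
    if not np.isfinite(total_cn) or not np.isfinite(ploidy):
        raise ValueError(f"non-finite input: total_cn={total_cn}, ploidy={ploidy}")
    if total_cn < 0:
        raise ValueError(f"total_cn must be >= 0, got {total_cn}")
    if ploidy <= 0:
        raise ValueError(f"ploidy must be > 0, got {ploidy}")
    if ploidy <= PLOIDY_CUTOFF:
        if total_cn >= AMP_CN_DIPLOID:
            return AMPLIFIED
        if total_cn == 0:
            return DELETED
    else:
        if total_cn >= AMP_CN_POLYPLOID:
            return AMPLIFIED
        if total_cn < ploidy - PLOIDY_CUTOFF:
            return DELETED
    return NEUTRAL


def calls_from_picnic(absolute_cn: pd.DataFrame, ploidy: pd.Series) -> pd.DataFrame:
    """Reduce an absolute CN matrix to three-level calls (-2, 0, +2).

    ``absolute_cn`` is gene x sample; ``ploidy`` is indexed by sample.
    PICNIC input carries no gain/hemiloss information, so the output uses
    only the variant-relevant levels.
    """
    missing = [s for s in absolute_cn.columns if s not in ploidy.index]
    if missing:
        raise ValueError(f"samples missing from ploidy table: {missing[:5]}")
    cn = absolute_cn.to_numpy(dtype=float)
    if np.nanmin(cn) < 0:
        raise ValueError("absolute copy numbers must be >= 0")
    p = ploidy.reindex(absolute_cn.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0):
        raise ValueError("ploidy values must be finite and > 0")
    near_diploid = p <= PLOIDY_CUTOFF
    amplified = np.where(near_diploid, cn >= AMP_CN_DIPLOID, cn >= AMP_CN_POLYPLOID)
    deleted = np.where(near_diploid, cn == 0, cn < p - PLOIDY_CUTOFF)
    calls = np.zeros_like(cn, dtype=np.int8)
    calls[amplified] = 2
    calls[deleted & ~amplified] = -2
    return pd.DataFrame(calls, index=absolute_cn.index,
                        columns=absolute_cn.columns)


def calls_from_gistic(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a discrete call matrix (entries in {-2..2} or missing).

    Returns a float matrix preserving NaN for missing entries; an
    out-of-range entry raises naming the gene, the sample and the value.
    Missing entries stay missing ("not evaluable") rather than being
    imputed as neutral, so they never inflate diploid reference sets.
    """
    if matrix.empty:
        raise ValueError("empty copy-number call matrix")
    values = matrix.to_numpy(dtype=float)
    finite = np.isfinite(values)
    bad = finite & ((values < -2) | (values > 2) | (values != np.round(values)))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"copy-number call out of range at gene {matrix.index[g]!r}, "
            f"sample {matrix.columns[s]!r}: {values[g, s]}")
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def variant_status(call: int) -> str:
    """Map one five-level call to amplified / deleted / neutral.

    +2 -> amplified, -2 -> deleted; -1, 0, +1 are not variant events for
    tendency classification.
    """
    if call not in (-2, -1, 0, 1, 2):
        raise ValueError(f"call must be in {{-2..2}}, got {call}")
    if call == 2:
        return AMPLIFIED
    if call == -2:
        return DELETED
    return NEUTRAL


def variant_masks(calls: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (amplified, deleted) masks over a call matrix; NaN-safe."""
    v = calls.to_numpy(dtype=float)
    return v == 2, v == -2
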